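"""Seed-reproducible synthetic datasets with the structure the analysis assumes.

The generator builds a small genome laid out as well-separated "sites"
(gene promoters and intergenic open-chromatin segments), places folded-G4
peaks inside the open-chromatin (DHS) workspace — a configurable fraction of
them ~80 bp upstream of a TSS — surrounds each with a stranded potential-G4
(OQ) footprint plus extra structure-free OQ sites, and then plants per-TF
ChIP-seq peak sets with a *known* fold enrichment at G4 centers:

    each peak is, independently with probability ``p``, centered on a
    uniformly chosen G4 (optionally displaced by a fixed offset whose sign
    follows the G4 strand — the R-loop-like mode), and otherwise placed
    uniformly over all legal start positions of the DHS workspace.

``p`` is solved from the closed-form expected-overlap equation so that the
expected randomization fold enrichment equals the requested target.  The
:class:`GeneratorLedger` records, per TF, the analytic expected overlap and
an exact null mean computed from the realized peak union by counting legal
start positions — the quantities every recovery check is scored against.

Expression follows ``log10 TPM = a + b * tf_count + Normal(0, sigma)`` with
``tf_count`` the number of distinct TFs bound at the promoter G4 (or the
promoter, for G4-free genes), so transcriptional output rises with hub
occupancy by construction.  Gaussian-bump signal tracks per TF support the
profile stage.  All randomness flows from a single seed through named
per-component substreams, so regenerating any one output is stable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .binding import BindingParams, CompetitionModel, competition_fraction
from .enrichment import Workspace, _sample_placements
from .intervals import (
    GenomeTable,
    GenomicInterval,
    IntervalSet,
    TssRecord,
    intersect,
    merge,
    write_bed,
    write_genome_table,
    write_tss_table,
)
from .profiles import SignalTrack, write_bedgraph

__all__ = [
    "TFSpec",
    "ExpressionModel",
    "SyntheticConfig",
    "GeneratorLedger",
    "SyntheticDataset",
    "generate_dataset",
    "simulate_elisa",
    "simulate_dose_response",
    "simulate_expression_experiment",
    "default_config",
    "fold_ladder_config",
]

# named substreams: all randomness flows from (seed, STREAM_x)
_STREAM_LAYOUT = 1
_STREAM_G4 = 2
_STREAM_OQ = 3
_STREAM_EXPR = 4
_STREAM_TF_BASE = 100


@dataclass
class TFSpec:
    """One synthetic TF peak set.

    ``target_fold`` is the desired randomization fold enrichment at G4s
    (>= 1); the targeting probability ``p`` is solved from it.  Alternatively
    ``p_target`` fixes ``p`` directly (used for the offset "R-loop-like" mode,
    where displaced peaks do not overlap the G4 so fold is not the right
    handle).  ``offset`` displaces targeted peaks downstream of the G4 by the
    given bp; with ``offset_strand_flip`` the genomic direction follows the
    G4 strand (downstream of a minus-strand G4 is toward lower coordinates).
    """

    label: str
    n_peaks: int
    peak_width: int = 40
    target_fold: Optional[float] = 1.0
    p_target: Optional[float] = None
    offset: int = 0
    offset_strand_flip: bool = False
    jitter: int = 5


@dataclass
class ExpressionModel:
    """log10 TPM = baseline + slope_per_tf * tf_count + Normal(0, noise_sd)."""

    baseline_log10_tpm: float = 0.5
    slope_per_tf: float = 0.08
    noise_sd: float = 0.5


@dataclass
class SyntheticConfig:
    n_chroms: int = 3
    chrom_length: int = 2_000_000
    n_genes: int = 600
    n_dhs_extra: int = 900
    dhs_promoter_fraction: float = 0.7
    dhs_extra_width: int = 800
    n_g4: int = 300
    g4_width: Tuple[int, int] = (30, 60)
    g4_promoter_fraction: float = 0.4
    g4_tss_offset: int = 80
    oq_superset_factor: float = 1.5
    oq_pad: int = 20
    promoter_upstream: int = 1000
    tfs: List[TFSpec] = field(default_factory=list)
    expression: ExpressionModel = field(default_factory=ExpressionModel)
    make_tracks: bool = True
    track_bin: int = 10
    track_halfwidth: int = 300
    track_sigma: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_g4 <= 0 or self.n_genes <= 0 or self.n_chroms <= 0:
            raise ValueError("all counts must be positive")
        if self.g4_width[0] < 20:
            raise ValueError("G4 widths must be >= 20 bp")
        if self.oq_superset_factor <= 1:
            raise ValueError("oq_superset_factor must be > 1")
        for tf in self.tfs:
            if tf.target_fold is not None and tf.target_fold < 1:
                raise ValueError(f"TF {tf.label}: target fold must be >= 1")


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default toy dataset: 3 chromosomes x 2 Mb, 600 genes, 300 G4s,
    12 TFs with planted folds spread over 1-8, plus an offset R-loop-like set.
    """
    folds = [1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 7.0, 8.0, 8.0]
    tfs = [
        TFSpec(label=f"TF{i + 1:02d}", n_peaks=800, peak_width=40, target_fold=f)
        for i, f in enumerate(folds)
    ]
    tfs.append(
        TFSpec(label="RLOOP", n_peaks=800, peak_width=40, target_fold=None,
               p_target=0.8, offset=140, offset_strand_flip=True)
    )
    cfg = SyntheticConfig(tfs=tfs, seed=seed)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def fold_ladder_config(seed: int = 0, n_peaks: int = 8000) -> SyntheticConfig:
    """A larger layout sized for precise fold-recovery studies.

    Twelve TFs with planted folds 1..12 over 4000 G4 sites in a ~5 Mb
    open-chromatin workspace; at these sizes the binomial scatter of the
    observed overlap is a few percent of its expectation even for the
    unenriched TF, so recovered folds resolve the whole ladder.
    """
    tfs = [
        TFSpec(label=f"TF{f:02d}", n_peaks=n_peaks, peak_width=40, target_fold=float(f))
        for f in range(1, 13)
    ]
    return SyntheticConfig(
        n_chroms=10,
        chrom_length=2_000_000,
        n_genes=2400,
        n_dhs_extra=4400,
        dhs_promoter_fraction=0.75,
        n_g4=4000,
        g4_width=(30, 50),
        g4_promoter_fraction=0.4,
        tfs=tfs,
        make_tracks=False,
        seed=seed,
    )


@dataclass
class TfLedgerEntry:
    label: str
    target_fold: Optional[float]
    p_target: float
    n_peaks: int
    expected_overlap: float
    expected_overlap_sd: float
    null_mean_exact: float
    expected_fold: float


@dataclass
class GeneratorLedger:
    """Ground truth for every planted quantity."""

    tf: Dict[str, TfLedgerEntry]
    genes: pd.DataFrame  # gene_id, dhs_positive, g4_positive, tf_count, log10_tpm
    g4_strand_counts: Dict[str, int]

    def to_json(self, path) -> None:
        payload = {
            "tf": {k: asdict(v) for k, v in self.tf.items()},
            "genes": self.genes.to_dict(orient="list"),
            "g4_strand_counts": self.g4_strand_counts,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    genome: GenomeTable
    tss: List[TssRecord]
    dhs: IntervalSet
    g4: IntervalSet
    oq_plus: IntervalSet
    oq_minus: IntervalSet
    tf_peaks: Dict[str, IntervalSet]
    tracks: Dict[str, SignalTrack]
    expression: Dict[str, float]
    config: SyntheticConfig

    def workspace(self) -> Workspace:
        return Workspace(self.dhs)


# ---------------------------------------------------------------------------
# closed-form planting math
# ---------------------------------------------------------------------------

def _exact_bg_hit_probs(
    g4_rows: pd.DataFrame, seg_bounds: np.ndarray, peak_width: int, total_legal: int
) -> np.ndarray:
    """Exact probability that one uniformly placed peak overlaps each G4.

    A background peak of width ``w`` starts uniformly over all legal start
    positions; the starts hitting G4 ``[gs, ge)`` inside host segment
    ``[s, e)`` are ``[max(gs - w + 1, s), min(ge - 1, e - w)]``.
    """
    gs = g4_rows["start"].to_numpy()
    ge = g4_rows["end"].to_numpy()
    s = seg_bounds[:, 0]
    e = seg_bounds[:, 1]
    lo = np.maximum(gs - peak_width + 1, s)
    hi = np.minimum(ge - 1, e - peak_width)
    return np.maximum(hi - lo + 1, 0) / float(total_legal)


def _targeted_hit_fraction(
    g4_rows: pd.DataFrame, spec: TFSpec
) -> np.ndarray:
    """Fraction of jitter draws for which a targeted peak overlaps its G4."""
    gs = g4_rows["start"].to_numpy()
    ge = g4_rows["end"].to_numpy()
    centers = (gs + ge) // 2
    signs = np.where(
        (g4_rows["strand"].to_numpy() == "-") & spec.offset_strand_flip, -1, 1
    )
    jit = np.arange(-spec.jitter, spec.jitter + 1)
    c = centers[:, None] + signs[:, None] * spec.offset + jit[None, :]
    half = spec.peak_width // 2
    ps = c - half
    pe = ps + spec.peak_width
    hit = (ps < ge[:, None]) & (pe > gs[:, None])
    return hit.mean(axis=1)


def _solve_targeting_probability(
    spec: TFSpec,
    g4_rows: pd.DataFrame,
    h: np.ndarray,
    kappa: np.ndarray,
    mean_piece_hit: float,
) -> float:
    """Solve the targeting probability ``p`` from the expected-fold equation.

    Expected overlap: ``E[O](p) = sum_j 1 - (1 - p*kappa_j/n_g4 -
    (1-p)*h_j)^n``.  The null mean is approximated for the solve (and later
    replaced by the exact value computed from the realized peak union) as
    ``mu0(p) = sum_j 1 - (1 - hbar_j)^(D(p) + (1-p)*n)`` with ``D(p)`` the
    expected number of distinct targeted G4s — targeted peaks stack on the
    same sites and therefore contribute less to the null than background
    peaks do.
    """
    n_g4 = len(g4_rows)
    n = spec.n_peaks

    def expected_overlap(p: float) -> float:
        q = p * kappa / n_g4 + (1 - p) * h
        return float(np.sum(1.0 - np.power(1.0 - q, n)))

    def null_mean(p: float) -> float:
        distinct = n_g4 * (1.0 - np.power(1.0 - p / n_g4, n))
        eff = distinct + (1 - p) * n
        return n_g4 * float(1.0 - np.power(1.0 - mean_piece_hit, eff))

    def fold(p: float) -> float:
        return expected_overlap(p) / null_mean(p)

    target = float(spec.target_fold)  # type: ignore[arg-type]
    if target <= fold(0.0):
        return 0.0
    if fold(1.0) < target:
        raise ValueError(
            f"TF {spec.label}: target fold {target:g} exceeds the maximum "
            f"achievable {fold(1.0):.2f} for this geometry; enlarge the "
            "workspace or lower the fold"
        )
    return float(brentq(lambda p: fold(p) - target, 0.0, 1.0, xtol=1e-10))


def _exact_null_mean(
    peaks: IntervalSet, workspace: Workspace, g4_lengths: np.ndarray
) -> float:
    """Exact expected overlap count for a workspace-randomized query.

    For each distinct query length L, the probability that a uniformly placed
    interval of length L overlaps the realized peak union is the number of
    legal start positions whose interval touches the union, divided by the
    total number of legal starts.  Start windows are built by extending each
    union piece L-1 bp to the left, merging, and intersecting with the
    per-segment legal start ranges.
    """
    union = merge(peaks, gap=0)
    total = 0.0
    for length in np.unique(g4_lengths):
        length = int(length)
        _, s_total = workspace.legal_starts(length)
        if s_total == 0:
            continue
        windows = IntervalSet(
            [
                GenomicInterval(iv.chrom, max(0, iv.start - length + 1), iv.end)
                for iv in union
            ]
        )
        legal = IntervalSet(
            [
                GenomicInterval(
                    workspace.chrom_names[ci], int(s), int(e) - length + 1
                )
                for ci, s, e in zip(
                    workspace.seg_chrom, workspace.seg_start, workspace.seg_end
                )
                if e - s >= length
            ]
        )
        hit_starts = intersect(merge(windows), legal).total_bp()
        p_hit = hit_starts / s_total
        total += p_hit * int(np.sum(g4_lengths == length))
    return total


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _layout_sites(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place gene and intergenic-DHS sites on an evenly spaced, jittered grid."""
    n_sites = cfg.n_genes + cfg.n_dhs_extra
    per_chrom = np.full(cfg.n_chroms, n_sites // cfg.n_chroms)
    per_chrom[: n_sites % cfg.n_chroms] += 1
    rows = []
    for ci in range(cfg.n_chroms):
        k = int(per_chrom[ci])
        if k == 0:
            continue
        slot = cfg.chrom_length // (k + 1)
        # the worst-case gap between adjacent sites must keep promoter
        # windows and promoter-DHS blocks of different genes from touching
        min_gap = slot - 2 * (slot // 10)
        if min_gap < 2 * cfg.promoter_upstream + 200:
            raise ValueError(
                "site layout too dense: increase chrom_length/n_chroms or "
                "reduce n_genes/n_dhs_extra"
            )
        jitter = rng.integers(-slot // 10, slot // 10 + 1, size=k)
        pos = (np.arange(1, k + 1) * slot + jitter).astype(np.int64)
        for p in pos:
            rows.append({"chrom": f"chr{ci + 1}", "pos": int(p)})
    df = pd.DataFrame(rows)
    kind = np.array(["gene"] * cfg.n_genes + ["extra"] * cfg.n_dhs_extra)
    rng.shuffle(kind)
    df["kind"] = kind
    return df


def generate_dataset(
    config: SyntheticConfig, outdir: Optional[Path] = None
) -> Tuple[SyntheticDataset, GeneratorLedger]:
    """Generate the full file bundle and its ground-truth ledger.

    With ``outdir`` set, writes genome.tsv, tss.tsv, dhs.bed, g4.bed,
    oq_plus.bed / oq_minus.bed, one BED per TF under tf/, one bedGraph per TF
    under tracks/ (when enabled) and ledger.json.  The same seed always
    produces a byte-identical bundle.
    """
    cfg = config
    genome = GenomeTable({f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)})
    rng_layout = np.random.default_rng([cfg.seed, _STREAM_LAYOUT])
    sites = _layout_sites(cfg, rng_layout)

    # --- genes, promoters, DHS ------------------------------------------
    gene_rows = sites[sites["kind"] == "gene"].reset_index(drop=True)
    extra_rows = sites[sites["kind"] == "extra"].reset_index(drop=True)
    strands = rng_layout.choice(["+", "-"], size=len(gene_rows))
    dhs_flags = rng_layout.random(len(gene_rows)) < cfg.dhs_promoter_fraction
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i + 1:05d}" for i in range(len(gene_rows))],
            "chrom": gene_rows["chrom"],
            "tss": gene_rows["pos"],
            "strand": strands,
            "dhs_positive": dhs_flags,
        }
    )
    dhs_iv: List[GenomicInterval] = []
    for _, g in genes[genes["dhs_positive"]].iterrows():
        if g["strand"] == "+":
            dhs_iv.append(
                GenomicInterval(g["chrom"], g["tss"] - cfg.promoter_upstream - 100,
                                g["tss"] + 100)
            )
        else:
            dhs_iv.append(
                GenomicInterval(g["chrom"], g["tss"] - 100,
                                g["tss"] + cfg.promoter_upstream + 100)
            )
    half_extra = cfg.dhs_extra_width // 2
    for _, row in extra_rows.iterrows():
        dhs_iv.append(
            GenomicInterval(row["chrom"], row["pos"] - half_extra, row["pos"] + half_extra)
        )
    dhs = merge(IntervalSet(dhs_iv, label="DHS"))
    workspace = Workspace(dhs)

    # --- G4 placement ----------------------------------------------------
    rng_g4 = np.random.default_rng([cfg.seed, _STREAM_G4])
    n_prom_g4 = int(round(cfg.n_g4 * cfg.g4_promoter_fraction))
    n_extra_g4 = cfg.n_g4 - n_prom_g4
    dhs_gene_idx = np.flatnonzero(genes["dhs_positive"].to_numpy())
    if n_prom_g4 > len(dhs_gene_idx) or n_extra_g4 > len(extra_rows):
        raise ValueError(
            "requested G4 count exceeds workspace capacity "
            f"({n_prom_g4} promoter G4s for {len(dhs_gene_idx)} open promoters, "
            f"{n_extra_g4} intergenic G4s for {len(extra_rows)} segments)"
        )
    prom_hosts = rng_g4.choice(dhs_gene_idx, size=n_prom_g4, replace=False)
    extra_hosts = rng_g4.choice(len(extra_rows), size=n_extra_g4, replace=False)
    widths = rng_g4.integers(cfg.g4_width[0], cfg.g4_width[1] + 1, size=cfg.n_g4)
    g4_strands = rng_g4.choice(["+", "-"], size=cfg.n_g4)
    max_reach = max(
        (tf.peak_width + abs(tf.offset) for tf in cfg.tfs), default=0
    ) + 20
    extra_margin = max_reach + cfg.g4_width[1] // 2
    jitter_span = max(half_extra - extra_margin, 0)
    g4_records: List[dict] = []
    for k, host in enumerate(prom_hosts):
        g = genes.iloc[host]
        center = g["tss"] - cfg.g4_tss_offset if g["strand"] == "+" else g["tss"] + cfg.g4_tss_offset
        w = int(widths[k])
        seg = (
            (g["tss"] - cfg.promoter_upstream - 100, g["tss"] + 100)
            if g["strand"] == "+"
            else (g["tss"] - 100, g["tss"] + cfg.promoter_upstream + 100)
        )
        g4_records.append(
            {
                "chrom": g["chrom"], "start": int(center - w // 2),
                "end": int(center - w // 2 + w), "strand": g4_strands[k],
                "gene_idx": int(host), "seg_start": int(seg[0]), "seg_end": int(seg[1]),
            }
        )
    for k, host in enumerate(extra_hosts):
        row = extra_rows.iloc[host]
        off = int(rng_g4.integers(-jitter_span, jitter_span + 1)) if jitter_span else 0
        center = int(row["pos"]) + off
        w = int(widths[n_prom_g4 + k])
        g4_records.append(
            {
                "chrom": row["chrom"], "start": center - w // 2,
                "end": center - w // 2 + w, "strand": g4_strands[n_prom_g4 + k],
                "gene_idx": -1,
                "seg_start": int(row["pos"]) - half_extra,
                "seg_end": int(row["pos"]) + half_extra,
            }
        )
    g4_df = pd.DataFrame(g4_records)
    g4 = IntervalSet(
        [
            GenomicInterval(r["chrom"], r["start"], r["end"], strand=r["strand"],
                            name=f"G4_{i + 1:05d}")
            for i, r in g4_df.iterrows()
        ],
        label="G4",
    )

    # --- OQ maps: strict superset of the G4 footprint --------------------
    rng_oq = np.random.default_rng([cfg.seed, _STREAM_OQ])
    oq_records: List[GenomicInterval] = []
    for _, r in g4_df.iterrows():
        oq_records.append(
            GenomicInterval(r["chrom"], r["start"] - cfg.oq_pad, r["end"] + cfg.oq_pad,
                            strand=r["strand"])
        )
    n_extra_oq = int(round((cfg.oq_superset_factor - 1.0) * cfg.n_g4))
    mean_w = (cfg.g4_width[0] + cfg.g4_width[1]) // 2
    free_genes = [i for i in dhs_gene_idx if i not in set(int(x) for x in prom_hosts)]
    free_extra = [i for i in range(len(extra_rows)) if i not in set(int(x) for x in extra_hosts)]
    hosts: List[Tuple[str, int]] = [("gene", i) for i in free_genes] + [
        ("extra", i) for i in free_extra
    ]
    if n_extra_oq > len(hosts):
        warnings.warn("not enough G4-free sites for the requested OQ superset factor",
                      stacklevel=2)
        n_extra_oq = len(hosts)
    pick = rng_oq.choice(len(hosts), size=n_extra_oq, replace=False)
    for idx in pick:
        kind, i = hosts[int(idx)]
        strand = str(rng_oq.choice(["+", "-"]))
        if kind == "gene":
            g = genes.iloc[i]
            center = g["tss"] - cfg.g4_tss_offset if g["strand"] == "+" else g["tss"] + cfg.g4_tss_offset
            chrom = g["chrom"]
        else:
            row = extra_rows.iloc[i]
            center, chrom = int(row["pos"]), row["chrom"]
        oq_records.append(
            GenomicInterval(chrom, int(center) - mean_w // 2,
                            int(center) - mean_w // 2 + mean_w, strand=strand)
        )
    oq_plus = IntervalSet([iv for iv in oq_records if iv.strand == "+"], label="OQ_plus")
    oq_minus = IntervalSet([iv for iv in oq_records if iv.strand == "-"], label="OQ_minus")

    # --- TF peaks with planted enrichment --------------------------------
    seg_bounds = g4_df[["seg_start", "seg_end"]].to_numpy()
    g4_lengths = (g4_df["end"] - g4_df["start"]).to_numpy()
    tf_peaks: Dict[str, IntervalSet] = {}
    tf_ledger: Dict[str, TfLedgerEntry] = {}
    g4_centers = ((g4_df["start"] + g4_df["end"]) // 2).to_numpy()
    g4_chroms = g4_df["chrom"].to_numpy()
    for t_idx, spec in enumerate(cfg.tfs):
        rng_tf = np.random.default_rng([cfg.seed, _STREAM_TF_BASE + t_idx])
        _, total_legal = workspace.legal_starts(spec.peak_width)
        h = _exact_bg_hit_probs(g4_df, seg_bounds, spec.peak_width, total_legal)
        kappa = _targeted_hit_fraction(g4_df, spec)
        mean_piece = float(np.mean((g4_lengths + spec.peak_width - 1))) / total_legal
        if spec.p_target is not None:
            p = float(spec.p_target)
        else:
            p = _solve_targeting_probability(spec, g4_df, h, kappa, mean_piece)
        targeted = rng_tf.random(spec.n_peaks) < p
        n_t = int(targeted.sum())
        half = spec.peak_width // 2
        intervals: List[GenomicInterval] = []
        if n_t:
            tgt = rng_tf.integers(0, cfg.n_g4, size=n_t)
            jit = rng_tf.integers(-spec.jitter, spec.jitter + 1, size=n_t)
            signs = np.where(
                (g4_df["strand"].to_numpy()[tgt] == "-") & spec.offset_strand_flip, -1, 1
            )
            centers = g4_centers[tgt] + signs * spec.offset + jit
            for c, gi in zip(centers, tgt):
                start = int(c) - half
                intervals.append(
                    GenomicInterval(g4_chroms[gi], start, start + spec.peak_width)
                )
        n_b = spec.n_peaks - n_t
        if n_b:
            placements, excluded = _sample_placements(
                np.full(n_b, spec.peak_width, dtype=np.int64), workspace, 1, rng_tf
            )
            if excluded.any():
                raise ValueError(f"TF {spec.label}: peaks wider than every DHS segment")
            ci, starts = placements[spec.peak_width]
            for c, s in zip(ci[0], starts[0]):
                intervals.append(
                    GenomicInterval(workspace.chrom_names[int(c)], int(s),
                                    int(s) + spec.peak_width)
                )
        peaks = IntervalSet(intervals, label=spec.label)
        tf_peaks[spec.label] = peaks
        q = p * kappa / cfg.n_g4 + (1 - p) * h
        per_g4 = 1.0 - np.power(1.0 - q, spec.n_peaks)
        e_overlap = float(per_g4.sum())
        sd_overlap = float(np.sqrt(np.sum(per_g4 * (1 - per_g4))))
        mu0 = _exact_null_mean(peaks, workspace, g4_lengths)
        tf_ledger[spec.label] = TfLedgerEntry(
            label=spec.label,
            target_fold=spec.target_fold,
            p_target=p,
            n_peaks=spec.n_peaks,
            expected_overlap=e_overlap,
            expected_overlap_sd=sd_overlap,
            null_mean_exact=mu0,
            expected_fold=e_overlap / mu0 if mu0 > 0 else float("nan"),
        )

    # --- expression: independent bookkeeping of per-gene TF counts -------
    # tf_count is taken on the full promoter window for every gene, so the
    # G4+/G4- comparison is width-matched: G4-positive promoters receive the
    # background rate plus the planted targeted peaks at their G4
    rng_expr = np.random.default_rng([cfg.seed, _STREAM_EXPR])
    gene_region: List[Tuple[str, int, int]] = []
    g4_pos_flags = np.zeros(len(genes), dtype=bool)
    for i in g4_df.loc[g4_df["gene_idx"] >= 0, "gene_idx"]:
        g4_pos_flags[int(i)] = True
    for i, g in genes.iterrows():
        if g["strand"] == "+":
            s, e = g["tss"] - cfg.promoter_upstream, g["tss"]
        else:
            s, e = g["tss"], g["tss"] + cfg.promoter_upstream
        gene_region.append((g["chrom"], int(s), int(e)))
    # brute-force membership via per-chromosome sorted starts + running max end
    tf_count = np.zeros(len(genes), dtype=np.int64)
    for label, peaks in tf_peaks.items():
        index: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends) in peaks.by_chrom().items():
            index[chrom] = (starts, np.maximum.accumulate(ends))
        for i, (chrom, s, e) in enumerate(gene_region):
            if chrom not in index:
                continue
            starts, cummax_end = index[chrom]
            k = int(np.searchsorted(starts, e, side="left"))
            if k > 0 and cummax_end[k - 1] > s:
                tf_count[i] += 1
    expr = cfg.expression
    log_tpm = (
        expr.baseline_log10_tpm
        + expr.slope_per_tf * tf_count
        + rng_expr.normal(0.0, expr.noise_sd, size=len(genes))
    )
    tpm = np.power(10.0, log_tpm)
    tss_records = [
        TssRecord(g["gene_id"], g["chrom"], int(g["tss"]), g["strand"], tpm=float(tpm[i]))
        for i, g in genes.iterrows()
    ]
    expression = {r.gene_id: float(r.tpm) for r in tss_records}

    # --- signal tracks ----------------------------------------------------
    tracks: Dict[str, SignalTrack] = {}
    if cfg.make_tracks:
        nbins_half = cfg.track_halfwidth // cfg.track_bin
        rel = (np.arange(-nbins_half, nbins_half) + 0.5) * cfg.track_bin
        bump = np.exp(-0.5 * (rel / cfg.track_sigma) ** 2)
        for label, peaks in tf_peaks.items():
            dense: Dict[str, np.ndarray] = {
                c: np.zeros(cfg.chrom_length // cfg.track_bin + 1) for c in genome
            }
            for iv in peaks:
                cbin = iv.center // cfg.track_bin
                lo = cbin - nbins_half
                hi = cbin + nbins_half
                b0, b1 = max(lo, 0), min(hi, len(dense[iv.chrom]))
                dense[iv.chrom][b0:b1] += bump[b0 - lo: len(bump) - (hi - b1)]
            data = {}
            for chrom, arr in dense.items():
                nz = np.flatnonzero(arr)
                if len(nz) == 0:
                    continue
                starts = nz * cfg.track_bin
                data[chrom] = (starts, starts + cfg.track_bin, arr[nz])
            tracks[label] = SignalTrack(data)

    dataset = SyntheticDataset(
        genome=genome, tss=tss_records, dhs=dhs, g4=g4,
        oq_plus=oq_plus, oq_minus=oq_minus, tf_peaks=tf_peaks,
        tracks=tracks, expression=expression, config=cfg,
    )
    ledger = GeneratorLedger(
        tf=tf_ledger,
        genes=pd.DataFrame(
            {
                "gene_id": genes["gene_id"],
                "dhs_positive": genes["dhs_positive"],
                "g4_positive": g4_pos_flags,
                "tf_count": tf_count,
                "log10_tpm": log_tpm,
            }
        ),
        g4_strand_counts={
            "+": int(np.sum(g4_df["strand"] == "+")),
            "-": int(np.sum(g4_df["strand"] == "-")),
        },
    )
    if outdir is not None:
        _write_bundle(dataset, ledger, Path(outdir))
    return dataset, ledger


def _write_bundle(ds: SyntheticDataset, ledger: GeneratorLedger, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome_table(ds.genome, outdir / "genome.tsv")
    write_tss_table(ds.tss, outdir / "tss.tsv")
    write_bed(ds.dhs, outdir / "dhs.bed")
    write_bed(ds.g4, outdir / "g4.bed")
    write_bed(ds.oq_plus, outdir / "oq_plus.bed")
    write_bed(ds.oq_minus, outdir / "oq_minus.bed")
    tf_dir = outdir / "tf"
    tf_dir.mkdir(exist_ok=True)
    for label, peaks in ds.tf_peaks.items():
        write_bed(peaks, tf_dir / f"{label}.bed")
    if ds.tracks:
        tr_dir = outdir / "tracks"
        tr_dir.mkdir(exist_ok=True)
        for label, track in ds.tracks.items():
            write_bedgraph(track, tr_dir / f"{label}.bedGraph")
    ledger.to_json(outdir / "ledger.json")


# ---------------------------------------------------------------------------
# binding-assay simulators
# ---------------------------------------------------------------------------

def simulate_elisa(
    true_params: BindingParams,
    conc: Sequence[float],
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Replicate saturation-curve signals with multiplicative Gaussian noise.

    ``signal = model(conc) * (1 + Normal(0, noise_cv))`` per replicate well.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    conc = np.asarray(conc, dtype=float)
    ideal = true_params.signal(conc)
    rows = []
    for rep in range(n_replicates):
        noise = rng.normal(0.0, noise_cv, size=len(conc)) if noise_cv > 0 else 0.0
        for c, s in zip(conc, ideal * (1.0 + noise)):
            rows.append({"conc_nM": float(c), "replicate": rep + 1, "signal": float(s)})
    return pd.DataFrame(rows)


def simulate_dose_response(
    model: CompetitionModel,
    doses: Sequence[float],
    noise_cv: float = 0.08,
    seed: Optional[int] = None,
    signal_scale: float = 1.0,
    background: float = 0.0,
) -> pd.DataFrame:
    """Competitive-displacement curve: occupancy scaled to signal units + noise."""
    doses = np.asarray(doses, dtype=float)
    if np.any(np.diff(doses) < 0):
        raise ValueError("doses must be increasing")
    rng = np.random.default_rng(seed)
    theta = competition_fraction(model, doses)
    ideal = background + signal_scale * theta
    noise = rng.normal(0.0, noise_cv, size=len(doses)) if noise_cv > 0 else 0.0
    return pd.DataFrame({"dose_nM": doses, "response": ideal * (1.0 + noise)})


def simulate_expression_experiment(
    n_genes: int = 500,
    slope_per_tf: float = 0.08,
    seed: Optional[int] = None,
    g4_fraction: float = 0.4,
    tf_rate_g4: float = 8.0,
    tf_rate_no_g4: float = 2.0,
    baseline_log10_tpm: float = 0.5,
    noise_sd: float = 0.5,
) -> pd.DataFrame:
    """Lightweight draw of the hub/expression model for power studies.

    Promoter G4 status is Bernoulli; the bound-TF count is Poisson with a
    higher rate at G4-positive promoters; log10 TPM rises linearly with the
    count.  With ``slope_per_tf = 0`` the two G4 classes have identical
    expression distributions, which is the null of the rank-sum comparison.
    """
    rng = np.random.default_rng(seed)
    g4_positive = rng.random(n_genes) < g4_fraction
    tf_count = np.where(
        g4_positive,
        rng.poisson(tf_rate_g4, size=n_genes),
        rng.poisson(tf_rate_no_g4, size=n_genes),
    )
    log_tpm = baseline_log10_tpm + slope_per_tf * tf_count + rng.normal(0, noise_sd, n_genes)
    return pd.DataFrame(
        {"g4_positive": g4_positive, "tf_count": tf_count, "log10_tpm": log_tpm,
         "tpm": np.power(10.0, log_tpm)}
    )
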