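"""Workspace-constrained randomization enrichment of peak sets.

The central question: are transcription-factor (TF) ChIP-seq peaks found at
G-quadruplex (G4) sites more often than expected in comparably open chromatin?
The null model keeps every query interval's length and confines random
placements to a *workspace* (typically the DNase-hypersensitive fraction of
the genome), so G4/TF co-occurrence is measured against an open-chromatin
background rather than the whole genome.

The query set (G4 peaks, control sites or consensus motif sites) is the set
that gets randomized.  One null ensemble is generated per query/workspace/seed
and reused across all subject (TF) peak sets, which makes a screen over
hundreds of TFs cheap and keeps per-TF results comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    GenomicInterval,
    IntervalSet,
    coverage_fn,
    count_overlapping,
    intersect,
    merge,
    overlap_bp,
)

__all__ = [
    "Workspace",
    "EnrichmentResult",
    "ComparisonTable",
    "randomize_in_workspace",
    "association_test",
    "build_control_sites",
    "compare_conditions",
    "spearman_rho",
    "results_to_frame",
]


class Workspace:
    """The disjoint region set within which randomization is permitted.

    Built by merging the supplied intervals (gap 0); exposes flat segment
    arrays used by the placement sampler.
    """

    def __init__(self, regions: IntervalSet):
        merged = merge(regions, gap=0)
        if len(merged) == 0:
            raise ValueError("workspace is empty")
        self.regions = merged
        chroms: List[str] = []
        seg_chrom: List[int] = []
        seg_start: List[int] = []
        seg_end: List[int] = []
        chrom_index: Dict[str, int] = {}
        for iv in merged:
            ci = chrom_index.setdefault(iv.chrom, len(chrom_index))
            if ci == len(chroms):
                chroms.append(iv.chrom)
            seg_chrom.append(ci)
            seg_start.append(iv.start)
            seg_end.append(iv.end)
        self.chrom_names: List[str] = chroms
        self.seg_chrom = np.asarray(seg_chrom, dtype=np.int32)
        self.seg_start = np.asarray(seg_start, dtype=np.int64)
        self.seg_end = np.asarray(seg_end, dtype=np.int64)
        self.seg_len = self.seg_end - self.seg_start
        self.total_bp = int(self.seg_len.sum())

    def legal_starts(self, length: int) -> Tuple[np.ndarray, int]:
        """Per-segment count of legal start positions for an interval of `length`."""
        w = np.maximum(self.seg_len - length + 1, 0)
        return w, int(w.sum())

    def __repr__(self) -> str:
        return f"Workspace(segments={len(self.seg_len)}, total_bp={self.total_bp})"


@dataclass
class EnrichmentResult:
    """Observed vs. null overlap for one (query, subject) pair."""

    query_label: str
    subject_label: str
    observed: float
    null_mean: float
    null_sd: float
    fold: float
    p_enrich: float
    p_deplete: float
    n_randomizations: int
    n_query: int
    n_subject: int
    undefined: bool = False


@dataclass
class ComparisonTable:
    """Per-TF paired enrichment in two conditions with a Spearman summary."""

    table: pd.DataFrame
    spearman: float
    n_ratio_above: int
    ratio_threshold: float


def _sample_placements(
    lengths: np.ndarray,
    workspace: Workspace,
    n_draws: int,
    rng: np.random.Generator,
) -> Tuple[Dict[int, Tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Sample uniform legal placements for each interval length, ``n_draws`` times.

    Returns ``{length: (chrom_idx, starts)}`` with arrays of shape
    ``(n_draws, n_intervals_of_that_length)``, plus a boolean mask over the
    input marking intervals that fit nowhere (excluded).
    """
    placements: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    excluded = np.zeros(len(lengths), dtype=bool)
    for length in np.unique(lengths):
        sel = lengths == length
        w, total = workspace.legal_starts(int(length))
        if total == 0:
            excluded[sel] = True
            continue
        m = int(sel.sum())
        cumw = np.cumsum(w)
        u = rng.integers(0, total, size=(n_draws, m))
        seg = np.searchsorted(cumw, u, side="right")
        offset = u - (cumw[seg] - w[seg])
        starts = workspace.seg_start[seg] + offset
        placements[int(length)] = (workspace.seg_chrom[seg], starts)
    return placements, excluded


def randomize_in_workspace(
    peaks: IntervalSet,
    workspace: Workspace,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[IntervalSet, int]:
    """Place each peak uniformly over all legal start positions in the workspace.

    Lengths are preserved; placements are independent, so randomized peaks may
    overlap one another.  Every legal start across all segments of sufficient
    length is equally likely (segment weight = segment_length - peak_length + 1).
    Peaks longer than every segment are skipped; the exclusion tally is
    returned alongside the randomized set.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lengths = np.array([len(iv) for iv in peaks], dtype=np.int64)
    placements, excluded = _sample_placements(lengths, workspace, 1, rng)
    if len(peaks) > 0 and excluded.all():
        raise ValueError("all peaks were longer than every workspace segment")
    out: List[GenomicInterval] = []
    cursor: Dict[int, int] = {}
    for iv, length, skip in zip(peaks, lengths, excluded):
        if skip:
            continue
        k = cursor.get(int(length), 0)
        cursor[int(length)] = k + 1
        ci, s = placements[int(length)]
        chrom = workspace.chrom_names[int(ci[0, k])]
        start = int(s[0, k])
        out.append(
            GenomicInterval(chrom, start, start + int(length), strand=iv.strand, name=iv.name)
        )
    return IntervalSet(out, label=peaks.label), int(excluded.sum())


def _null_statistics(
    placements: Dict[int, Tuple[np.ndarray, np.ndarray]],
    workspace: Workspace,
    subject: IntervalSet,
    n_draws: int,
    min_overlap: int,
    statistic: str,
) -> np.ndarray:
    """Per-draw overlap statistic of the randomized query against one subject."""
    union = {}
    for chrom, (s, e) in subject.by_chrom().items():
        cummax = np.maximum.accumulate(e)
        new_group = np.empty(len(s), dtype=bool)
        new_group[0] = True
        new_group[1:] = s[1:] > cummax[:-1]
        idx = np.flatnonzero(new_group)
        gid = np.cumsum(new_group) - 1
        me = np.zeros(len(idx), dtype=np.int64)
        np.maximum.at(me, gid, e)
        union[chrom] = (s[idx], me)
    f = coverage_fn(union)
    totals = np.zeros(n_draws, dtype=np.float64)
    chrom_ids = {name: i for i, name in enumerate(workspace.chrom_names)}
    for length, (ci, starts) in placements.items():
        ends = starts + length
        hit_or_bp = np.zeros(ci.shape, dtype=np.int64)
        for chrom, cid in chrom_ids.items():
            mask = ci == cid
            if not mask.any():
                continue
            bp = f(chrom, ends[mask]) - f(chrom, starts[mask])
            hit_or_bp[mask] = bp
        if statistic == "count":
            totals += (hit_or_bp >= min_overlap).sum(axis=1)
        else:  # bp
            totals += hit_or_bp.sum(axis=1)
    return totals


def association_test(
    query: IntervalSet,
    subjects: Sequence[IntervalSet],
    workspace: Workspace,
    n_randomizations: int = 1000,
    seed: Optional[int] = None,
    statistic: str = "count",
    min_overlap: int = 1,
) -> List[EnrichmentResult]:
    """Randomization enrichment of each subject peak set at the query sites.

    One null ensemble of ``n_randomizations`` workspace-randomized copies of
    the query is generated and reused for every subject.  For each subject:

    * ``observed`` - number of query intervals overlapping the subject
      (or total overlap bp when ``statistic="bp"``),
    * ``fold`` - observed / mean of the null ensemble,
    * ``p_enrich`` = (1 + #{null >= observed}) / (N + 1) (add-one rule;
      ``p_deplete`` analogous), so no empirical p is ever exactly zero.
    """
    if statistic not in ("count", "bp"):
        raise ValueError("statistic must be 'count' or 'bp'")
    if n_randomizations < 100:
        warnings.warn(
            f"n_randomizations={n_randomizations} < 100: empirical p-values are coarse",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    lengths = np.array([len(iv) for iv in query], dtype=np.int64)
    placements, excluded = _sample_placements(lengths, workspace, n_randomizations, rng)
    if len(query) > 0 and excluded.all():
        raise ValueError("all query intervals were longer than every workspace segment")
    n = n_randomizations
    results: List[EnrichmentResult] = []
    for subject in subjects:
        if len(subject) == 0:
            results.append(
                EnrichmentResult(
                    query.label, subject.label, 0.0, 0.0, 0.0, float("nan"),
                    1.0, 1.0, n, len(query), 0, undefined=True,
                )
            )
            continue
        if statistic == "count":
            observed = float(count_overlapping(query, subject, min_overlap=min_overlap))
        else:
            observed = float(overlap_bp(query, subject).sum())
        null = _null_statistics(placements, workspace, subject, n, min_overlap, statistic)
        null_mean = float(null.mean())
        null_sd = float(null.std(ddof=1)) if n > 1 else 0.0
        undefined = null_mean == 0.0
        fold = float("nan") if undefined else observed / null_mean
        p_enrich = (1.0 + float(np.count_nonzero(null >= observed))) / (n + 1.0)
        p_deplete = (1.0 + float(np.count_nonzero(null <= observed))) / (n + 1.0)
        results.append(
            EnrichmentResult(
                query.label, subject.label, observed, null_mean, null_sd, fold,
                p_enrich, p_deplete, n, len(query), len(subject), undefined=undefined,
            )
        )
    return results


def build_control_sites(
    oq: IntervalSet,
    promoters: IntervalSet,
    dhs: Workspace,
    g4: IntervalSet,
) -> IntervalSet:
    """Structure-free G-rich control sites.

    Keeps potential-G4 (OQ) intervals that lie in promoters of open chromatin
    but carry no detectable folded G4: overlap-select on promoters, then on
    the DHS workspace, then drop any interval touching a G4 peak (whole
    interval excluded on any contact).
    """
    in_promoter = [iv for iv, bp in zip(oq, overlap_bp(oq, promoters)) if bp >= 1]
    step1 = IntervalSet(in_promoter, label=oq.label)
    if len(step1) == 0:
        warnings.warn("no potential-G4 sites overlap promoters", stacklevel=2)
        return IntervalSet([], label=f"{oq.label}_control")
    in_dhs = [iv for iv, bp in zip(step1, overlap_bp(step1, dhs.regions)) if bp >= 1]
    step2 = IntervalSet(in_dhs, label=oq.label)
    if len(g4) == 0:
        kept = list(step2)
    else:
        kept = [iv for iv, bp in zip(step2, overlap_bp(step2, g4)) if bp == 0]
    return IntervalSet(kept, label=f"{oq.label}_control")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks.  Raises on constant input, for which the
    coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    return float(np.clip(np.mean(rx * ry), -1.0, 1.0))


def compare_conditions(
    results_a: Iterable[EnrichmentResult],
    results_b: Iterable[EnrichmentResult],
    ratio_threshold: float = 2.0,
) -> ComparisonTable:
    """Pair per-TF enrichments from two conditions.

    Replicate datasets of a TF are collapsed by taking the maximum fold within
    each condition.  Only TFs present in both conditions appear.  The summary
    Spearman coefficient is computed over the paired maxima, and the count of
    TFs with fold ratio A/B >= ``ratio_threshold`` is reported.
    """
    def collapse(results: Iterable[EnrichmentResult]) -> Dict[str, float]:
        best: Dict[str, float] = {}
        for r in results:
            if r.undefined or np.isnan(r.fold):
                continue
            label = r.subject_label
            if label not in best or r.fold > best[label]:
                best[label] = r.fold
        return best

    a = collapse(results_a)
    b = collapse(results_b)
    common = sorted(set(a) & set(b))
    if not common:
        raise ValueError("no TFs are present in both conditions")
    fold_a = np.array([a[t] for t in common])
    fold_b = np.array([b[t] for t in common])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fold_b > 0, fold_a / fold_b, np.inf)
    table = pd.DataFrame(
        {"tf": common, "fold_a": fold_a, "fold_b": fold_b, "ratio": ratio}
    ).set_index("tf")
    rho = spearman_rho(fold_a, fold_b) if len(common) >= 3 else float("nan")
    n_above = int(np.count_nonzero(ratio >= ratio_threshold))
    return ComparisonTable(table, rho, n_above, ratio_threshold)


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results, with an optional BH-adjusted column."""
    df = pd.DataFrame(
        {
            "query": [r.query_label for r in results],
            "subject": [r.subject_label for r in results],
            "observed": [r.observed for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "fold": [r.fold for r in results],
            "p_enrich": [r.p_enrich for r in results],
            "p_deplete": [r.p_deplete for r in results],
            "n_randomizations": [r.n_randomizations for r in results],
            "n_query": [r.n_query for r in results],
            "n_subject": [r.n_subject for r in results],
            "undefined": [r.undefined for r in results],
        }
    )
    return df


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (step-up), available as a post-hoc column."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.minimum(adj, 1.0)
    return out
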