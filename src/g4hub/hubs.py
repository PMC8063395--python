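"""TF co-occupancy at promoter G4s and its link to transcriptional output.

Promoters in open chromatin are split into those that contain a folded G4
peak and those that do not; for each gene the number of *distinct* TFs bound
is counted (on the G4 footprint for G4-positive promoters, on the whole
promoter window otherwise) and joined to expression (TPM).  The association
between occupancy class and expression is assessed with the Mann-Whitney
rank-sum test ("unpaired Wilcoxon").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import Workspace
from .intervals import GenomicInterval, IntervalSet, overlap_bp

__all__ = [
    "RankSumResult",
    "distinct_tf_count",
    "classify_promoters",
    "expression_by_count",
    "mann_whitney_u",
    "DEFAULT_COUNT_EDGES",
]

# Fig-style occupancy bins: 0, 1-10, 11-25, 26-50, 51-100, >100 bound TFs
DEFAULT_COUNT_EDGES: Tuple[float, ...] = (1, 11, 26, 51, 101)

EXACT_LIMIT = 12  # exact rank-sum enumeration up to this pooled sample size


@dataclass
class RankSumResult:
    """Mann-Whitney U with a two-sided p-value.

    ``method`` records whether the p came from exact enumeration of all
    rank assignments or the tie-corrected normal approximation.
    """

    u: float
    n1: int
    n2: int
    z: float
    p_two_sided: float
    method: str
    all_tied: bool = False


def distinct_tf_count(
    regions: IntervalSet, tf_sets: Sequence[IntervalSet]
) -> np.ndarray:
    """Per-region count of distinct TF labels with at least one overlapping peak.

    Replicate datasets sharing a label are collapsed (with a warning) so a TF
    mapped twice never counts twice.
    """
    by_label: Dict[str, List[IntervalSet]] = {}
    for ts in tf_sets:
        by_label.setdefault(ts.label, []).append(ts)
    dupes = [lab for lab, group in by_label.items() if len(group) > 1]
    if dupes:
        warnings.warn(f"collapsing replicate TF datasets for labels: {dupes}", stacklevel=2)
    counts = np.zeros(len(regions), dtype=np.int64)
    for label, group in by_label.items():
        pooled = group[0] if len(group) == 1 else IntervalSet(
            [iv for ts in group for iv in ts], label=label
        )
        counts += overlap_bp(regions, pooled) >= 1
    return counts


def classify_promoters(
    promoters: IntervalSet,
    dhs: Workspace,
    g4: IntervalSet,
    tf_sets: Sequence[IntervalSet],
    expression: Mapping[str, float],
    count_on: str = "g4",
) -> pd.DataFrame:
    """Build the per-gene table behind the hub/expression analysis.

    Restricts to DHS-positive promoters (>= 1 bp in open chromatin); a
    promoter is ``g4_positive`` iff it overlaps at least one G4 peak.  The
    distinct-TF count is taken on the G4 footprint inside the promoter for
    G4-positive genes and on the promoter window otherwise
    (``count_on="promoter"`` uses the promoter window for every gene).
    Genes missing from ``expression`` are excluded and counted in the
    ``n_missing_expression`` DataFrame attribute.
    """
    if count_on not in ("g4", "promoter"):
        raise ValueError("count_on must be 'g4' or 'promoter'")
    dhs_bp = overlap_bp(promoters, dhs.regions)
    dhs_pos = [iv for iv, bp in zip(promoters, dhs_bp) if bp >= 1]
    if not dhs_pos:
        raise ValueError("no DHS-positive promoters")
    kept: List[GenomicInterval] = []
    n_missing = 0
    for iv in dhs_pos:
        if iv.name in expression:
            kept.append(iv)
        else:
            n_missing += 1
    if not kept:
        raise ValueError("no DHS-positive promoter has expression data")
    prom = IntervalSet(kept, label="promoters_dhs")
    g4_hits = overlap_bp(prom, g4) >= 1 if len(g4) else np.zeros(len(prom), dtype=bool)

    # counting regions: the promoter-contained G4 footprint for G4+ genes
    count_regions: List[GenomicInterval] = []
    if count_on == "g4" and len(g4) > 0:
        g4_by_chrom = g4.by_chrom()
        for iv, has_g4 in zip(prom, g4_hits):
            if has_g4:
                gs, ge = g4_by_chrom[iv.chrom]
                lo = np.searchsorted(ge, iv.start, side="right")
                hi = np.searchsorted(gs, iv.end, side="left")
                s = int(min(max(gs[k], iv.start) for k in range(lo, hi)))
                e = int(max(min(ge[k], iv.end) for k in range(lo, hi)))
                count_regions.append(GenomicInterval(iv.chrom, s, e, name=iv.name))
            else:
                count_regions.append(iv)
    else:
        count_regions = list(prom)
    region_set = IntervalSet(count_regions)
    counts_by_gene = dict(
        zip((iv.name for iv in region_set), distinct_tf_count(region_set, tf_sets))
    )
    counts = np.array([counts_by_gene[iv.name] for iv in prom], dtype=np.int64)
    df = pd.DataFrame(
        {
            "gene_id": [iv.name for iv in prom],
            "chrom": [iv.chrom for iv in prom],
            "start": [iv.start for iv in prom],
            "end": [iv.end for iv in prom],
            "g4_positive": np.asarray(g4_hits, dtype=bool),
            "tf_count": counts,
            "tpm": [float(expression[iv.name]) for iv in prom],
        }
    )
    df.attrs["n_missing_expression"] = n_missing
    return df


def expression_by_count(
    table: pd.DataFrame,
    bin_edges: Sequence[float] = DEFAULT_COUNT_EDGES,
    pseudocount: float = 0.01,
    value_column: str = "tpm",
) -> pd.DataFrame:
    """Grouped log10-expression distributions per (G4 class x TF-count bin).

    ``bin_edges`` are the left edges of the occupancy bins above 0 (the 0-count
    bin is implicit); they must be strictly increasing.  For each group the
    case count, median and quartiles of ``log10(value + pseudocount)`` are
    returned; empty groups appear with ``n = 0``.  Substituting a signal
    column (e.g. polymerase occupancy) for TPM reuses the same path.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    full_edges = [-np.inf, *edges, np.inf]
    labels = []
    for lo, hi in zip(full_edges[:-1], full_edges[1:]):
        lo_i = 0 if lo == -np.inf else int(lo)
        labels.append(f">={lo_i}" if hi == np.inf else f"{lo_i}-{int(hi) - 1}")
    logv = np.log10(table[value_column].to_numpy(dtype=float) + pseudocount)
    binned = pd.cut(table["tf_count"], bins=full_edges, labels=labels, right=False)
    rows = []
    for g4_class in (False, True):
        for lab in labels:
            sel = (table["g4_positive"] == g4_class) & (binned == lab)
            vals = logv[np.asarray(sel)]
            rows.append(
                {
                    "g4_positive": g4_class,
                    "count_bin": lab,
                    "n": int(sel.sum()),
                    "median_log10": float(np.median(vals)) if len(vals) else np.nan,
                    "q1_log10": float(np.percentile(vals, 25)) if len(vals) else np.nan,
                    "q3_log10": float(np.percentile(vals, 75)) if len(vals) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _u_from_ranks(ranks: np.ndarray, n1: int) -> float:
    r1 = float(ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Mann-Whitney U ("unpaired Wilcoxon") with mid-ranks and tie correction.

    The U statistic is computed from mid-ranks.  When the pooled sample size
    is at most 12, the two-sided p comes from exact enumeration of all
    ``C(n1+n2, n1)`` group assignments of the pooled values (valid with ties);
    otherwise from the normal approximation with tie-corrected variance and a
    0.5 continuity correction.  If every value in both samples is identical,
    the test is degenerate: ``p = 1`` with ``all_tied`` set.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    u = _u_from_ranks(ranks, n1)
    if np.all(pooled == pooled[0]):
        return RankSumResult(u, n1, n2, 0.0, 1.0, "degenerate", all_tied=True)
    mu = n1 * n2 / 2.0
    if n <= EXACT_LIMIT:
        # permutation-exact distribution of U over all group labelings
        idx = range(n)
        deltas = []
        for comb in combinations(idx, n1):
            r1 = ranks[list(comb)].sum()
            deltas.append(abs((r1 - n1 * (n1 + 1) / 2.0) - mu))
        deltas = np.asarray(deltas)
        p = float(np.count_nonzero(deltas >= abs(u - mu) - 1e-9) / len(deltas))
        return RankSumResult(u, n1, n2, float("nan"), min(p, 1.0), "exact")
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankSumResult(u, n1, n2, 0.0, 1.0, "degenerate", all_tied=True)
    z = (u - mu - math.copysign(0.5, u - mu)) / math.sqrt(var) if u != mu else 0.0
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return RankSumResult(u, n1, n2, z, min(p, 1.0), "normal")
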