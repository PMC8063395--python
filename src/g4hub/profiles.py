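"""Strand-aware aggregate occupancy profiles around G4 anchors.

A :class:`SignalTrack` is a per-chromosome step function (bedGraph semantics).
:func:`metaprofile` averages the signal in fixed-width bins around anchor
centers; minus-strand anchors are mirrored before aggregation so that
"downstream of the G4" always points in the same direction in the profile
frame.  :func:`profile_max_offset` and :func:`count_centered` summarise where
a factor's occupancy peaks relative to the structure — the machinery behind
statements like "the TF profile is centered on the G4" or "shifted ~140 bp
downstream on the opposite strand" (the R-loop signature).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import BedParseError, GenomicInterval, IntervalSet, overlap_bp

__all__ = [
    "SignalTrack",
    "MetaProfile",
    "read_bedgraph",
    "write_bedgraph",
    "assign_g4_strand",
    "metaprofile",
    "profile_max_offset",
    "count_centered",
    "summit_offsets",
]


class SignalTrack:
    """A per-chromosome step function with 0-based half-open spans.

    Spans must be non-overlapping within a chromosome; uncovered positions
    have value 0.
    """

    def __init__(self, data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"empty or inverted span on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping spans on {chrom}")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite signal value on {chrom}")
            self._data[chrom] = (starts, ends, values)
        # integral of the step function up to each span start, for O(log n) queries
        self._cum: Dict[str, np.ndarray] = {
            chrom: np.concatenate(([0.0], np.cumsum((e - s) * v)))
            for chrom, (s, e, v) in self._data.items()
        }

    def chroms(self) -> List[str]:
        return list(self._data)

    def spans(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._data[chrom]

    def integral(self, chrom: str, x) -> np.ndarray:
        """Integral of the track over ``(-inf, x)`` (vectorised in x)."""
        x = np.asarray(x, dtype=np.int64)
        if chrom not in self._data:
            return np.zeros(x.shape, dtype=float)
        s, e, v = self._data[chrom]
        cum = self._cum[chrom]
        idx = np.searchsorted(s, x, side="right") - 1
        idx_c = np.clip(idx, 0, len(s) - 1)
        partial = np.clip(x - s[idx_c], 0, e[idx_c] - s[idx_c]) * v[idx_c]
        partial = np.where(idx < 0, 0.0, partial)
        base = np.where(idx < 0, 0.0, cum[idx_c])
        return base + partial

    def __add__(self, other: "SignalTrack") -> "SignalTrack":
        """Pointwise sum of two tracks (used by the linearity property)."""
        out: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in sorted(set(self.chroms()) | set(other.chroms())):
            edges: List[int] = []
            for t in (self, other):
                if chrom in t._data:
                    s, e, _ = t._data[chrom]
                    edges.extend(s.tolist())
                    edges.extend(e.tolist())
            grid = np.unique(np.asarray(edges, dtype=np.int64))
            starts, ends = grid[:-1], grid[1:]
            vals = np.zeros(len(starts), dtype=float)
            for t in (self, other):
                vals += (t.integral(chrom, ends) - t.integral(chrom, starts)) / (ends - starts)
            keep = vals != 0.0
            if keep.any():
                out[chrom] = (starts[keep], ends[keep], vals[keep])
        return SignalTrack(out)


@dataclass
class MetaProfile:
    """Binned, strand-oriented mean signal around anchor centers."""

    window: int
    bin_size: int
    offsets: np.ndarray  # bin midpoints in bp relative to anchor center
    mean_signal: np.ndarray
    n_anchors: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.n_anchors <= 0:
            raise ValueError("profile requires at least one usable anchor")


def read_bedgraph(path) -> SignalTrack:
    """Read a 4-column bedGraph file (chrom, start, end, value)."""
    data: Dict[str, Tuple[List[int], List[int], List[float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            col = data.setdefault(chrom, ([], [], []))
            col[0].append(s)
            col[1].append(e)
            col[2].append(v)
    return SignalTrack(
        {
            c: (np.asarray(s), np.asarray(e), np.asarray(v))
            for c, (s, e, v) in data.items()
        }
    )


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            starts, ends, values = track.spans(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{format(v, 'g')}\n")


def assign_g4_strand(
    g4: IntervalSet, oq_plus: IntervalSet, oq_minus: IntervalSet
) -> Tuple[IntervalSet, Dict[str, int]]:
    """Derive G4 strandedness from strand-split potential-G4 (OQ) maps.

    A G4 peak overlapping only plus-strand OQ sequence becomes "+", only
    minus-strand becomes "-", and both or neither stays ".".  Returns the
    restranded set and the per-class counts.
    """
    plus_bp = overlap_bp(g4, oq_plus) if len(oq_plus) else np.zeros(len(g4), dtype=int)
    minus_bp = overlap_bp(g4, oq_minus) if len(oq_minus) else np.zeros(len(g4), dtype=int)
    out: List[GenomicInterval] = []
    counts = {"+": 0, "-": 0, ".": 0}
    for iv, p, m in zip(g4, plus_bp, minus_bp):
        if p >= 1 and m < 1:
            strand = "+"
        elif m >= 1 and p < 1:
            strand = "-"
        else:
            strand = "."
        counts[strand] += 1
        out.append(GenomicInterval(iv.chrom, iv.start, iv.end, strand=strand,
                                   name=iv.name, score=iv.score))
    return IntervalSet(out, label=g4.label), counts


def metaprofile(
    track: SignalTrack,
    anchors: IntervalSet,
    window: int = 1000,
    bin_size: int = 10,
    strand_aware: bool = True,
    include_unstranded: bool = True,
    genome=None,
) -> MetaProfile:
    """Mean signal in ``bin_size`` bins over ``[center - window, center + window)``.

    The anchor center is the floor midpoint.  With ``strand_aware`` the bin
    vector of a minus-strand anchor is reversed before averaging, so positive
    offsets read "downstream of the anchored structure".  Unstranded (".")
    anchors are treated as plus-strand unless ``include_unstranded`` is False.
    Anchors whose window leaves the chromosome (coordinate < 0, or past the
    chromosome end when a genome table is given) are dropped and counted in
    ``n_dropped``; uncovered positions inside the chromosome contribute 0.
    """
    if len(anchors) == 0:
        raise ValueError("anchors must be non-empty")
    if window <= 0 or bin_size <= 0 or window % bin_size != 0:
        raise ValueError("window must be a positive multiple of bin_size")
    n_bins = 2 * window // bin_size
    edges_rel = np.arange(-window, window + bin_size, bin_size, dtype=np.int64)
    total = np.zeros(n_bins, dtype=float)
    n_used = 0
    n_dropped = 0
    for iv in anchors:
        if iv.strand == "." and not include_unstranded:
            n_dropped += 1
            continue
        center = iv.center
        edges = center + edges_rel
        if edges[0] < 0 or (genome is not None and edges[-1] > genome[iv.chrom]):
            n_dropped += 1
            continue
        vals = np.diff(track.integral(iv.chrom, edges)) / bin_size
        if strand_aware and iv.strand == "-":
            vals = vals[::-1]
        total += vals
        n_used += 1
    if n_used == 0:
        raise ValueError("all anchors were dropped")
    offsets = edges_rel[:-1] + bin_size // 2
    return MetaProfile(window, bin_size, offsets.astype(float),
                       total / n_used, n_used, n_dropped)


def profile_max_offset(profile: MetaProfile) -> Tuple[float, bool]:
    """Center offset (bp) of the bin with maximal mean signal.

    Ties are broken toward the offset closest to 0, then toward the negative
    one.  Returns ``(offset, is_flat)``; a flat profile yields ``(0.0, True)``.
    """
    sig = profile.mean_signal
    if np.allclose(sig, sig[0]):
        return 0.0, True
    maxima = np.flatnonzero(sig == sig.max())
    offs = profile.offsets[maxima]
    best = offs[np.lexsort((offs, np.abs(offs)))][0]
    return float(best), False


def count_centered(offsets: Sequence[float], threshold: float) -> int:
    """Number of offsets within +/- ``threshold`` bp of the anchor center."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    arr = np.asarray(list(offsets), dtype=float)
    if arr.size == 0:
        return 0
    return int(np.count_nonzero(np.abs(arr) <= threshold))


def summit_offsets(
    peaks: IntervalSet, anchors: IntervalSet, max_distance: Optional[int] = None
) -> np.ndarray:
    """Signed distance from each peak midpoint to the nearest anchor center.

    Strand-aware: distances to minus-strand anchors are negated so that
    positive always means "downstream of the structure".  An alternative to
    profile maxima for the "how centered is this TF" summary; peaks farther
    than ``max_distance`` from every anchor are omitted.
    """
    anchor_by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for iv in anchors:
        cs, ss = anchor_by_chrom.setdefault(iv.chrom, ([], []))  # type: ignore[assignment]
        cs.append(iv.center)
        ss.append(-1 if iv.strand == "-" else 1)
    anchor_by_chrom = {
        c: (np.asarray(cent, dtype=np.int64), np.asarray(sign, dtype=np.int64))
        for c, (cent, sign) in anchor_by_chrom.items()
    }
    out: List[float] = []
    for iv in peaks:
        if iv.chrom not in anchor_by_chrom:
            continue
        centers, signs = anchor_by_chrom[iv.chrom]
        mid = iv.center
        j = int(np.argmin(np.abs(centers - mid)))
        d = (mid - int(centers[j])) * int(signs[j])
        if max_distance is not None and abs(d) > max_distance:
            continue
        out.append(float(d))
    return np.asarray(out, dtype=float)
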