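"""Genomic coordinate model and exact interval algebra.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
The :class:`IntervalSet` container keeps its records sorted by
``(chrom, start, end)`` and exposes per-chromosome NumPy views so that the
set-algebra operations (:func:`merge`, :func:`subtract`, :func:`intersect`,
:func:`count_overlapping`) run as vectorised sweeps.  These primitives back
every downstream stage: randomization enrichment, control-site construction,
strand assignment, promoter classification and co-occupancy counting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GenomeTable",
    "TssRecord",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_genome_table",
    "write_genome_table",
    "read_tss_table",
    "write_tss_table",
    "merge",
    "subtract",
    "intersect",
    "count_overlapping",
    "overlap_bp",
    "promoter_intervals",
]


class BedParseError(ValueError):
    """Raised when a BED-like file contains a malformed line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span.

    Parameters
    ----------
    chrom : chromosome name, taken literally (no "chr1"/"1" aliasing).
    start, end : 0-based half-open coordinates, ``0 <= start < end``.
    strand : one of ``+``, ``-`` or ``.`` (unstranded).
    name, score : optional BED columns 4 and 5.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}; must be one of {STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Floor midpoint, the anchor used by profile aggregation."""
        return (self.start + self.end) // 2


class IntervalSet:
    """A labelled, sorted collection of :class:`GenomicInterval`.

    Sorted order by ``(chrom, start, end)`` is established on construction and
    maintained by every operation that returns a new set.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = ""):
        self.label = label
        self._intervals: List[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self._by_chrom_cache: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet(label={self.label!r}, n={len(self)})"

    # -- views ---------------------------------------------------------------
    def chroms(self) -> List[str]:
        seen: Dict[str, None] = {}
        for iv in self._intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome ``(starts, ends)`` int64 arrays, sorted by start."""
        if self._by_chrom_cache is None:
            out: Dict[str, Tuple[List[int], List[int]]] = {}
            for iv in self._intervals:
                s, e = out.setdefault(iv.chrom, ([], []))
                s.append(iv.start)
                e.append(iv.end)
            self._by_chrom_cache = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for c, (s, e) in out.items()
            }
        return self._by_chrom_cache

    def total_bp(self) -> int:
        """Sum of interval lengths (overlaps counted multiply)."""
        return sum(len(iv) for iv in self._intervals)

    def with_label(self, label: str) -> "IntervalSet":
        out = IntervalSet.__new__(IntervalSet)
        out.label = label
        out._intervals = self._intervals
        out._by_chrom_cache = self._by_chrom_cache
        return out

    def validate_against(self, genome: "GenomeTable") -> None:
        """Check every interval lies within the genome table bounds."""
        for iv in self._intervals:
            if iv.chrom not in genome:
                raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > genome[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                    f"length {genome[iv.chrom]}"
                )


class GenomeTable(dict):
    """Mapping chromosome name -> length in bp (all lengths > 0)."""

    def __init__(self, mapping: Mapping[str, int] = ()):
        super().__init__()
        for chrom, length in dict(mapping).items():
            self[chrom] = length

    def __setitem__(self, chrom: str, length: int) -> None:
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        super().__setitem__(str(chrom), length)


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site with optional expression level (TPM)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    tpm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("TSS position must be non-negative")
        if self.tpm is not None and self.tpm < 0:
            raise ValueError("TPM must be >= 0")


# ---------------------------------------------------------------------------
# I/O: BED3-BED6, genome table, TSS/expression table
# ---------------------------------------------------------------------------

def _fmt_score(score: float) -> str:
    return format(score, "g")


def read_bed(path, label: str = "") -> IntervalSet:
    """Read a whitespace-delimited BED3-BED6 file into a sorted IntervalSet.

    Columns 4-6 (name, score, strand) are used when present; a missing strand
    becomes ``"."``.  Malformed lines raise :class:`BedParseError` naming the
    line number.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad score {fields[4]!r}") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals, label=label)


def write_bed(intervals: IntervalSet, path) -> None:
    """Write BED3 or BED6 (6 columns whenever any record carries name/score/strand)."""
    six = any(iv.name is not None or iv.score is not None or iv.strand != "." for iv in intervals)
    buf = io.StringIO()
    for iv in intervals:
        if six:
            name = iv.name if iv.name is not None else "."
            score = _fmt_score(iv.score) if iv.score is not None else "0"
            buf.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
        else:
            buf.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_genome_table(path) -> GenomeTable:
    """Two-column (chrom, length) whitespace-delimited table."""
    table = GenomeTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            table[fields[0]] = int(fields[1])
    return table


def write_genome_table(genome: GenomeTable, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


def read_tss_table(path) -> List[TssRecord]:
    """Tab-separated TSS table: gene_id, chrom, tss, strand[, tpm]; header allowed."""
    records: List[TssRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene_id":  # header
                continue
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected >= 4 columns")
            tpm = float(fields[4]) if len(fields) > 4 and fields[4] != "" else None
            try:
                records.append(
                    TssRecord(fields[0], fields[1], int(fields[2]), fields[3], tpm=tpm)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_tss_table(records: Sequence[TssRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\ttpm\n")
        for r in records:
            tpm = "" if r.tpm is None else format(r.tpm, ".6g")
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.tss}\t{r.strand}\t{tpm}\n")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def _merged_arrays(ivset: IntervalSet, gap: int = 0) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome disjoint union arrays after fusing intervals within `gap`."""
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (starts, ends) in ivset.by_chrom().items():
        if len(starts) == 0:
            continue
        # starts already sorted; compute running max of ends
        cummax = np.maximum.accumulate(ends)
        new_group = np.empty(len(starts), dtype=bool)
        new_group[0] = True
        new_group[1:] = starts[1:] > cummax[:-1] + gap
        idx = np.flatnonzero(new_group)
        merged_starts = starts[idx]
        group_id = np.cumsum(new_group) - 1
        merged_ends = np.zeros(len(idx), dtype=np.int64)
        np.maximum.at(merged_ends, group_id, ends)
        out[chrom] = (merged_starts, merged_ends)
    return out


def _arrays_to_set(arrays: Dict[str, Tuple[np.ndarray, np.ndarray]], label: str) -> IntervalSet:
    intervals = [
        GenomicInterval(chrom, int(s), int(e))
        for chrom in sorted(arrays)
        for s, e in zip(*arrays[chrom])
    ]
    return IntervalSet(intervals, label=label)


def merge(ivset: IntervalSet, gap: int = 0) -> IntervalSet:
    """Fuse same-chromosome intervals separated by <= ``gap`` bp.

    The result is a disjoint footprint; name/score/strand are dropped.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    return _arrays_to_set(_merged_arrays(ivset, gap), ivset.label)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Portions of ``a`` not covered by ``b`` (fragments keep a's annotation)."""
    b_merged = _merged_arrays(b)
    out: List[GenomicInterval] = []
    for iv in a:
        pieces = b_merged.get(iv.chrom)
        if pieces is None:
            out.append(iv)
            continue
        bs, be = pieces
        lo = int(np.searchsorted(be, iv.start, side="right"))
        hi = int(np.searchsorted(bs, iv.end, side="left"))
        cursor = iv.start
        emitted = False
        for k in range(lo, hi):
            if bs[k] > cursor:
                out.append(replace(iv, start=cursor, end=int(bs[k])))
                emitted = True
            cursor = max(cursor, int(be[k]))
        if cursor < iv.end:
            out.append(replace(iv, start=cursor, end=iv.end))
            emitted = True
        del emitted
    return IntervalSet(out, label=a.label)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Portions of ``a`` covered by the union of ``b``."""
    b_merged = _merged_arrays(b)
    out: List[GenomicInterval] = []
    for iv in a:
        pieces = b_merged.get(iv.chrom)
        if pieces is None:
            continue
        bs, be = pieces
        lo = int(np.searchsorted(be, iv.start, side="right"))
        hi = int(np.searchsorted(bs, iv.end, side="left"))
        for k in range(lo, hi):
            s = max(iv.start, int(bs[k]))
            e = min(iv.end, int(be[k]))
            if s < e:
                out.append(replace(iv, start=s, end=e))
    return IntervalSet(out, label=a.label)


def coverage_fn(union: Dict[str, Tuple[np.ndarray, np.ndarray]]):
    """Return ``f(chrom, x)`` = union bp strictly left of coordinate ``x``.

    ``x`` may be a NumPy array.  The union must be disjoint and sorted.
    """
    cum: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, (s, e) in union.items():
        lens = e - s
        csum = np.concatenate(([0], np.cumsum(lens)))
        cum[chrom] = (s, e, lens, csum)

    def f(chrom: str, x):
        x = np.asarray(x, dtype=np.int64)
        if chrom not in cum:
            return np.zeros(x.shape, dtype=np.int64)
        s, e, lens, csum = cum[chrom]
        idx = np.searchsorted(s, x, side="right") - 1
        idx_c = np.clip(idx, 0, len(s) - 1)
        partial = np.clip(x - s[idx_c], 0, lens[idx_c])
        partial = np.where(idx < 0, 0, partial)
        base = csum[np.clip(idx, 0, len(s) - 1)]
        base = np.where(idx < 0, 0, base)
        return base + partial

    return f


def overlap_bp(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Per-query-interval bp of intersection with the subject union."""
    union = _merged_arrays(subject)
    f = coverage_fn(union)
    out = np.zeros(len(query), dtype=np.int64)
    by_chrom: Dict[str, Tuple[List[int], List[int], List[int]]] = {}
    for i, iv in enumerate(query):
        idxs, ss, es = by_chrom.setdefault(iv.chrom, ([], [], []))
        idxs.append(i)
        ss.append(iv.start)
        es.append(iv.end)
    for chrom, (idxs, ss, es) in by_chrom.items():
        s = np.asarray(ss, dtype=np.int64)
        e = np.asarray(es, dtype=np.int64)
        out[np.asarray(idxs)] = f(chrom, e) - f(chrom, s)
    return out


def count_overlapping(query: IntervalSet, subject: IntervalSet, min_overlap: int = 1) -> int:
    """Number of query intervals with >= ``min_overlap`` bp of subject-union overlap.

    Each query interval is counted at most once regardless of how many subject
    intervals it touches.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if len(query) == 0 or len(subject) == 0:
        return 0
    return int(np.count_nonzero(overlap_bp(query, subject) >= min_overlap))


def promoter_intervals(
    tss_table: Sequence[TssRecord],
    genome: GenomeTable,
    upstream: int = 1000,
    downstream: int = 0,
) -> IntervalSet:
    """Fixed windows upstream of each TSS, strand-mirrored and clipped.

    For a "+" gene the window is ``[tss - upstream, tss + downstream)``;
    for a "-" gene the mirror ``[tss - downstream, tss + upstream)``.
    Windows falling entirely outside the chromosome are excluded; the count of
    exclusions is available on the returned set as ``n_excluded``.
    """
    if upstream <= 0:
        raise ValueError("upstream must be > 0")
    if downstream < 0:
        raise ValueError("downstream must be >= 0")
    out: List[GenomicInterval] = []
    n_excluded = 0
    for rec in tss_table:
        length = genome[rec.chrom]
        if rec.strand == "+":
            start, end = rec.tss - upstream, rec.tss + downstream
        else:
            start, end = rec.tss - downstream, rec.tss + upstream
        start, end = max(0, start), min(length, end)
        if start >= end:
            n_excluded += 1
            continue
        out.append(GenomicInterval(rec.chrom, start, end, strand=rec.strand, name=rec.gene_id))
    result = IntervalSet(out, label="promoters")
    result.n_excluded = n_excluded  # type: ignore[attr-defined]
    return result
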