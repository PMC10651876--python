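"""Genomic interval primitives, the overlap/merge engine, and flat-file I/O.

All coordinates are 0-based half-open (BED convention). GTF input, which is
1-based closed, is converted on read. Strand is metadata: it determines TSS
placement and element naming but never participates in overlap arithmetic,
because ChIP/ATAC peaks are unstranded.

The merge/assignment primitive (:func:`merge_assign_bitmask`) is the hot path
of the co-binding randomization null and is fully vectorized: a single lexsort
followed by a running-maximum sweep and ``bitwise_or.reduceat``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "IntervalSet",
    "PeakCollection",
    "GeneModel",
    "read_intervals",
    "overlap_pairs",
    "merge",
    "merge_assign_bitmask",
    "promoter_window",
]

_VALID_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """A standard-format file failed to parse."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and their lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name in self.chrom_names:
            if name not in self.chrom_lengths:
                raise ValueError(f"no length for chromosome {name!r}")
            if self.chrom_lengths[name] <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}")

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chrom_names)

    def write_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in self.chrom_names:
                fh.write(f"{name}\t{self.chrom_lengths[name]}\n")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic range."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """A collection of intervals held as parallel numpy arrays.

    Optionally carries per-interval scores, a label and a genome layout.
    ``sources`` (set by :func:`merge`) records, per interval, which input set
    names contributed to it.
    """

    def __init__(
        self,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        scores: Sequence[float] | None = None,
        strands: Sequence[str] | None = None,
        name: str = "",
        layout: GenomeLayout | None = None,
        sources: list[tuple[str, ...]] | None = None,
    ):
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms/starts/ends length mismatch")
        if np.any(self.starts < 0) or np.any(self.starts >= self.ends):
            bad = int(np.flatnonzero((self.starts < 0) | (self.starts >= self.ends))[0])
            raise ValueError(
                f"invalid interval at row {bad}: "
                f"{self.chroms[bad]}:{self.starts[bad]}-{self.ends[bad]}"
            )
        self.scores = None if scores is None else np.asarray(scores, dtype=float)
        self.strands = None if strands is None else np.asarray(strands, dtype=object)
        self.name = name
        self.layout = layout
        self.sources = sources
        if layout is not None:
            self._check_bounds(layout)

    def _check_bounds(self, layout: GenomeLayout) -> None:
        for chrom in np.unique(self.chroms):
            if chrom not in layout.chrom_lengths:
                raise ValueError(f"chromosome {chrom!r} absent from layout")
            mask = self.chroms == chrom
            if np.any(self.ends[mask] > layout.chrom_lengths[chrom]):
                raise ValueError(f"interval beyond end of chromosome {chrom!r}")

    @classmethod
    def from_intervals(
        cls, intervals: Sequence[GenomicInterval], name: str = "", layout=None
    ) -> "IntervalSet":
        return cls(
            [iv.chrom for iv in intervals],
            [iv.start for iv in intervals],
            [iv.end for iv in intervals],
            strands=[iv.strand for iv in intervals] or None,
            name=name,
            layout=layout,
        )

    def __len__(self) -> int:
        return len(self.starts)

    def __getitem__(self, i: int) -> GenomicInterval:
        strand = "." if self.strands is None else self.strands[i]
        return GenomicInterval(self.chroms[i], int(self.starts[i]), int(self.ends[i]), strand)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for i in range(len(self)):
            yield self[i]

    def sorted(self) -> "IntervalSet":
        order = np.lexsort((self.starts, self.chroms))
        return self.take(order)

    def take(self, idx) -> "IntervalSet":
        idx = np.asarray(idx)
        return IntervalSet(
            self.chroms[idx],
            self.starts[idx],
            self.ends[idx],
            None if self.scores is None else self.scores[idx],
            None if self.strands is None else self.strands[idx],
            name=self.name,
            layout=self.layout,
            sources=None if self.sources is None else [self.sources[int(i)] for i in idx],
        )

    def total_bp(self) -> int:
        return int(np.sum(self.ends - self.starts))

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({"chrom": self.chroms, "start": self.starts, "end": self.ends})
        if self.scores is not None:
            df["score"] = self.scores
        if self.strands is not None:
            df["strand"] = self.strands
        return df

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i in range(len(self)):
                fields = [str(self.chroms[i]), str(int(self.starts[i])), str(int(self.ends[i]))]
                if self.scores is not None or self.strands is not None:
                    score = 0.0 if self.scores is None else float(self.scores[i])
                    strand = "." if self.strands is None else str(self.strands[i])
                    fields += [f"{self.name or 'region'}_{i}", f"{score:g}", strand]
                fh.write("\t".join(fields) + "\n")

    def overlaps_point_set(self, other: "IntervalSet", min_bp: int = 1) -> np.ndarray:
        """Boolean mask: which intervals of *self* overlap any interval of *other*."""
        hit = np.zeros(len(self), dtype=bool)
        if len(self) == 0 or len(other) == 0:
            return hit
        for ia, ib in overlap_pairs(self, other, min_bp=min_bp):
            hit[ia] = True
        return hit


@dataclass
class PeakCollection:
    """ChIP peak calls for one factor in one cell type."""

    factor: str
    cell_type: str
    peaks: IntervalSet

    def __post_init__(self) -> None:
        if self.peaks.layout is not None:
            self.peaks._check_bounds(self.peaks.layout)


@dataclass(frozen=True)
class GeneModel:
    """A gene body plus the derived TSS coordinate."""

    gene_id: str
    gene_name: str
    tss: int
    strand: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("gene strand must be + or -")
        expect = self.body.start if self.strand == "+" else self.body.end - 1
        if self.tss != expect:
            raise ValueError(f"TSS {self.tss} inconsistent with body/strand for {self.gene_id}")

    @classmethod
    def from_body(cls, gene_id: str, gene_name: str, body: GenomicInterval, strand: str):
        tss = body.start if strand == "+" else body.end - 1
        return cls(gene_id, gene_name, tss, strand, body)


def promoter_window(
    gene: GeneModel, upstream_bp: int = 10_000, downstream_bp: int = 2_000
) -> GenomicInterval:
    """Promoter window around the TSS, oriented by gene strand.

    Upstream extends against the direction of transcription; the window always
    contains the TSS base itself.
    """
    if gene.strand == "+":
        start = gene.tss - upstream_bp
        end = gene.tss + max(downstream_bp, 1)
    else:
        start = gene.tss - max(downstream_bp, 1) + 1
        end = gene.tss + upstream_bp + 1
    return GenomicInterval(gene.body.chrom, max(0, start), max(1, end), gene.strand)


# ---------------------------------------------------------------------------
# Readers


def _parse_bed_line(fields, lineno, path, min_cols):
    if len(fields) < min_cols:
        raise FormatError(f"{path}:{lineno}: expected >= {min_cols} columns, got {len(fields)}")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
    if start >= end or start < 0:
        raise FormatError(f"{path}:{lineno}: invalid coordinates {start}>={end}")
    return fields[0], start, end


def _read_bedlike(path, min_cols, score_col=None, strand_col=None, name=""):
    chroms, starts, ends, scores, strands = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = _parse_bed_line(fields, lineno, path, min_cols)
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            if score_col is not None and len(fields) > score_col:
                try:
                    scores.append(float(fields[score_col]))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            if strand_col is not None and len(fields) > strand_col:
                strands.append(fields[strand_col] if fields[strand_col] in _VALID_STRANDS else ".")
    return IntervalSet(
        chroms,
        starts,
        ends,
        scores if len(scores) == len(chroms) else None,
        strands if len(strands) == len(chroms) else None,
        name=name or Path(path).stem,
    )


_GTF_ATTR = None  # compiled lazily


def _gtf_attr(attrs: str, key: str) -> str | None:
    import re

    m = re.search(rf'{key} "([^"]+)"', attrs)
    return m.group(1) if m else None


def _read_gtf_genes(path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start1 > end1 or start1 < 1:
                raise FormatError(f"{path}:{lineno}: invalid GTF coordinates")
            strand = fields[6]
            if strand not in {"+", "-"}:
                raise FormatError(f"{path}:{lineno}: gene strand must be + or -")
            gene_id = _gtf_attr(fields[8], "gene_id") or f"gene_line{lineno}"
            gene_name = _gtf_attr(fields[8], "gene_name") or gene_id
            body = GenomicInterval(fields[0], start1 - 1, end1, strand)
            genes.append(GeneModel.from_body(gene_id, gene_name, body, strand))
    return genes


def _read_chrom_sizes(path) -> GenomeLayout:
    names, lengths = [], {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'name<TAB>length'")
            try:
                lengths[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer length") from exc
            names.append(fields[0])
    return GenomeLayout(tuple(names), lengths)


def read_intervals(path: str | Path, format: str):
    """Read a standard region file.

    ``format`` is one of ``bed``, ``narrowPeak``, ``chrom.sizes``, ``gtf``.
    Returns an :class:`IntervalSet`, a list of :class:`GeneModel` (gtf), or a
    :class:`GenomeLayout` (chrom.sizes).
    """
    if format == "bed":
        return _read_bedlike(path, min_cols=3, score_col=4, strand_col=5)
    if format == "narrowPeak":
        # 10-column ENCODE narrowPeak; signalValue (col 7) kept as the score
        return _read_bedlike(path, min_cols=10, score_col=6, strand_col=5)
    if format == "chrom.sizes":
        return _read_chrom_sizes(path)
    if format == "gtf":
        return _read_gtf_genes(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Overlap / merge engine


def overlap_pairs(a: IntervalSet, b: IntervalSet, min_bp: int = 1) -> list[tuple[int, int]]:
    """All (index_a, index_b) pairs whose intersection is >= ``min_bp`` bp.

    Vectorized per chromosome over the smaller axis; intended for the
    moderate set sizes of this pipeline (the co-binding null uses the
    dedicated :func:`merge_assign_bitmask` engine instead).
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    pairs: list[tuple[int, int]] = []
    if len(a) == 0 or len(b) == 0:
        return pairs
    chroms = set(np.unique(a.chroms)) & set(np.unique(b.chroms))
    for chrom in sorted(chroms):
        ia = np.flatnonzero(a.chroms == chrom)
        ib = np.flatnonzero(b.chroms == chrom)
        bs, be = b.starts[ib], b.ends[ib]
        for i in ia:
            inter = np.minimum(a.ends[i], be) - np.maximum(a.starts[i], bs)
            for j in np.flatnonzero(inter >= min_bp):
                pairs.append((int(i), int(ib[j])))
    pairs.sort()
    return pairs


def merge_assign_bitmask(
    chrom_codes: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    bits: np.ndarray,
    span_guard: int | None = None,
):
    """Merge intervals into maximal non-overlapping regions and OR their bits.

    Parameters are parallel arrays; ``bits`` carries one integer bit flag per
    interval (e.g. ``1 << factor_index``). Returns
    ``(region_chrom_codes, region_starts, region_ends, region_masks)``.
    Book-ended intervals are merged (regions are maximal contiguous coverage
    runs, the bedtools-merge convention); overlap *tests* elsewhere remain
    strictly half-open.
    """
    n = len(starts)
    if n == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty, empty
    if span_guard is None:
        span_guard = int(ends.max()) + 1
    order = np.lexsort((starts, chrom_codes))
    cc = chrom_codes[order]
    ss = starts[order]
    ee = ends[order]
    bb = bits[order]
    gstart = ss + cc.astype(np.int64) * span_guard
    gend = ee + cc.astype(np.int64) * span_guard
    run_end = np.maximum.accumulate(gend)
    breaks = np.empty(n, dtype=bool)
    breaks[0] = True
    breaks[1:] = gstart[1:] > run_end[:-1]
    first = np.flatnonzero(breaks)
    region_masks = np.bitwise_or.reduceat(bb, first)
    region_starts = ss[first]
    region_ends = np.maximum.reduceat(ee, first)
    region_chroms = cc[first]
    return region_chroms, region_starts, region_ends, region_masks


def merge(*sets: IntervalSet) -> IntervalSet:
    """Union of one or more interval sets into non-overlapping sorted regions.

    The covered bp are preserved exactly and each merged region records which
    input set names contributed to it (``sources``).
    """
    if not sets:
        raise ValueError("merge requires at least one IntervalSet")
    names = [s.name or f"set{i}" for i, s in enumerate(sets)]
    chrom_names = sorted({c for s in sets for c in np.unique(s.chroms)})
    code_of = {c: i for i, c in enumerate(chrom_names)}
    chroms = np.concatenate([s.chroms for s in sets]) if sets else np.empty(0, object)
    starts = np.concatenate([s.starts for s in sets])
    ends = np.concatenate([s.ends for s in sets])
    bits = np.concatenate(
        [np.full(len(s), 1 << i, dtype=np.int64) for i, s in enumerate(sets)]
    )
    codes = np.array([code_of[c] for c in chroms], dtype=np.int64)
    rc, rs, re_, masks = merge_assign_bitmask(codes, starts, ends, bits)
    sources = [
        tuple(names[i] for i in range(len(sets)) if mask >> i & 1) for mask in masks
    ]
    layout = next((s.layout for s in sets if s.layout is not None), None)
    return IntervalSet(
        np.array([chrom_names[c] for c in rc], dtype=object),
        rs,
        re_,
        name="+".join(dict.fromkeys(names)),
        layout=layout,
        sources=sources,
    )
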