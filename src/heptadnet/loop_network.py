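"""Promoter-enhancer network construction from significance-annotated loops.

Pipeline per cell type: keep loops at FDR <= threshold (inclusive boundary,
as printed), classify each anchor as promoter (overlaps a strand-oriented
TSS window) or enhancer, gate promoter-enhancer loops on the presence of an
accessible (ATAC) region at the distal anchor, and assemble per-gene element
tables with kb-offset element names (e.g. ERG+85 = 85 kb downstream of the
ERG TSS along the direction of transcription).

Region->gene linking for differential-region sets: direct when the region
overlaps the promoter window, indirect when it sits on one anchor of a
significant loop whose other anchor overlaps the promoter window.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core_intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    PeakCollection,
    promoter_window,
)

__all__ = [
    "Loop",
    "AnchorAnnotation",
    "RegulatoryElement",
    "GeneNetwork",
    "read_bedpe",
    "write_bedpe",
    "filter_loops",
    "classify_anchors",
    "gate_by_atac",
    "name_element",
    "build_gene_network",
    "link_regions_to_genes",
]


@dataclass(frozen=True)
class Loop:
    """A chromatin interaction between two anchors with a loop-call q-value."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    q_value: float
    contact_count: int | None = None

    def __post_init__(self) -> None:
        if self.q_value is None or math.isnan(self.q_value):
            raise ValueError("loop missing q_value")
        if not 0 <= self.q_value <= 1:
            raise ValueError(f"q_value {self.q_value} outside [0, 1]")


@dataclass(frozen=True)
class AnchorAnnotation:
    """Per-loop promoter/enhancer call: class in {P-P, P-E, E-E}."""

    loop_class: str
    genes_a: tuple[str, ...]
    genes_b: tuple[str, ...]
    distal: str | None  # "a" or "b" for P-E loops, else None

    @property
    def distal_anchor_of(self):
        return self.distal


def read_bedpe(path: str | Path, q_col: int = 8) -> list[Loop]:
    """Read loops from BEDPE: 6 coordinate columns, then name, score/contact
    count, q-value (the layout :func:`write_bedpe` emits). ``q_col`` is the
    0-based q-value column index for other dialects."""
    loops: list[Loop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) <= q_col:
                raise ValueError(f"{path}:{lineno}: expected > {q_col} columns")
            try:
                a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
                q = float(fields[q_col])
                contact = int(float(fields[7])) if len(fields) > 7 and q_col != 7 else None
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BEDPE record") from exc
            loops.append(Loop(a, b, q, contact))
    return loops


def write_bedpe(loops: list[Loop], path: str | Path, name_prefix: str = "loop") -> None:
    with open(path, "w") as fh:
        for i, lp in enumerate(loops):
            fh.write(
                "\t".join(
                    [
                        lp.anchor_a.chrom, str(lp.anchor_a.start), str(lp.anchor_a.end),
                        lp.anchor_b.chrom, str(lp.anchor_b.start), str(lp.anchor_b.end),
                        f"{name_prefix}_{i}", str(lp.contact_count or 0),
                        f"{lp.q_value:.6g}",
                    ]
                )
                + "\n"
            )


def write_interact(loops: list[Loop], path: str | Path, name_prefix: str = "loop") -> None:
    """UCSC interact track for browser display of the loop set."""
    with open(path, "w") as fh:
        fh.write('track type=interact name="loops" useScore=on\n')
        for i, lp in enumerate(loops):
            a, b = lp.anchor_a, lp.anchor_b
            start = min(a.start, b.start)
            end = max(a.end, b.end)
            score = int(min(1000, max(0, -10 * math.log10(max(lp.q_value, 1e-100)))))
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        a.chrom, start, end, f"{name_prefix}_{i}", score, lp.q_value,
                        ".", "0", a.chrom, a.start, a.end, ".", ".",
                        b.chrom, b.start, b.end, ".", ".",
                    ]
                )
                + "\n"
            )


def filter_loops(loops: list[Loop], fdr_max: float) -> list[Loop]:
    """Keep loops with q_value <= fdr_max (inclusive), preserving order."""
    if not 0 < fdr_max <= 1:
        raise ValueError("fdr_max must be in (0, 1]")
    return [lp for lp in loops if lp.q_value <= fdr_max]


def _promoter_hits(anchor: GenomicInterval, windows: list[tuple[GenomicInterval, str]]):
    return tuple(
        gname for win, gname in windows
        if win.chrom == anchor.chrom and anchor.start < win.end and anchor.end > win.start
    )


def classify_anchors(
    loops: list[Loop],
    genes: list[GeneModel],
    promoter_upstream_bp: int = 10_000,
    promoter_downstream_bp: int = 2_000,
) -> list[AnchorAnnotation]:
    """Per-loop anchor classification into P-P / P-E / E-E.

    An anchor is a promoter anchor iff it overlaps the strand-oriented TSS
    window of any gene; P-E loops record which anchor is the distal one.
    """
    if not genes:
        raise ValueError("empty gene list")
    if promoter_upstream_bp < 0 or promoter_downstream_bp < 0:
        raise ValueError("promoter windows must be >= 0")
    windows = [
        (promoter_window(g, promoter_upstream_bp, promoter_downstream_bp), g.gene_name)
        for g in genes
    ]
    out = []
    for lp in loops:
        ga = _promoter_hits(lp.anchor_a, windows)
        gb = _promoter_hits(lp.anchor_b, windows)
        if ga and gb:
            cls, distal = "P-P", None
        elif ga or gb:
            cls, distal = "P-E", ("b" if ga else "a")
        else:
            cls, distal = "E-E", None
        out.append(AnchorAnnotation(cls, ga, gb, distal))
    return out


def gate_by_atac(
    pe_loops: list[Loop],
    annotations: list[AnchorAnnotation],
    atac: IntervalSet,
    min_bp: int = 1,
) -> list[Loop]:
    """Keep P-E loops whose distal anchor overlaps >= 1 accessible region."""
    if len(pe_loops) != len(annotations):
        raise ValueError("loops and annotations length mismatch")
    kept = []
    for lp, ann in zip(pe_loops, annotations):
        if ann.loop_class != "P-E":
            continue
        distal = lp.anchor_a if ann.distal == "a" else lp.anchor_b
        inter = np.minimum(atac.ends, distal.end) - np.maximum(atac.starts, distal.start)
        hit = np.any((atac.chroms == distal.chrom) & (inter >= min_bp))
        if hit:
            kept.append(lp)
    return kept


def name_element(
    element: GenomicInterval, gene: GeneModel, sub_kb: bool = False
) -> str:
    """kb-offset element id relative to the gene TSS, downstream positive.

    Offsets round half away from zero to the nearest kb; with ``sub_kb`` the
    offset is rendered with one decimal (e.g. TAL1+0.5).
    """
    offset_bp = element.midpoint - gene.tss
    if gene.strand == "-":
        offset_bp = -offset_bp
    if sub_kb:
        kb = offset_bp / 1000
        sign = "+" if kb >= 0 else "-"
        return f"{gene.gene_name}{sign}{abs(kb):.1f}"
    kb = int(math.floor(abs(offset_bp) / 1000 + 0.5)) * (1 if offset_bp >= 0 else -1)
    sign = "+" if kb >= 0 else "-"
    return f"{gene.gene_name}{sign}{abs(kb)}"


@dataclass
class RegulatoryElement:
    interval: GenomicInterval
    element_id: str
    kind: str  # promoter | enhancer
    bound_factors: dict[str, tuple[str, ...]] = field(default_factory=dict)  # cell -> factors
    looped: dict[str, bool] = field(default_factory=dict)  # cell -> direct link to promoter
    direct: bool = True  # False for elements reached only via E-E loops


@dataclass
class GeneNetwork:
    """Per-gene element x cell-type connectivity map (the dot-plot table)."""

    gene: GeneModel
    elements: list[RegulatoryElement]
    edges: dict[str, list[tuple[str, str]]]  # cell -> (element_id, element_id)

    def to_table(self) -> pd.DataFrame:
        cells = sorted(self.edges)
        rows = []
        for el in self.elements:
            row = {
                "element_id": el.element_id,
                "chrom": el.interval.chrom,
                "start": el.interval.start,
                "end": el.interval.end,
                "kind": el.kind,
                "direct": el.direct,
            }
            for cell in cells:
                row[f"n_factors_{cell}"] = len(el.bound_factors.get(cell, ()))
                row[f"looped_{cell}"] = bool(el.looped.get(cell, False))
            rows.append(row)
        return pd.DataFrame(rows)


def _overlapping_factors(
    interval: GenomicInterval, collections: list[PeakCollection]
) -> tuple[str, ...]:
    bound = []
    for col in collections:
        p = col.peaks
        inter = np.minimum(p.ends, interval.end) - np.maximum(p.starts, interval.start)
        if np.any((p.chroms == interval.chrom) & (inter >= 1)):
            bound.append(col.factor)
    return tuple(bound)


def build_gene_network(
    gene_name: str,
    genes: list[GeneModel],
    loops_by_cell: dict[str, list[Loop]],
    peaks_by_cell: dict[str, list[PeakCollection]],
    atac_by_cell: dict[str, IntervalSet],
    fdr_max: float = 0.01,
    promoter_upstream_bp: int = 10_000,
    promoter_downstream_bp: int = 2_000,
    sub_kb: bool = False,
) -> GeneNetwork:
    """Assemble the regulatory network of one gene across cell types.

    Elements are the promoter window, the distal anchors of ATAC-gated P-E
    loops of any cell type, and (flagged indirect) anchors reachable from
    those by one E-E loop. Per element and cell type the table records how
    many factors have a peak there and whether the element is directly looped
    to the promoter in that cell type.
    """
    matches = [g for g in genes if g.gene_name == gene_name or g.gene_id == gene_name]
    if not matches:
        raise ValueError(f"gene {gene_name!r} absent from gene models")
    gene = matches[0]
    prom_win = promoter_window(gene, promoter_upstream_bp, promoter_downstream_bp)

    # collect per-cell direct distal anchors and E-E expansions (depth 1)
    direct_anchors: dict[str, list[tuple[str, GenomicInterval]]] = {}
    indirect_anchors: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for cell, loops in loops_by_cell.items():
        sig = filter_loops(loops, fdr_max)
        anns = classify_anchors(sig, genes, promoter_upstream_bp, promoter_downstream_bp)
        gated = gate_by_atac(sig, anns, atac_by_cell[cell])
        gated_set = {id(lp) for lp in gated}
        cell_direct = []
        for lp, ann in zip(sig, anns):
            if ann.loop_class != "P-E" or id(lp) not in gated_set:
                continue
            prom_genes = ann.genes_a if ann.distal == "b" else ann.genes_b
            if gene.gene_name not in prom_genes:
                continue
            distal = lp.anchor_a if ann.distal == "a" else lp.anchor_b
            cell_direct.append(distal)
        direct_anchors[cell] = [("enhancer", iv) for iv in cell_direct]
        # one-step E-E reachability from the direct anchors
        reached = []
        for lp, ann in zip(sig, anns):
            if ann.loop_class != "E-E":
                continue
            for iv in cell_direct:
                if lp.anchor_a.overlap_bp(iv) >= 1 and lp.anchor_b.overlap_bp(iv) < 1:
                    reached.append(lp.anchor_b)
                elif lp.anchor_b.overlap_bp(iv) >= 1 and lp.anchor_a.overlap_bp(iv) < 1:
                    reached.append(lp.anchor_a)
        indirect_anchors[cell] = [("enhancer", iv) for iv in reached]

    # deduplicate element intervals across cell types by midpoint-kb identity
    elements: dict[str, RegulatoryElement] = {}

    def _add(interval: GenomicInterval, kind: str, direct: bool) -> RegulatoryElement:
        eid = name_element(interval, gene, sub_kb=sub_kb) if kind != "promoter" else (
            f"{gene.gene_name}_promoter"
        )
        if eid not in elements:
            elements[eid] = RegulatoryElement(interval, eid, kind, {}, {}, direct)
        elif direct and not elements[eid].direct:
            elements[eid].direct = True
        return elements[eid]

    _add(prom_win, "promoter", True)
    edges: dict[str, list[tuple[str, str]]] = {cell: [] for cell in loops_by_cell}
    for cell in loops_by_cell:
        for kind, iv in direct_anchors[cell]:
            el = _add(iv, kind, True)
            el.looped[cell] = True
            edges[cell].append((f"{gene.gene_name}_promoter", el.element_id))
        for kind, iv in indirect_anchors[cell]:
            el = _add(iv, kind, False)
            el.looped.setdefault(cell, False)
            # edge from nearest direct element: record as element-element link
            edges[cell].append((el.element_id, el.element_id))

    for cell, collections in peaks_by_cell.items():
        for el in elements.values():
            el.bound_factors[cell] = _overlapping_factors(el.interval, collections)
            el.looped.setdefault(cell, False)

    return GeneNetwork(gene, list(elements.values()), edges)


def to_networkx(network: GeneNetwork, cell_type: str) -> nx.Graph:
    g = nx.Graph()
    for el in network.elements:
        g.add_node(el.element_id, kind=el.kind, n_factors=len(el.bound_factors.get(cell_type, ())))
    for a, b in network.edges.get(cell_type, []):
        if a != b:
            g.add_edge(a, b)
    return g


def link_regions_to_genes(
    regions: IntervalSet,
    genes: list[GeneModel],
    loops: list[Loop],
    promoter_upstream_bp: int = 10_000,
    promoter_downstream_bp: int = 2_000,
) -> pd.DataFrame:
    """Map regions to genes directly (promoter-window overlap) or indirectly
    (via one significant loop to a promoter window).

    ``loops`` must already be significance-filtered. Returns one row per
    (region, gene, link_type); unlinked regions appear once with gene NaN.
    """
    if not genes:
        raise ValueError("empty gene list")
    windows = [
        (promoter_window(g, promoter_upstream_bp, promoter_downstream_bp), g.gene_name)
        for g in genes
    ]
    rows = []
    for i in range(len(regions)):
        region = regions[i]
        linked = set()
        for win, gname in windows:
            if region.overlap_bp(win) >= 1:
                rows.append({"region_index": i, "gene": gname, "link_type": "direct"})
                linked.add(gname)
        for lp in loops:
            for near, far in ((lp.anchor_a, lp.anchor_b), (lp.anchor_b, lp.anchor_a)):
                if region.overlap_bp(near) < 1:
                    continue
                for win, gname in windows:
                    if far.overlap_bp(win) >= 1 and gname not in linked:
                        rows.append(
                            {"region_index": i, "gene": gname, "link_type": "indirect"}
                        )
                        linked.add(gname)
        if not linked:
            rows.append({"region_index": i, "gene": None, "link_type": "unlinked"})
    return pd.DataFrame(rows, columns=["region_index", "gene", "link_type"])
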