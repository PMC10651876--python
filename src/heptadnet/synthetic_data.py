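"""Fully synthetic study generator with ground truth.

Emulates the *shape* of a sorted-HSPC regulatory study: a small genome with
gene models, per-factor/per-cell-type ChIP peak sets with planted
combinatorial structure (a core set of regions bound by the full factor
complement in every cell type, plus cell-type-specific regions bound by
lineage-flavoured subsets), accessible-region calls, FDR-annotated loop
calls connecting planted enhancers to their nearest promoter, per-track
signal coverage, and region sequences carrying planted cell-type motif
grammars. Every emitted file is a standard flat format readable by
``core_intervals``; a TruthTable records what was planted where.

What this emulates and what it does not: combinatorial occupancy, loop
significance separation, landscape signal archetypes and motif grammars are
planted with controllable effect sizes over an i.i.d. uniform-ACGT
background. Read-level properties (fragment lengths, GC bias, mappability)
are not modelled, so recovery rates here bound algorithmic correctness, not
performance on real libraries.

Determinism: one RNG stream per output concern, derived from the master
seed, so adding one output never perturbs the others; the same seed yields
byte-identical files.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_intervals import (
    GenomeLayout,
    GenomicInterval,
    GeneModel,
    IntervalSet,
    PeakCollection,
)
from .loop_network import Loop, write_bedpe
from .peak_annotation import IUPAC, reverse_complement

__all__ = [
    "SimulationConfig",
    "StudyBundle",
    "simulate_study",
    "simulate_null_peaks",
    "simulate_signal_matrix",
    "simulate_replicate_signals",
    "simulate_motif_regions",
    "HEPTAD",
    "CELL_TYPES",
]

HEPTAD = ("FLI1", "ERG", "GATA2", "RUNX1", "TAL1", "LYL1", "LMO2")
CELL_TYPES = ("HSC-MPP", "CMP", "GMP", "MEP")

MARKS = ("ATAC", "H3K4me3", "H3K27ac", "H3K27me3", "CTCF")

# signal amplitudes (x baseline) per landscape archetype, per mark
_ARCHETYPES = {
    "active_promoter": {"H3K4me3": 8.0, "H3K27ac": 6.0, "ATAC": 4.0},
    "bivalent_promoter": {"H3K4me3": 8.0, "H3K27me3": 6.0, "ATAC": 3.0},
    "ctcf": {"CTCF": 8.0, "ATAC": 3.0},
    "enhancer": {"H3K27ac": 8.0, "ATAC": 6.0},
}


def _default_cell_specific():
    return {
        "HSC-MPP": (("FLI1", "ERG", "RUNX1"), 150),
        "CMP": (("FLI1", "RUNX1", "GATA2", "TAL1"), 100),
        "GMP": (("FLI1", "RUNX1", "LYL1", "LMO2"), 150),
        "MEP": (("GATA2", "TAL1", "LYL1", "LMO2"), 150),
    }


def _default_grammar():
    # one rare 6-mer plus one common short motif per cell type, planted only
    # in that cell type's specific regions
    return {
        "HSC-MPP": (("TGTGGT", 4), ("GATA", 3)),
        "CMP": (("GGAA", 4), ("CANNTG", 3)),
        "GMP": (("AGGAAG", 4), ("GGAA", 3)),
        "MEP": (("AGATAA", 4), ("CAGCTG", 3)),
    }


@dataclass
class SimulationConfig:
    """Study-shape parameters. Defaults are the package's reference
    conditions; see the methods note for the rationale behind each."""

    n_chrom: int = 2
    chrom_length_bp: int = 10_000_000
    n_genes: int = 40
    factors: tuple[str, ...] = HEPTAD
    cell_types: tuple[str, ...] = CELL_TYPES
    n_core_regions: int = 80  # full-complement regions shared by all cells
    cell_specific: dict = field(default_factory=_default_cell_specific)
    region_width_bp: int = 600
    peak_width_mean: float = 400.0
    peak_width_sd: float = 80.0
    n_background_peaks: int = 300  # per factor per cell type
    n_atac_background: int = 600
    loop_rate: float = 0.8
    loop_fdr_signal: float = 0.005
    loop_fdr_noise: tuple[float, float] = (0.05, 1.0)
    n_decoy_loops: int = 150
    anchor_width_bp: int = 5_000
    motif_grammar: dict = field(default_factory=_default_grammar)
    noise_sd: float = 0.4  # log-normal sigma on signal tracks
    n_replicates: int = 3
    baseline_bin_bp: int = 5_000
    min_region_separation_bp: int = 3_000
    tss_exclusion_bp: int = 15_000  # keeps 5 kb anchors clear of promoter windows
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chrom", "chrom_length_bp", "n_genes", "n_core_regions",
            "n_background_peaks", "n_atac_background", "n_decoy_loops",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for grammar in self.motif_grammar.values():
            for consensus, count in grammar:
                for ch in consensus.upper():
                    if ch not in IUPAC:
                        raise ValueError(f"invalid IUPAC code {ch!r} in grammar")
                if count < 0:
                    raise ValueError("motif counts must be >= 0")


@dataclass
class StudyBundle:
    """Paths of the emitted files plus the planted-truth table."""

    outdir: Path
    layout: GenomeLayout
    genes: list[GeneModel]
    fasta: Path
    chrom_sizes: Path
    gtf: Path
    peak_paths: dict  # (factor, cell) -> narrowPeak path
    atac_paths: dict  # cell -> BED path
    loop_paths: dict  # cell -> BEDPE path
    signal_paths: dict  # (track, cell) -> bedGraph path
    replicate_paths: dict  # (cell, rep) -> bedGraph of summed factor signal
    truth: pd.DataFrame


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _place_regions(
    rng, layout: GenomeLayout, n: int, width: int, occupied: dict, min_sep: int
):
    """Rejection-sample n non-overlapping regions, min_sep bp apart from
    anything already in ``occupied`` (per-chrom sorted list of (start, end))."""
    chroms = list(layout.chrom_names)
    lengths = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    placed = []
    attempts = 0
    max_attempts = max(2000, 400 * n)
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} regions of {width} bp: chromosome capacity exceeded"
            )
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        lo, hi = min_sep, int(lengths[ci]) - width - min_sep
        if hi <= lo:
            raise ValueError("chromosome too short for requested regions")
        start = int(rng.integers(lo, hi))
        end = start + width
        clashes = any(
            start - min_sep < oe and end + min_sep > os
            for os, oe in occupied.get(chrom, [])
        )
        if clashes:
            continue
        occupied.setdefault(chrom, []).append((start, end))
        placed.append((chrom, start, end))
    return placed


def _realize_motif(rng, consensus: str) -> str:
    return "".join(
        ch if ch in "ACGT" else IUPAC[ch][rng.integers(len(IUPAC[ch]))]
        for ch in consensus.upper()
    )


def _write_fasta(path: Path, layout: GenomeLayout, seqs: dict, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in layout.chrom_names:
            fh.write(f">{chrom}\n")
            seq = seqs[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_narrowpeak(path: Path, rows) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end, signal) in enumerate(rows):
            fh.write(
                f"{chrom}\t{start}\t{end}\tpeak_{i}\t{min(1000, int(signal * 100))}\t.\t"
                f"{signal:.4f}\t-1\t-1\t{(end - start) // 2}\n"
            )


def _write_signal_track(
    path: Path, layout: GenomeLayout, elevated, baseline: float, bin_bp: int, sigma: float, rng
) -> None:
    """bedGraph: noisy baseline bins with additive elevated segments.

    ``elevated``: list of (chrom, start, end, amplitude); overlaps add.
    """
    by_chrom: dict[str, list] = {c: [] for c in layout.chrom_names}
    for chrom, start, end, amp in elevated:
        by_chrom[chrom].append((start, end, amp))
    with open(path, "w") as fh:
        for chrom in layout.chrom_names:
            L = layout.chrom_lengths[chrom]
            events = []
            for start, end, amp in by_chrom[chrom]:
                events.append((max(0, start), amp))
                events.append((min(L, end), -amp))
            cuts = sorted({0, L, *range(bin_bp, L, bin_bp), *(p for p, _ in events)})
            events.sort()
            amp_running = 0.0
            ev_i = 0
            for seg_start, seg_end in zip(cuts[:-1], cuts[1:]):
                while ev_i < len(events) and events[ev_i][0] <= seg_start:
                    amp_running += events[ev_i][1]
                    ev_i += 1
                value = baseline * rng.lognormal(0.0, sigma)
                if amp_running > 0:
                    value += amp_running * rng.lognormal(0.0, sigma)
                fh.write(f"{chrom}\t{seg_start}\t{seg_end}\t{value:.4f}\n")


def simulate_study(config: SimulationConfig, outdir: str | Path) -> StudyBundle:
    """Generate the full synthetic study bundle under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "peaks").mkdir(exist_ok=True)
    (out / "signal").mkdir(exist_ok=True)
    cfg = config

    layout = GenomeLayout(
        tuple(f"chr{i + 1}" for i in range(cfg.n_chrom)),
        {f"chr{i + 1}": cfg.chrom_length_bp for i in range(cfg.n_chrom)},
    )

    # --- genome sequence ---------------------------------------------------
    rng_genome = _rng(cfg.seed, 0)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {
        chrom: np.array(
            rng_genome.choice(bases, size=layout.chrom_lengths[chrom]), dtype="S1"
        )
        for chrom in layout.chrom_names
    }

    # --- genes -------------------------------------------------------------
    rng_genes = _rng(cfg.seed, 1)
    genes: list[GeneModel] = []
    per_chrom = max(1, cfg.n_genes // cfg.n_chrom)
    gi = 0
    for chrom in layout.chrom_names:
        L = layout.chrom_lengths[chrom]
        slot = L // (per_chrom + 1)
        for s in range(per_chrom):
            if gi >= cfg.n_genes:
                break
            body_len = int(np.clip(rng_genes.normal(8_000, 2_000), 2_000, slot - 1_000))
            anchor = (s + 1) * slot
            start = int(np.clip(anchor + rng_genes.integers(-slot // 4, slot // 4), 1_000, L - body_len - 1_000))
            strand = "+" if rng_genes.random() < 0.5 else "-"
            gi += 1
            genes.append(
                GeneModel.from_body(
                    f"G{gi:04d}", f"GENE{gi}", GenomicInterval(chrom, start, start + body_len, strand), strand
                )
            )

    # --- planted regions ---------------------------------------------------
    rng_regions = _rng(cfg.seed, 2)
    occupied: dict[str, list] = {}
    for g in genes:
        occupied.setdefault(g.body.chrom, []).append(
            (g.tss - cfg.tss_exclusion_bp, g.tss + cfg.tss_exclusion_bp)
        )

    truth_rows = []
    rid = 0

    def _plant(n, subset, cell_type, landscape_class):
        nonlocal rid
        for chrom, start, end in _place_regions(
            rng_regions, layout, n, cfg.region_width_bp, occupied, cfg.min_region_separation_bp
        ):
            rid += 1
            truth_rows.append(
                {
                    "region_id": f"R{rid:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "cell_type": cell_type,
                    "factors": "+".join(subset),
                    "landscape_class": landscape_class,
                    "looped_cells": "",
                    "loop_gene": "",
                    "motifs": "",
                }
            )

    _plant(cfg.n_core_regions, cfg.factors, "all", "enhancer_shared")
    for cell, (subset, n) in cfg.cell_specific.items():
        _plant(n, subset, cell, f"enhancer_{cell}")

    # background accessible regions cycling through the non-enhancer archetypes
    bg_classes = ("active_promoter", "bivalent_promoter", "ctcf", "enhancer")
    bg_placed = _place_regions(
        rng_regions, layout, cfg.n_atac_background, cfg.region_width_bp, occupied,
        cfg.min_region_separation_bp,
    )
    for k, (chrom, start, end) in enumerate(bg_placed):
        rid += 1
        truth_rows.append(
            {
                "region_id": f"R{rid:05d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "cell_type": "background",
                "factors": "",
                "landscape_class": bg_classes[k % len(bg_classes)],
                "looped_cells": "",
                "loop_gene": "",
                "motifs": "",
            }
        )
    truth = pd.DataFrame(truth_rows)

    planted = truth[truth["cell_type"] != "background"]

    # --- peaks -------------------------------------------------------------
    rng_peaks = _rng(cfg.seed, 3)
    peak_paths = {}
    peaks_by = {}
    for cell in cfg.cell_types:
        active = planted[(planted["cell_type"] == cell) | (planted["cell_type"] == "all")]
        for factor in cfg.factors:
            rows = []
            for _, r in active.iterrows():
                if factor not in r["factors"].split("+"):
                    continue
                width = max(60.0, rng_peaks.normal(cfg.peak_width_mean, cfg.peak_width_sd))
                width = int(width * (1 + rng_peaks.uniform(-0.2, 0.2)))
                mid = (r["start"] + r["end"]) // 2 + int(
                    rng_peaks.integers(-cfg.region_width_bp // 4, cfg.region_width_bp // 4 + 1)
                )
                start = max(0, mid - width // 2)
                end = min(layout.chrom_lengths[r["chrom"]], start + width)
                rows.append((r["chrom"], start, end, float(rng_peaks.lognormal(2.0, 0.5))))
            for _ in range(cfg.n_background_peaks):
                width = int(max(60.0, rng_peaks.normal(cfg.peak_width_mean, cfg.peak_width_sd)))
                ci = int(rng_peaks.integers(cfg.n_chrom))
                chrom = layout.chrom_names[ci]
                start = int(rng_peaks.integers(0, layout.chrom_lengths[chrom] - width))
                rows.append((chrom, start, start + width, float(rng_peaks.lognormal(1.0, 0.5))))
            rows.sort()
            path = out / "peaks" / f"{factor}.{cell}.narrowPeak"
            _write_narrowpeak(path, rows)
            peak_paths[(factor, cell)] = path
            peaks_by[(factor, cell)] = rows

    # --- ATAC --------------------------------------------------------------
    atac_paths = {}
    for cell in cfg.cell_types:
        acc = truth[
            (truth["cell_type"].isin([cell, "all", "background"]))
        ].sort_values(["chrom", "start"])
        path = out / f"atac.{cell}.bed"
        with open(path, "w") as fh:
            for _, r in acc.iterrows():
                fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['region_id']}\t0\t.\n")
        atac_paths[cell] = path

    # --- loops -------------------------------------------------------------
    rng_loops = _rng(cfg.seed, 4)
    loop_paths = {}
    tss_by_chrom = {}
    for g in genes:
        tss_by_chrom.setdefault(g.body.chrom, []).append((g.tss, g.gene_name))
    for chrom in tss_by_chrom:
        tss_by_chrom[chrom].sort()
    half = cfg.anchor_width_bp // 2
    looped_cells = {i: [] for i in truth.index}
    loop_gene = {i: "" for i in truth.index}
    for cell in cfg.cell_types:
        loops = []
        active_idx = truth.index[
            (truth["cell_type"] == cell) | (truth["cell_type"] == "all")
        ]
        for i in active_idx:
            r = truth.loc[i]
            if rng_loops.random() >= cfg.loop_rate:
                continue
            cands = tss_by_chrom.get(r["chrom"], [])
            if not cands:
                continue
            mid = (r["start"] + r["end"]) // 2
            tss, gname = min(cands, key=lambda t: abs(t[0] - mid))
            L = layout.chrom_lengths[r["chrom"]]
            a = GenomicInterval(r["chrom"], max(0, mid - half), min(L, mid + half))
            b = GenomicInterval(r["chrom"], max(0, tss - half), min(L, tss + half))
            q = float(rng_loops.uniform(1e-6, cfg.loop_fdr_signal))
            loops.append(Loop(a, b, q))
            looped_cells[i].append(cell)
            loop_gene[i] = gname
        for _ in range(cfg.n_decoy_loops):
            ci = int(rng_loops.integers(cfg.n_chrom))
            chrom = layout.chrom_names[ci]
            L = layout.chrom_lengths[chrom]
            p1 = int(rng_loops.integers(half, L - half))
            p2 = int(rng_loops.integers(half, L - half))
            q = float(rng_loops.uniform(*cfg.loop_fdr_noise))
            loops.append(
                Loop(
                    GenomicInterval(chrom, p1 - half, p1 + half),
                    GenomicInterval(chrom, p2 - half, p2 + half),
                    q,
                )
            )
        path = out / f"loops.{cell}.bedpe"
        write_bedpe(loops, path)
        loop_paths[cell] = path
    truth["looped_cells"] = [",".join(looped_cells[i]) for i in truth.index]
    truth["loop_gene"] = [loop_gene[i] for i in truth.index]

    # --- motif grammar -----------------------------------------------------
    rng_motifs = _rng(cfg.seed, 7)
    planted_motifs = {i: [] for i in truth.index}
    for i in truth.index:
        r = truth.loc[i]
        grammar = cfg.motif_grammar.get(r["cell_type"])
        if not grammar:
            continue
        seq = seqs[r["chrom"]]
        width = r["end"] - r["start"]
        taken: list[tuple[int, int]] = []
        for consensus, count in grammar:
            m = len(consensus)
            for _ in range(count):
                for _try in range(50):
                    off = int(rng_motifs.integers(0, width - m))
                    if all(off + m <= s or off >= e for s, e in taken):
                        break
                else:
                    continue
                taken.append((off, off + m))
                realized = _realize_motif(rng_motifs, consensus)
                if rng_motifs.random() < 0.5:
                    realized = reverse_complement(realized)
                pos = r["start"] + off
                seq[pos : pos + m] = np.frombuffer(realized.encode(), dtype="S1")
                planted_motifs[i].append(consensus)
    truth["motifs"] = [",".join(planted_motifs[i]) for i in truth.index]

    # --- genome files (after motif substitution) ---------------------------
    fasta = out / "genome.fa"
    _write_fasta(fasta, layout, {c: seqs[c].tobytes().decode() for c in layout.chrom_names})
    chrom_sizes = out / "genome.chrom.sizes"
    layout.write_chrom_sizes(chrom_sizes)
    gtf = out / "genes.gtf"
    with open(gtf, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.body.chrom}\tsynthetic\tgene\t{g.body.start + 1}\t{g.body.end}\t.\t"
                f'{g.strand}\t.\tgene_id "{g.gene_id}"; gene_name "{g.gene_name}";\n'
            )

    # --- signal tracks -----------------------------------------------------
    rng_signal = _rng(cfg.seed, 5)
    signal_paths = {}
    for cell in cfg.cell_types:
        active = truth[
            (truth["cell_type"].isin([cell, "all", "background"]))
        ]
        for mark in MARKS:
            elevated = []
            for _, r in active.iterrows():
                cls = r["landscape_class"]
                arche = cls.split("_")[0] if cls.startswith("enhancer") else cls
                amp = _ARCHETYPES.get(arche, {}).get(mark, 0.0)
                if amp > 0:
                    elevated.append((r["chrom"], r["start"], r["end"], amp))
            path = out / "signal" / f"{mark}.{cell}.bedgraph"
            _write_signal_track(
                path, layout, elevated, 1.0, cfg.baseline_bin_bp, cfg.noise_sd, rng_signal
            )
            signal_paths[(mark, cell)] = path
        for factor in cfg.factors:
            elevated = [
                (chrom, start, end, 8.0) for chrom, start, end, _ in peaks_by[(factor, cell)]
            ]
            path = out / "signal" / f"{factor}.{cell}.bedgraph"
            _write_signal_track(
                path, layout, elevated, 1.0, cfg.baseline_bin_bp, cfg.noise_sd, rng_signal
            )
            signal_paths[(factor, cell)] = path

    # replicate tracks of summed factor signal (for the differential stage)
    replicate_paths = {}
    for cell in cfg.cell_types:
        active = planted[(planted["cell_type"] == cell) | (planted["cell_type"] == "all")]
        elevated = [
            (r["chrom"], r["start"], r["end"], 4.0 * len(r["factors"].split("+")))
            for _, r in active.iterrows()
        ]
        for rep in range(1, cfg.n_replicates + 1):
            path = out / "signal" / f"HEPTADSUM.{cell}.rep{rep}.bedgraph"
            _write_signal_track(
                path, layout, elevated, 1.0, cfg.baseline_bin_bp, cfg.noise_sd, rng_signal
            )
            replicate_paths[(cell, rep)] = path

    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return StudyBundle(
        out, layout, genes, fasta, chrom_sizes, gtf,
        peak_paths, atac_paths, loop_paths, signal_paths, replicate_paths, truth,
    )


def simulate_null_peaks(
    layout: GenomeLayout,
    n_per_factor: int,
    width_mean: float = 400.0,
    width_sd: float = 80.0,
    seed: int = 0,
    factors: tuple[str, ...] = HEPTAD,
    cell_type: str = "null",
) -> list[PeakCollection]:
    """Per-factor peaks placed uniformly, chromosomes weighted by length.

    The calibration input for the co-binding null: any structure the
    z-scores find here is Monte-Carlo error.
    """
    rng = np.random.default_rng([seed, 11])
    chroms = list(layout.chrom_names)
    lengths = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    collections = []
    for factor in factors:
        if n_per_factor == 0:
            collections.append(
                PeakCollection(factor, cell_type, IntervalSet([], [], [], name=factor))
            )
            continue
        widths = np.clip(
            rng.normal(width_mean, width_sd, size=n_per_factor), 60, None
        ).astype(np.int64)
        ci = rng.choice(len(chroms), size=n_per_factor, p=probs)
        if np.any(widths >= lengths[ci]):
            raise ValueError("peak width exceeds chromosome length")
        starts = rng.integers(0, (lengths[ci] - widths).astype(np.int64) + 1)
        order = np.lexsort((starts, ci))
        collections.append(
            PeakCollection(
                factor,
                cell_type,
                IntervalSet(
                    [chroms[c] for c in ci[order]], starts[order], (starts + widths)[order],
                    name=factor, layout=layout,
                ),
            )
        )
    return collections


def simulate_signal_matrix(
    n_regions: int = 5_000,
    n_classes: int = 4,
    noise_sd: float = 0.4,
    seed: int = 0,
):
    """Regions x tracks matrix with planted signal archetypes.

    Returns ``(SignalMatrix (raw), labels)``; labels are the planted class of
    each region. Archetypes reuse the study's landscape classes.
    """
    from .region_landscape import SignalMatrix

    if n_classes < 2 or n_classes > len(_ARCHETYPES):
        raise ValueError(f"n_classes must be in [2, {len(_ARCHETYPES)}]")
    rng = np.random.default_rng([seed, 21])
    class_names = list(_ARCHETYPES)[:n_classes]
    labels = rng.integers(0, n_classes, size=n_regions)
    tracks = [(mark, "pooled") for mark in MARKS]
    values = np.empty((n_regions, len(tracks)))
    for j, (mark, _) in enumerate(tracks):
        amp = np.array([1.0 + _ARCHETYPES[c].get(mark, 0.0) for c in class_names])
        values[:, j] = amp[labels] * rng.lognormal(0.0, noise_sd, size=n_regions)
    width = 600
    regions = IntervalSet(
        ["chrS"] * n_regions,
        np.arange(n_regions) * (width + 100),
        np.arange(n_regions) * (width + 100) + width,
        name="simulated_landscape",
    )
    df = pd.DataFrame(values, columns=pd.MultiIndex.from_tuples(tracks, names=["track", "cell_type"]))
    return SignalMatrix(regions, df, "raw"), labels


def simulate_replicate_signals(
    n_regions: int = 2_000,
    n_replicates: int = 3,
    frac_enriched: float = 0.0,
    fold: float = 4.0,
    noise_sd: float = 0.4,
    seed: int = 0,
):
    """Replicate signal pair for the differential-enrichment stage.

    Returns ``(regions, signal_a, signal_b, enriched_mask)``: log-normal
    noise around a shared per-region baseline, with the first
    ``frac_enriched`` regions ``fold``-times higher in A.
    """
    rng = np.random.default_rng([seed, 22])
    base = rng.lognormal(2.0, 0.6, size=n_regions)
    enriched = np.zeros(n_regions, dtype=bool)
    enriched[: int(round(frac_enriched * n_regions))] = True
    a = base[:, None] * rng.lognormal(0.0, noise_sd, size=(n_regions, n_replicates))
    b = base[:, None] * rng.lognormal(0.0, noise_sd, size=(n_regions, n_replicates))
    a[enriched] *= fold
    width = 600
    regions = IntervalSet(
        ["chrS"] * n_regions,
        np.arange(n_regions) * (width + 100),
        np.arange(n_regions) * (width + 100) + width,
        name="simulated_replicates",
    )
    return regions, a, b, enriched


def simulate_motif_regions(
    n_regions: int,
    region_length: int = 500,
    grammar: tuple = (),
    seed: int = 0,
) -> list[str]:
    """Uniform-ACGT sequences with a motif grammar planted by substitution.

    ``grammar``: tuple of (IUPAC consensus, count per region). With an empty
    grammar this is the background cohort.
    """
    rng = np.random.default_rng([seed, 23])
    bases = "ACGT"
    seqs = []
    for _ in range(n_regions):
        seq = list("".join(bases[b] for b in rng.integers(0, 4, size=region_length)))
        taken: list[tuple[int, int]] = []
        for consensus, count in grammar:
            m = len(consensus)
            for _ in range(count):
                for _try in range(50):
                    off = int(rng.integers(0, region_length - m))
                    if all(off + m <= s or off >= e for s, e in taken):
                        break
                else:
                    continue
                taken.append((off, off + m))
                realized = _realize_motif(rng, consensus)
                if rng.random() < 0.5:
                    realized = reverse_complement(realized)
                seq[off : off + m] = list(realized)
        seqs.append("".join(seq))
    return seqs
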