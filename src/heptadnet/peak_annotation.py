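"""Peak feature-class assignment relative to TSS and consensus-motif scanning.

Each ChIP peak is assigned to exactly one of four genomic feature classes by
the unsigned distance from its midpoint to the nearest TSS, with promoter
classes taking precedence over gene-body overlap (a peak spanning its own
gene's TSS is a promoter peak, not an intragenic one). Motif enrichment is
reported as the fraction of peaks containing at least one consensus match on
either strand — deliberately a consensus (IUPAC) scan, not a PWM scan.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core_intervals import GeneModel, GenomicInterval, IntervalSet, PeakCollection

__all__ = [
    "FeatureClass",
    "ConsensusMotif",
    "DEFAULT_MOTIFS",
    "classify_peak",
    "classify_peaks",
    "feature_fractions",
    "scan_consensus",
    "count_matches",
    "motif_fraction",
    "reverse_complement",
]


class FeatureClass(str, Enum):
    promoter_proximal = "promoter_proximal"
    promoter_adjacent = "promoter_adjacent"
    intragenic = "intragenic"
    intergenic = "intergenic"


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsensusMotif:
    """A named IUPAC consensus, e.g. ETS = GGAA."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("empty consensus")
        for ch in self.consensus.upper():
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC code {ch!r} in motif {self.name}")

    def _regex(self, pattern: str) -> re.Pattern:
        # lookahead so overlapping occurrences are all reported; classes over
        # ACGT only, so N in the *sequence* can never match
        body = "".join(f"[{IUPAC[ch]}]" for ch in pattern.upper())
        return re.compile(f"(?=({body}))")

    @property
    def forward_regex(self) -> re.Pattern:
        return self._regex(self.consensus)

    @property
    def reverse_regex(self) -> re.Pattern:
        return self._regex(reverse_complement(self.consensus))


# The four consensus motifs profiled across factor peak sets: ETS and E-box
# are found for all factors, GATA marks the GATA2/TAL1/LYL1/LMO2 arm, RUNX
# uses the canonical core since published motif sets rarely print one.
DEFAULT_MOTIFS = (
    ConsensusMotif("ETS", "GGAA"),
    ConsensusMotif("GATA", "GATA"),
    ConsensusMotif("E-box", "CANNTG"),
    ConsensusMotif("RUNX", "TGTGGT"),
)


def scan_consensus(sequence: str, motif: ConsensusMotif) -> list[int]:
    """Start positions (forward coordinates) of double-strand consensus matches.

    A window matches if the forward strand or its reverse complement matches
    the IUPAC pattern; coincident forward/reverse hits are deduplicated.
    """
    seq = sequence.upper()
    for ch in set(seq):
        if ch not in "ACGTN":
            raise ValueError(f"invalid sequence character {ch!r}")
    hits = {m.start() for m in motif.forward_regex.finditer(seq)}
    hits |= {m.start() for m in motif.reverse_regex.finditer(seq)}
    return sorted(hits)


def count_matches(sequence: str, motif: ConsensusMotif) -> int:
    return len(scan_consensus(sequence, motif))


def _nearest_tss_distance(chrom: str, midpoint: int, tss_by_chrom) -> float:
    tss = tss_by_chrom.get(chrom)
    if tss is None or len(tss) == 0:
        return np.inf
    i = np.searchsorted(tss, midpoint)
    best = np.inf
    if i < len(tss):
        best = min(best, abs(int(tss[i]) - midpoint))
    if i > 0:
        best = min(best, abs(int(tss[i - 1]) - midpoint))
    return best


def _index_genes(genes: list[GeneModel]):
    tss_by_chrom: dict[str, np.ndarray] = {}
    bodies_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.body.chrom, []).append(g.tss)  # type: ignore[arg-type]
        bodies_by_chrom.setdefault(g.body.chrom, []).append((g.body.start, g.body.end))  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}
    bodies_by_chrom = {
        c: (np.asarray([b[0] for b in v]), np.asarray([b[1] for b in v]))
        for c, v in bodies_by_chrom.items()
    }
    return tss_by_chrom, bodies_by_chrom


def classify_peak(
    peak: GenomicInterval,
    genes: list[GeneModel],
    proximal_bp: int = 1_000,
    adjacent_bp: int = 10_000,
) -> FeatureClass:
    """Assign one peak to its genomic feature class (see module docstring)."""
    if not genes:
        raise ValueError("empty gene list")
    if not 0 < proximal_bp < adjacent_bp:
        raise ValueError("need adjacent_bp > proximal_bp > 0")
    tss_by_chrom, bodies_by_chrom = _index_genes(genes)
    return _classify_one(peak, tss_by_chrom, bodies_by_chrom, proximal_bp, adjacent_bp)


def _classify_one(peak, tss_by_chrom, bodies_by_chrom, proximal_bp, adjacent_bp):
    mid = peak.midpoint
    d = _nearest_tss_distance(peak.chrom, mid, tss_by_chrom)
    if d <= proximal_bp:
        return FeatureClass.promoter_proximal
    if d <= adjacent_bp:
        return FeatureClass.promoter_adjacent
    bodies = bodies_by_chrom.get(peak.chrom)
    if bodies is not None:
        bs, be = bodies
        if np.any((peak.start < be) & (peak.end > bs)):
            return FeatureClass.intragenic
    return FeatureClass.intergenic


def classify_peaks(
    peaks: IntervalSet,
    genes: list[GeneModel],
    proximal_bp: int = 1_000,
    adjacent_bp: int = 10_000,
) -> list[FeatureClass]:
    if not genes:
        raise ValueError("empty gene list")
    if not 0 < proximal_bp < adjacent_bp:
        raise ValueError("need adjacent_bp > proximal_bp > 0")
    tss_by_chrom, bodies_by_chrom = _index_genes(genes)
    return [
        _classify_one(peaks[i], tss_by_chrom, bodies_by_chrom, proximal_bp, adjacent_bp)
        for i in range(len(peaks))
    ]


def feature_fractions(classes: list[FeatureClass]) -> dict[str, float]:
    """Per-class fractions; they sum to 1 for any non-empty input."""
    if not classes:
        raise ValueError("no peaks classified")
    n = len(classes)
    return {fc.value: sum(c == fc for c in classes) / n for fc in FeatureClass}


def motif_fraction(
    peaks: PeakCollection | IntervalSet,
    genome,
    motifs=DEFAULT_MOTIFS,
) -> dict[str, float]:
    """Fraction of peaks containing >= 1 double-strand match per motif.

    ``genome`` is a ``pyfaidx.Fasta`` (or a mapping chrom -> sequence string).
    An empty collection yields NaN fractions ("missing").
    """
    regions = peaks.peaks if isinstance(peaks, PeakCollection) else peaks
    if len(regions) == 0:
        return {m.name: float("nan") for m in motifs}
    counts = {m.name: 0 for m in motifs}
    for i in range(len(regions)):
        chrom = regions.chroms[i]
        start, end = int(regions.starts[i]), int(regions.ends[i])
        try:
            seq = str(genome[chrom][start:end])
        except Exception as exc:  # noqa: BLE001 - re-raise naming the peak
            raise ValueError(f"sequence fetch failed for {chrom}:{start}-{end}") from exc
        for m in motifs:
            if count_matches(seq, m) > 0:
                counts[m.name] += 1
    n = len(regions)
    return {name: c / n for name, c in counts.items()}
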