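"""Combinatorial TF co-occupancy statistics against a randomization null.

The observed statistic: merge all factors' peaks of one cell type into a
universe of non-overlapping regions, assign each region the *exact* subset of
factors with an overlapping peak (exclusive counting — a region bound by all
seven factors counts once, for the seven-factor combination only), and count
regions per subset. Exclusive counting is what makes the full-factor
combination stand out while individual pairs stay modest; an inclusive mode
(region counted for every sub-combination of its bound set) is available
behind a flag.

The null: every peak is independently re-placed uniformly on its own
chromosome with its length preserved, factors shuffled independently,
overlaps among shuffled peaks permitted. z(S) = (obs - mean_null)/sd_null.
A circular-shift mode (one random offset per factor per chromosome) is the
alternative, spacing-preserving null.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core_intervals import GenomeLayout, IntervalSet, PeakCollection, merge_assign_bitmask

__all__ = [
    "CombinationAssignment",
    "assign_combinations",
    "cobinding_zscores",
    "single_factor_regions",
    "subset_label",
]


def subset_label(factors: tuple[str, ...]) -> str:
    return "+".join(factors)


@dataclass
class CombinationAssignment:
    """Exact factor subset per merged region (a partition of the universe)."""

    regions: IntervalSet
    masks: np.ndarray  # int bitmask per region, bit i = factors[i] bound
    factors: tuple[str, ...]

    def subset_of(self, i: int) -> tuple[str, ...]:
        return tuple(f for j, f in enumerate(self.factors) if self.masks[i] >> j & 1)

    def regions_with_subset(self, subset: tuple[str, ...]) -> IntervalSet:
        idx = {f: j for j, f in enumerate(self.factors)}
        mask = 0
        for f in subset:
            mask |= 1 << idx[f]
        return self.regions.take(np.flatnonzero(self.masks == mask))


def _pack_collections(collections: list[PeakCollection], layout: GenomeLayout | None):
    factors = tuple(c.factor for c in collections)
    if len(set(factors)) != len(factors):
        raise ValueError("duplicate factor labels")
    if len(factors) < 2:
        raise ValueError("need >= 2 factors")
    cell_types = {c.cell_type for c in collections}
    if len(cell_types) > 1:
        raise ValueError(f"collections span multiple cell types: {sorted(cell_types)}")
    if layout is None:
        layout = next((c.peaks.layout for c in collections if c.peaks.layout), None)
    if layout is not None:
        chrom_names = list(layout.chrom_names)
    else:
        chrom_names = sorted({c for col in collections for c in np.unique(col.peaks.chroms)})
    code_of = {c: i for i, c in enumerate(chrom_names)}
    chrom_codes = np.concatenate(
        [np.array([code_of[c] for c in col.peaks.chroms], dtype=np.int64) for col in collections]
    ) if collections else np.empty(0, np.int64)
    starts = np.concatenate([col.peaks.starts for col in collections])
    ends = np.concatenate([col.peaks.ends for col in collections])
    bits = np.concatenate(
        [np.full(len(col.peaks), 1 << i, dtype=np.int64) for i, col in enumerate(collections)]
    )
    return factors, chrom_names, chrom_codes, starts, ends, bits, layout


def _count_by_mask(chrom_codes, starts, ends, bits, n_factors, span_guard, min_bp):
    eff_bits = bits if min_bp <= 1 else np.where(ends - starts >= min_bp, bits, 0)
    _, _, _, masks = merge_assign_bitmask(chrom_codes, starts, ends, eff_bits, span_guard)
    return np.bincount(masks, minlength=1 << n_factors)


def _inclusive_counts(exclusive: np.ndarray, n_factors: int) -> np.ndarray:
    # superset-sum (zeta) transform: counts[S] = number of regions whose
    # exact subset is a superset of S
    out = exclusive.astype(np.int64).copy()
    for j in range(n_factors):
        bit = 1 << j
        idx = np.arange(1 << n_factors)
        has = (idx & bit).astype(bool)
        out[~has] += out[idx[~has] | bit]
    return out


def _build_table(
    factors, observed, null_mean=None, null_sd=None, n_randomizations=0, seed=None, mode="exclusive"
) -> pd.DataFrame:
    rows = []
    k = len(factors)
    for size in range(1, k + 1):
        for subset in combinations(range(k), size):
            mask = 0
            for j in subset:
                mask |= 1 << j
            row = {
                "subset": subset_label(tuple(factors[j] for j in subset)),
                "size": size,
                "observed": int(observed[mask]),
            }
            if null_mean is not None:
                mu, sd = float(null_mean[mask]), float(null_sd[mask])
                obs = observed[mask]
                if sd > 0:
                    z = (obs - mu) / sd
                elif obs == mu:
                    z = 0.0
                else:
                    z = np.inf if obs > mu else -np.inf
                row.update(null_mean=mu, null_sd=sd, z=z)
            rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs.update(
        factors=tuple(factors), n_randomizations=n_randomizations, seed=seed, mode=mode
    )
    return table


def assign_combinations(
    collections: list[PeakCollection],
    min_bp: int = 1,
    layout: GenomeLayout | None = None,
    mode: str = "exclusive",
) -> tuple[CombinationAssignment, pd.DataFrame]:
    """Merge all factors' peaks and count regions per exact factor subset.

    Returns the per-region assignment and a CombinationTable with observed
    counts only (no null columns). Size-1 subsets are retained (flagged by
    their ``size`` column) for the single-factor priming analysis.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    factors, chrom_names, cc, ss, ee, bits, layout = _pack_collections(collections, layout)
    span_guard = int(ee.max()) + 1 if len(ee) else 1
    eff_bits = bits if min_bp <= 1 else np.where(ee - ss >= min_bp, bits, 0)
    rc, rs, re_, masks = merge_assign_bitmask(cc, ss, ee, eff_bits, span_guard)
    regions = IntervalSet(
        np.array([chrom_names[c] for c in rc], dtype=object), rs, re_,
        name="merged_universe", layout=layout,
    )
    counts = np.bincount(masks, minlength=1 << len(factors))
    if mode == "inclusive":
        counts = _inclusive_counts(counts, len(factors))
    elif mode != "exclusive":
        raise ValueError(f"unknown counting mode {mode!r}")
    table = _build_table(factors, counts, mode=mode)
    return CombinationAssignment(regions, masks, factors), table


def cobinding_zscores(
    collections: list[PeakCollection],
    layout: GenomeLayout,
    n_randomizations: int = 1_000,
    seed: int = 0,
    min_bp: int = 1,
    mode: str = "exclusive",
    null: str = "uniform",
) -> pd.DataFrame:
    """CombinationTable with observed counts, null moments and z per subset.

    ``null='uniform'`` re-places every peak uniformly on its own chromosome
    (length preserved); ``null='shift'`` applies one random circular offset
    per factor per chromosome, preserving intra-factor spacing.
    """
    if n_randomizations < 10:
        raise ValueError("n_randomizations must be >= 10")
    factors, chrom_names, cc, ss, ee, bits, _ = _pack_collections(collections, layout)
    k = len(factors)
    chrom_len = np.array([layout.chrom_lengths[c] for c in chrom_names], dtype=np.int64)
    lengths = ee - ss
    max_start = chrom_len[cc] - lengths
    if np.any(max_start < 0):
        bad = int(np.flatnonzero(max_start < 0)[0])
        raise ValueError(
            f"peak longer than its chromosome ({chrom_names[cc[bad]]}, {lengths[bad]} bp)"
        )
    span_guard = int(chrom_len.max()) + 1
    n_masks = 1 << k

    observed = _count_by_mask(cc, ss, ee, bits, k, span_guard, min_bp)
    if mode == "inclusive":
        observed = _inclusive_counts(observed, k)
    elif mode != "exclusive":
        raise ValueError(f"unknown counting mode {mode!r}")

    rng = np.random.default_rng(seed)
    total = np.zeros(n_masks, dtype=np.float64)
    total_sq = np.zeros(n_masks, dtype=np.float64)
    factor_bits = np.log2(bits).astype(np.int64)  # bits are single set bits
    for _ in range(n_randomizations):
        if null == "uniform":
            new_starts = rng.integers(0, max_start + 1)
        elif null == "shift":
            # one offset per (factor, chromosome); wrap within the legal
            # start range so lengths stay in bounds
            new_starts = ss.copy()
            for fi in range(k):
                for ci in range(len(chrom_names)):
                    sel = (factor_bits == fi) & (cc == ci)
                    if not np.any(sel):
                        continue
                    room = int(chrom_len[ci] - lengths[sel].max())
                    off = int(rng.integers(0, room + 1))
                    new_starts[sel] = (ss[sel] + off) % np.maximum(max_start[sel] + 1, 1)
        else:
            raise ValueError(f"unknown null model {null!r}")
        counts = _count_by_mask(cc, new_starts, new_starts + lengths, bits, k, span_guard, min_bp)
        if mode == "inclusive":
            counts = _inclusive_counts(counts, k)
        total += counts
        total_sq += counts.astype(np.float64) ** 2
    mean = total / n_randomizations
    var = (total_sq - n_randomizations * mean**2) / max(n_randomizations - 1, 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    if np.any((sd == 0) & (observed != mean)):
        warnings.warn(
            "some subsets have zero null variance but non-null observed counts; "
            "their z is reported as an infinite sentinel",
            stacklevel=2,
        )
    return _build_table(factors, observed, mean, sd, n_randomizations, seed, mode)


def single_factor_regions(collections: list[PeakCollection], factor: str, min_bp: int = 1) -> IntervalSet:
    """Merged regions whose exact assignment is {factor} — priming candidates."""
    factors = [c.factor for c in collections]
    if factor not in factors:
        raise ValueError(f"unknown factor {factor!r} (have {factors})")
    assignment, _ = assign_combinations(collections, min_bp=min_bp)
    return assignment.regions_with_subset((factor,))
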