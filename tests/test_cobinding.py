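"""Combination counting, randomization null, determinism."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heptadnet.core_intervals import GenomeLayout, IntervalSet, PeakCollection
from heptadnet.cobinding import (
    assign_combinations,
    cobinding_zscores,
    single_factor_regions,
    subset_label,
)
from heptadnet.synthetic_data import simulate_null_peaks

from conftest import random_interval_set


def collections_from(rng, factors, n_peaks, cell="X", max_pos=1_000_000):
    return [
        PeakCollection(f, cell, random_interval_set(rng, n_peaks, chroms=("c1",), max_pos=max_pos, name=f))
        for f in factors
    ]


def oracle_counts(collections):
    """Per-base brute force: union bitmap, connected runs, factor subsets."""
    size = 1_100_000
    cover = np.zeros(size, dtype=np.int64)
    for k, col in enumerate(collections):
        for i in range(len(col.peaks)):
            cover[col.peaks.starts[i] : col.peaks.ends[i]] |= 1 << k
    counts: dict[int, int] = {}
    i = 0
    while i < size:
        if cover[i] == 0:
            i += 1
            continue
        j = i
        mask = 0
        while j < size and cover[j] != 0:
            mask |= int(cover[j])
            j += 1
        counts[mask] = counts.get(mask, 0) + 1
        i = j
    return counts


class TestAssign:
    def test_identical_sets_give_single_full_combination(self):
        base = IntervalSet(["c1"], [100], [200])
        cols = [PeakCollection(f, "X", base) for f in "ABCDEFG"]
        assignment, table = assign_combinations(cols)
        full = table[table["subset"] == subset_label(tuple("ABCDEFG"))]
        assert int(full["observed"].iloc[0]) == 1
        assert int(table["observed"].sum()) == 1

    def test_disjoint_pairs_zero(self):
        a = PeakCollection("A", "X", IntervalSet(["c1", "c1"], [0, 100], [10, 110]))
        b = PeakCollection("B", "X", IntervalSet(["c1"], [500], [510]))
        _, table = assign_combinations([a, b])
        assert int(table.loc[table["size"] >= 2, "observed"].sum()) == 0
        singles = table[table["size"] == 1].set_index("subset")["observed"]
        assert singles["A"] == 2 and singles["B"] == 1

    def test_duplicate_factor_labels_rejected(self):
        s = IntervalSet(["c1"], [0], [10])
        with pytest.raises(ValueError):
            assign_combinations([PeakCollection("A", "X", s), PeakCollection("A", "X", s)])

    def test_mixed_cell_types_rejected(self):
        s = IntervalSet(["c1"], [0], [10])
        with pytest.raises(ValueError):
            assign_combinations([PeakCollection("A", "X", s), PeakCollection("B", "Y", s)])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25)
    def test_counts_match_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cols = collections_from(rng, "ABCDE", 100)
        assignment, table = assign_combinations(cols)
        expected = oracle_counts(cols)
        got = {
            int(m): int(c)
            for m, c in zip(*np.unique(assignment.masks, return_counts=True))
        }
        assert got == expected
        # partition conservation, exact
        assert int(table["observed"].sum()) == len(assignment.regions)

    def test_inclusive_mode_counts_subcombinations(self):
        base = IntervalSet(["c1"], [100], [200])
        cols = [PeakCollection(f, "X", base) for f in "ABC"]
        _, table = assign_combinations(cols, mode="inclusive")
        # the single ABC region counts for every non-empty subset
        assert (table["observed"] == 1).all()


class TestSingleFactor:
    def test_identical_sets_have_no_singletons(self):
        base = IntervalSet(["c1"], [100], [200])
        cols = [PeakCollection(f, "X", base) for f in "ABCDEFG"]
        for f in "ABCDEFG":
            assert len(single_factor_regions(cols, f)) == 0

    def test_disjoint_factor_fully_returned(self, rng):
        a = PeakCollection("A", "X", IntervalSet(["c1", "c1"], [0, 1000], [100, 1100]))
        b = PeakCollection("B", "X", IntervalSet(["c1"], [5000], [5100]))
        regions = single_factor_regions([a, b], "A")
        assert len(regions) == 2

    def test_unknown_factor_rejected(self):
        a = PeakCollection("A", "X", IntervalSet(["c1"], [0], [10]))
        b = PeakCollection("B", "X", IntervalSet(["c1"], [50], [60]))
        with pytest.raises(ValueError):
            single_factor_regions([a, b], "Z")

    def test_matches_assignment_filter(self, rng):
        cols = collections_from(rng, "ABCD", 80)
        assignment, _ = assign_combinations(cols)
        expected = assignment.regions_with_subset(("B",))
        got = single_factor_regions(cols, "B")
        assert np.array_equal(got.starts, expected.starts)


class TestZScores:
    def test_perfect_cooccurrence_is_top(self, toy_layout, rng):
        peaks = random_interval_set(rng, 60, chroms=("chr1",), max_pos=900_000)
        cols = [PeakCollection("A", "X", peaks), PeakCollection("B", "X", peaks)]
        table = cobinding_zscores(cols, toy_layout, n_randomizations=50, seed=0)
        pair = table[table["subset"] == "A+B"].iloc[0]
        assert pair["z"] == table["z"].max()

    def test_determinism(self, rng):
        layout = GenomeLayout(("c1",), {"c1": 1_100_000})
        cols = collections_from(rng, "ABC", 50, max_pos=900_000)
        t1 = cobinding_zscores(cols, layout, 20, seed=9)
        t2 = cobinding_zscores(cols, layout, 20, seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_peak_longer_than_chromosome_rejected(self):
        layout = GenomeLayout(("c1",), {"c1": 100})
        cols = [
            PeakCollection("A", "X", IntervalSet(["c1"], [0], [99])),
            PeakCollection("B", "X", IntervalSet(["c1"], [0], [200], )),
        ]
        with pytest.raises(ValueError, match="longer than"):
            cobinding_zscores(cols, GenomeLayout(("c1",), {"c1": 150}), 10, 0)

    def test_min_randomizations_enforced(self, rng):
        layout = GenomeLayout(("c1",), {"c1": 1_100_000})
        cols = collections_from(rng, "AB", 10, max_pos=900_000)
        with pytest.raises(ValueError):
            cobinding_zscores(cols, layout, n_randomizations=5, seed=0)

    def test_null_input_is_calibrated(self):
        layout = GenomeLayout(("n1", "n2"), {"n1": 4_000_000, "n2": 4_000_000})
        cols = simulate_null_peaks(layout, 800, seed=3)
        table = cobinding_zscores(cols, layout, n_randomizations=200, seed=3)
        multi = table[(table["size"] >= 2) & (table["null_sd"] > 0) & np.isfinite(table["z"])]
        assert abs(multi["z"].mean()) <= 0.25
        assert 0.6 <= multi["z"].std() <= 1.5
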