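import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan.model import DataError, PopulationMap, Window
from sweepscan.window_stats import (
    compute_window_stats,
    intersect_windows,
    make_windows,
    pi_ratio,
    select_top,
    window_fst,
    window_pi,
)

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_pi(dosages, window_length):
    """Mean per-pair per-bp difference count over all chromosome pairs.

    Each individual contributes two chromosomes; per site the alleles of
    an individual with dosage d are d alt alleles among its two copies
    (which pair of copies carries them does not change per-site counts).
    """
    dosages = np.asarray(dosages)
    n_sites, n_ind = dosages.shape
    n_chrom = 2 * n_ind
    haplotypes = np.zeros((n_sites, n_chrom), dtype=int)
    for j in range(n_ind):
        for s in range(n_sites):
            d = dosages[s, j]
            haplotypes[s, 2 * j] = 1 if d >= 1 else 0
            haplotypes[s, 2 * j + 1] = 1 if d == 2 else 0
    pairs = list(itertools.combinations(range(n_chrom), 2))
    total = sum(
        int((haplotypes[:, a] != haplotypes[:, b]).sum()) for a, b in pairs
    )
    return total / len(pairs) / window_length


def per_site_fst_oracle(dosages, hg_cols, cg_cols):
    """Hudson ratio-of-averages computed site by site from first principles."""
    dosages = np.asarray(dosages)
    num_sum = den_sum = 0.0
    for row in dosages:
        sums = []
        for cols in (hg_cols, cg_cols):
            vals = row[cols]
            vals = vals[vals >= 0]
            sums.append((vals.sum(), 2 * len(vals)))
        (c1, n1), (c2, n2) = sums
        if n1 < 2 or n2 < 2:
            continue
        p1, p2 = c1 / n1, c2 / n2
        den = p1 * (1 - p2) + p2 * (1 - p1)
        if den <= 0:
            continue
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        num_sum += num
        den_sum += den
    return num_sum / den_sum if den_sum > 0 else math.nan


# ---------------------------------------------------------------------------
# make_windows

class TestMakeWindows:
    def test_100kb_default(self):
        wins = make_windows({"1": 100_000})
        assert [(w.start, w.end) for w in wins] == [
            (0, 40_000), (20_000, 60_000), (40_000, 80_000), (60_000, 100_000)
        ]

    def test_exact_single_window(self):
        wins = make_windows({"1": 40_000})
        assert [(w.start, w.end) for w in wins] == [(0, 40_000)]

    def test_too_short_no_window(self):
        assert make_windows({"1": 39_999}) == []

    def test_keep_partial_terminal(self):
        wins = make_windows({"1": 105_000}, keep_partial=True)
        assert wins[-1] == Window("1", 80_000, 105_000)

    def test_keep_partial_not_added_when_exact(self):
        wins = make_windows({"1": 100_000}, keep_partial=True)
        assert len(wins) == 4

    def test_nonpositive_fatal(self):
        with pytest.raises(DataError):
            make_windows({"1": 100_000}, window_bp=0)
        with pytest.raises(DataError):
            make_windows({"1": -5})

    def test_multiple_chromosomes(self):
        wins = make_windows({"1": 100_000, "2": 40_000})
        assert sum(w.chrom == "2" for w in wins) == 1


# ---------------------------------------------------------------------------
# pi

class TestWindowPi:
    def test_single_site_c2_of_4(self, popmap_4):
        # one SNP, 4 chromosomes in HG (2 individuals), c = 2
        gm = make_genotypes([[1, 1, 0, 0]])
        w = Window("1", 0, 40_000)
        pi = window_pi(gm, popmap_4, w, "HG")
        assert pi == pytest.approx((2 * 2 * 2) / (4 * 3) / 40_000, abs=1e-15)

    def test_monomorphic_zero(self, popmap_4):
        gm = make_genotypes([[2, 2, 0, 0], [0, 0, 1, 1]])
        assert window_pi(gm, popmap_4, Window("1", 0, 1000), "HG") == 0.0

    def test_two_chromosomes_het(self):
        pops = PopulationMap({"a": "HG", "c1": "CG", "c2": "CG"})
        gm = make_genotypes([[1, 0, 0]], ids=["a", "c1", "c2"])
        # n = 2, c = 1 -> per-site pi = 1
        assert window_pi(gm, pops, Window("1", 0, 100), "HG") == pytest.approx(1 / 100)

    def test_empty_group_fatal(self, popmap_4):
        gm = make_genotypes([[1, 1, 0, 0]], ids=["x1", "x2", "x3", "x4"])
        with pytest.raises(DataError):
            window_pi(gm, popmap_4, Window("1", 0, 100), "HG")

    def test_per_site_normalization(self, popmap_4):
        gm = make_genotypes([[1, 1, 0, 0], [2, 0, 1, 1]])
        w = Window("1", 0, 40_000)
        per_bp = window_pi(gm, popmap_4, w, "HG")
        per_site = window_pi(gm, popmap_4, w, "HG", per_site_norm=True)
        assert per_site == pytest.approx(per_bp * 40_000 / 2)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1), st.integers(2, 4), st.integers(1, 12))
    def test_brute_force_oracle(self, seed, n_ind, n_sites):
        # <= 8 chromosomes, no missing data: exact pairwise equivalence
        rng = np.random.default_rng(seed)
        dosages = rng.integers(0, 3, size=(n_sites, n_ind + 2))
        ids = [f"h{i}" for i in range(n_ind)] + ["c1", "c2"]
        pops = PopulationMap(
            {**{f"h{i}": "HG" for i in range(n_ind)}, "c1": "CG", "c2": "CG"}
        )
        gm = make_genotypes(dosages, ids=ids)
        w = Window("1", 0, 2000)
        expected = brute_force_pi(dosages[:, :n_ind], 2000)
        assert window_pi(gm, pops, w, "HG") == pytest.approx(expected, abs=1e-12)


class TestWindowFst:
    def test_fixed_difference_is_one(self, popmap_4):
        gm = make_genotypes([[2, 2, 0, 0]])
        assert window_fst(gm, popmap_4, Window("1", 0, 1000)) == pytest.approx(1.0)

    def test_derived_example(self):
        # p1 = 0.5 with n1 = 10 chromosomes, p2 = 0.25 with n2 = 8
        hg_dos = [2, 2, 1, 0, 0]          # c1 = 5 of 10
        cg_dos = [1, 1, 0, 0]             # c2 = 2 of 8
        ids = [f"h{i}" for i in range(5)] + [f"c{i}" for i in range(4)]
        pops = PopulationMap(
            {**{f"h{i}": "HG" for i in range(5)}, **{f"c{i}": "CG" for i in range(4)}}
        )
        gm = make_genotypes([hg_dos + cg_dos], ids=ids)
        expected = (0.0625 - 0.25 / 9 - 0.1875 / 7) / 0.5
        fst = window_fst(gm, pops, Window("1", 0, 1000))
        assert fst == pytest.approx(expected, abs=1e-12)
        assert fst == pytest.approx(0.015873, abs=1e-6)

    def test_monomorphic_site_skipped(self, popmap_4):
        gm = make_genotypes([[0, 0, 0, 0], [2, 2, 0, 0]])
        assert window_fst(gm, popmap_4, Window("1", 0, 1000)) == pytest.approx(1.0)

    def test_all_uninformative_undefined(self, popmap_4):
        gm = make_genotypes([[0, 0, 0, 0]])
        assert math.isnan(window_fst(gm, popmap_4, Window("1", 0, 1000)))

    def test_never_exceeds_one(self, popmap_4):
        rng = np.random.default_rng(3)
        for _ in range(50):
            dosages = rng.integers(0, 3, size=(rng.integers(1, 20), 4))
            gm = make_genotypes(dosages)
            fst = window_fst(gm, popmap_4, Window("1", 0, 10_000))
            assert math.isnan(fst) or fst <= 1.0 + 1e-12

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_ratio_of_averages_matches_per_site_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dosages = rng.integers(0, 3, size=(20, 8))
        ids = [f"h{i}" for i in range(4)] + [f"c{i}" for i in range(4)]
        pops = PopulationMap(
            {**{f"h{i}": "HG" for i in range(4)}, **{f"c{i}": "CG" for i in range(4)}}
        )
        gm = make_genotypes(dosages, ids=ids)
        got = window_fst(gm, pops, Window("1", 0, 10_000))
        expected = per_site_fst_oracle(dosages, np.arange(4), np.arange(4, 8))
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    def test_identical_groups_near_zero(self):
        # duplicated dosage columns: estimator expectation <= 0
        rng = np.random.default_rng(11)
        half = rng.integers(0, 3, size=(80, 10))
        dosages = np.hstack([half, half])
        ids = [f"h{i}" for i in range(10)] + [f"c{i}" for i in range(10)]
        pops = PopulationMap(
            {**{f"h{i}": "HG" for i in range(10)}, **{f"c{i}": "CG" for i in range(10)}}
        )
        gm = make_genotypes(dosages, ids=ids)
        assert window_fst(gm, pops, Window("1", 0, 10_000)) <= 0.05


class TestPiRatio:
    def test_simple(self):
        assert pi_ratio(0.002, 0.001) == pytest.approx(2.0)

    def test_infinite(self):
        assert pi_ratio(0.001, 0.0) == math.inf

    def test_both_zero_undefined(self):
        assert math.isnan(pi_ratio(0.0, 0.0))

    def test_negative_fatal(self):
        with pytest.raises(DataError):
            pi_ratio(-1.0, 0.5)


# ---------------------------------------------------------------------------
# selection

class TestSelectTop:
    def test_upper_1_percent_of_1_to_100(self):
        cutoff, sel = select_top(list(range(1, 101)), tail="upper", fraction=0.01)
        assert cutoff == pytest.approx(99.01)
        assert sel == [100]

    def test_lower_1_percent_of_1_to_100(self):
        cutoff, sel = select_top(list(range(1, 101)), tail="lower", fraction=0.01)
        assert sel == [1]

    def test_all_equal_empty(self):
        _, sel = select_top([5.0] * 20, tail="upper", fraction=0.1)
        assert sel == []

    def test_inf_always_selected_upper(self):
        values = [1.0, 2.0, 3.0, math.inf]
        _, sel = select_top(values, tail="upper", fraction=0.25)
        assert math.inf in sel

    def test_nan_excluded(self):
        values = [1.0, 2.0, math.nan, 3.0, 4.0]
        cutoff, sel = select_top(values, tail="upper", fraction=0.25)
        assert not any(math.isnan(v) for v in sel)

    def test_too_few_defined_fatal(self):
        with pytest.raises(DataError):
            select_top([1.0, math.nan], tail="upper")

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1), st.integers(50, 400),
           st.sampled_from([0.01, 0.05, 0.1]))
    def test_count_within_one_of_fraction(self, seed, n, fraction):
        rng = np.random.default_rng(seed)
        values = rng.permutation(n).astype(float).tolist()  # distinct
        _, sel = select_top(values, tail="upper", fraction=fraction)
        assert abs(len(sel) - math.ceil(fraction * n)) <= 1


class TestIntersectWindows:
    def _rows(self, names):
        from sweepscan.model import WindowStatRow
        return [
            WindowStatRow(Window("1", ord(n) * 1000, ord(n) * 1000 + 40000),
                          1, 0, 0, 1, 0)
            for n in names
        ]

    def test_three_way(self):
        got = intersect_windows(self._rows("ABC"), self._rows("BCD"), self._rows("BE"))
        assert [w.start for w in got] == [ord("B") * 1000]

    def test_empty_input_empty_result(self):
        assert intersect_windows(self._rows("AB"), [], self._rows("AB")) == []

    def test_idempotent(self):
        rows = self._rows("ABC")
        got = intersect_windows(rows, rows, rows)
        assert [(w.chrom, w.start, w.end) for w in got] == sorted(
            (r.window.chrom, r.window.start, r.window.end) for r in rows
        )


class TestComputeWindowStats:
    def test_matches_per_window_functions(self, popmap_4):
        rng = np.random.default_rng(5)
        dosages = rng.integers(0, 3, size=(200, 4))
        gm = make_genotypes(dosages, spacing=50)
        windows = make_windows({"1": 10_000}, window_bp=4_000, step_bp=2_000)
        rows = compute_window_stats(gm, popmap_4, windows)
        assert len(rows) == len(windows)
        for row in rows:
            assert row.pi_hg == pytest.approx(
                window_pi(gm, popmap_4, row.window, "HG"), abs=1e-12
            )
            got = window_fst(gm, popmap_4, row.window)
            if math.isnan(row.fst):
                assert math.isnan(got)
            else:
                assert row.fst == pytest.approx(got, abs=1e-12)
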