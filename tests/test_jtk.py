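"""JTK_cycle statistic, exact null, scan and transcriptome summaries."""

import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circaflux import (ExprTruth, InvalidInputError, cpm_filter, deg_anova,
                       gen_expr_matrix, heatmap_matrix, jt_statistic,
                       jtk_null, jtk_references, jtk_scan, phase_day_night,
                       select_rhythmic, set_overlaps)
from conftest import cosine_gene


class TestCpmFilter:
    def test_boundary_and_zero_genes(self):
        mat = pd.DataFrame({f"s{i}": [1.0 if i < 3 else 0.0, 0.0, 5.0]
                            for i in range(6)}, index=["edge", "zero", "high"])
        kept, report = cpm_filter(mat, min_cpm=1.0, min_samples=3)
        assert list(kept.index) == ["edge", "high"]
        assert report == {"kept": 2, "dropped": 1, "min_cpm": 1.0,
                          "min_samples": 3}

    def test_matches_brute_force_comprehension(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.poisson(1.0, size=(40, 24)).astype(float),
                           index=[f"g{i}" for i in range(40)])
        kept, _ = cpm_filter(mat, 1.0, 3)
        oracle = {g for g in mat.index
                  if sum(v >= 1.0 for v in mat.loc[g]) >= 3}
        assert set(kept.index) == oracle


class TestReferences:
    def test_lag0_cosine_ordering(self, design_6x4):
        _, tvec, _ = design_6x4
        refs = jtk_references(tvec, 24.0)
        r0 = refs.ranks[0]
        assert refs.lags_h[0] == 0.0
        # t = 0 samples share the top rank, t = 12 the bottom
        assert np.all(r0[tvec == 0.0] == r0.max())
        assert np.all(r0[tvec == 12.0] == r0.min())

    def test_lag_shift_by_sampling_interval_is_cyclic(self, design_6x4):
        _, tvec, _ = design_6x4
        refs = jtk_references(tvec, 24.0)
        lag4 = refs.ranks[list(refs.lags_h).index(4.0)]
        # shifting timepoints by 4 h reproduces the lag-0 reference
        shifted = jtk_references((tvec - 4.0) % 24.0, 24.0).ranks[0]
        np.testing.assert_array_equal(lag4, shifted)

    def test_default_grid_has_12_lags(self, design_6x4):
        _, tvec, _ = design_6x4
        refs = jtk_references(tvec, 24.0)
        assert refs.lags_h.size == 12
        np.testing.assert_allclose(np.diff(refs.lags_h), 2.0)


class TestJTStatistic:
    def test_perfect_concordance_and_reversal(self):
        ref = np.array([1.0, 2, 3, 4, 5, 6])
        s, tau = jt_statistic(ref, ref)
        assert tau == 1.0
        s, tau = jt_statistic(ref[::-1], ref)
        assert tau == -1.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=8)
            ref = rng.integers(1, 4, size=8).astype(float)
            s, tau = jt_statistic(x, ref)
            s_oracle = sum(np.sign(x[j] - x[i]) * np.sign(ref[j] - ref[i])
                           for i in range(8) for j in range(i + 1, 8))
            m = sum(ref[i] != ref[j]
                    for i in range(8) for j in range(i + 1, 8))
            assert s == s_oracle
            if m:
                assert tau == pytest.approx(s_oracle / m)

    def test_all_tied_data_flagged(self):
        s, tau = jt_statistic(np.ones(6), np.arange(6.0))
        assert s == 0 and math.isnan(tau)


def _enumerate_null(ref):
    cnt = Counter()
    for perm in itertools.permutations(range(ref.size)):
        s, _ = jt_statistic(np.array(perm, dtype=float), ref)
        cnt[s] += 1
    total = sum(cnt.values())
    return {s: c / total for s, c in cnt.items()}


class TestJTKNull:
    def test_distinct_ranks_match_full_enumeration(self):
        ref = np.arange(1.0, 7.0)
        null = jtk_null(ref)
        oracle = _enumerate_null(ref)
        assert null.exact
        for s, p in zip(null.s_support, null.pmf):
            assert p == pytest.approx(oracle.get(int(s), 0.0), abs=1e-12)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 3), min_size=2, max_size=4)
           .filter(lambda g: sum(g) <= 8))
    def test_random_tie_structures_match_enumeration(self, groups):
        ref = np.concatenate([np.full(k, i, dtype=float)
                              for i, k in enumerate(groups)])
        null = jtk_null(ref)
        oracle = _enumerate_null(ref)
        for s, p in zip(null.s_support, null.pmf):
            assert p == pytest.approx(oracle.get(int(s), 0.0), abs=1e-12)

    def test_symmetry_and_normalization(self, design_6x4):
        _, tvec, _ = design_6x4
        ref = jtk_references(tvec, 24.0).ranks[0]
        null = jtk_null(ref)
        assert null.pmf.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(null.pmf, null.pmf[::-1], atol=1e-15)

    def test_normal_approximation_close_to_exact(self):
        ref = np.arange(30.0)
        exact = jtk_null(ref, exact_limit=50)
        approx = jtk_null(ref, exact_limit=10)
        assert not approx.exact
        for s in (40, 80, 120):
            assert approx.p_two_sided(s) == pytest.approx(
                exact.p_two_sided(s), rel=0.1)


class TestJTKScan:
    def test_noiseless_cosine_detected_with_correct_lag(self, design_6x4):
        samples, tvec, annot = design_6x4
        vals = cosine_gene(tvec, lag=6.0) + np.tile([0, .01, .02, .03], 6)
        mat = pd.DataFrame([vals], index=["cos6"], columns=samples)
        res = jtk_scan(mat, annot)
        assert res.loc["cos6", "adj_p"] < 0.01
        assert res.loc["cos6", "lag_h"] == 6.0

    def test_constant_gene_p_one(self, design_6x4):
        samples, _, annot = design_6x4
        mat = pd.DataFrame([np.full(24, 7.0)], index=["flat"], columns=samples)
        res = jtk_scan(mat, annot)
        assert res.loc["flat", "p"] == 1.0
        assert res.loc["flat", "amplitude"] == 0.0

    def test_lag_recovered_for_every_grid_lag(self, design_6x4):
        # exhaustive over the 12-lag grid, noiseless cosine each time
        samples, tvec, annot = design_6x4
        perturb = np.tile([0, .01, .02, .03], 6)
        rows, names = [], []
        for lag in np.arange(0.0, 24.0, 2.0):
            rows.append(cosine_gene(tvec, lag=lag) + perturb)
            names.append(f"lag{lag:g}")
        res = jtk_scan(pd.DataFrame(rows, index=names, columns=samples), annot)
        for lag, name in zip(np.arange(0.0, 24.0, 2.0), names):
            assert abs(res.loc[name, "lag_h"] - lag) <= 2.0 or \
                abs(res.loc[name, "lag_h"] - lag) >= 22.0  # circular slack
            assert res.loc[name, "adj_p"] < 0.01

    def test_flat_gene_adjusted_p_dominates_uniform(self):
        # conservative test: empirical CDF of adjusted p below the diagonal
        data = gen_expr_matrix(ExprTruth(n_genes=2000, frac_rhythmic=0.0,
                                         baseline_cpm=100.0, dispersion=0.1,
                                         seed=23))
        res = jtk_scan(data.counts, data.annot)
        for alpha in (0.01, 0.05, 0.1, 0.25):
            assert (res["adj_p"] <= alpha).mean() <= alpha + 0.01

    def test_amplitude_on_cpm_scale(self, design_6x4):
        samples, tvec, annot = design_6x4
        vals = cosine_gene(tvec, baseline=100.0, rel_amp=0.5, lag=4.0)
        mat = pd.DataFrame([vals], index=["g"], columns=samples)
        res = jtk_scan(mat, annot)
        # true peak-trough half-range at sampled phases is ~40-50 cpm
        assert 30.0 < res.loc["g", "amplitude"] < 55.0


class TestSelectRhythmic:
    def test_threshold_boundaries(self):
        res = pd.DataFrame({"adj_p": [0.005, 0.005, 0.02],
                            "amplitude": [12.0, 5.0, 12.0]},
                           index=["in", "low_amp", "high_p"])
        sel = select_rhythmic(res, p_max=0.01, amp_min=10.0)
        assert list(sel) == ["in"]

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(31)
        res = pd.DataFrame({"adj_p": rng.uniform(0, 1, 100),
                            "amplitude": rng.uniform(0, 30, 100)})
        base = set(select_rhythmic(res, 0.01, 10.0))
        assert base <= set(select_rhythmic(res, 0.05, 10.0))
        assert base <= set(select_rhythmic(res, 0.01, 5.0))

    def test_sensitivity_on_strong_synthetic_rhythms(self):
        truth = ExprTruth(n_genes=300, frac_rhythmic=0.5, rel_amplitude=0.5,
                          baseline_cpm=100.0, dispersion=0.02, seed=29)
        data = gen_expr_matrix(truth)
        res = jtk_scan(data.counts, data.annot)
        sel = set(select_rhythmic(res))
        rhythmic = set(data.truth.index[data.truth["is_rhythmic"]])
        sensitivity = len(sel & rhythmic) / len(rhythmic)
        assert sensitivity >= 0.9


class TestPhaseSummaries:
    def test_all_day_lags(self):
        s = phase_day_night(np.array([4.0, 6.0, 8.0]))
        assert s.day_fraction == 1.0 and s.night_fraction == 0.0

    def test_split_lags(self):
        s = phase_day_night(np.array([4.0, 18.0]))
        assert s.day_fraction == 0.5

    def test_boundary_12_counts_as_night(self):
        s = phase_day_night(np.array([12.0]))
        assert s.night_fraction == 1.0

    def test_uniform_lags_near_half(self):
        rng = np.random.default_rng(37)
        s = phase_day_night(rng.uniform(0, 24, 400))
        # binomial 95% band around 0.5 at n = 400
        assert abs(s.day_fraction - 0.5) < 1.96 * 0.5 / math.sqrt(400) + 1e-9

    def test_empty_flagged(self):
        s = phase_day_night(np.array([]))
        assert s.empty and math.isnan(s.day_fraction)

    def test_bin_counts_cover_all(self):
        s = phase_day_night(np.array([1.0, 3.0, 13.0]), bin_h=2.0)
        assert s.bin_counts.sum() == 3
        assert s.bin_counts.size == 12


class TestSetOverlaps:
    def test_three_set_example(self):
        venn = set_overlaps({"A": {"a", "b", "c"}, "B": {"b", "c", "d"},
                             "C": {"c", "e"}})
        assert venn[("A", "B", "C")] == 1
        assert venn[("A", "B")] == 1      # {b}
        assert venn[("A",)] == 1          # {a}
        assert venn[("C",)] == 1          # {e}

    def test_disjoint_sets(self):
        venn = set_overlaps({"A": {1, 2}, "B": {3}, "C": {4}})
        assert venn[("A", "B")] == 0 and venn[("A", "B", "C")] == 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_region_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sets = {k: set(rng.integers(0, 20, size=rng.integers(0, 12)).tolist())
                for k in "ABC"}
        venn = set_overlaps(sets)
        universe = set().union(*sets.values())
        for combo, count in venn.items():
            members = {e for e in universe
                       if all((e in sets[k]) == (k in combo) for k in sets)}
            assert count == len(members)

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(InvalidInputError):
            set_overlaps({"A": {1}})


class TestHeatmapMatrix:
    def _setup(self, design):
        samples, tvec, annot = design
        mat = pd.DataFrame(
            [cosine_gene(tvec, lag=4.0), cosine_gene(tvec, lag=16.0),
             np.full(24, 3.0)],
            index=["early", "late", "flat"], columns=samples)
        res = pd.DataFrame({"lag_h": [16.0, 4.0, 0.0]},
                           index=["late", "early", "flat"])
        return mat, annot, res

    def test_scaling_to_unit_interval(self, design_6x4):
        mat, annot, res = self._setup(design_6x4)
        hm = heatmap_matrix(mat, annot, res, ["early", "late"])
        assert hm.to_numpy().max() == pytest.approx(1.0)
        assert hm.to_numpy().min() == pytest.approx(-1.0)

    def test_rows_sorted_by_lag(self, design_6x4):
        mat, annot, res = self._setup(design_6x4)
        hm = heatmap_matrix(mat, annot, res, ["late", "early"])
        assert list(hm.index) == ["early", "late"]

    def test_argmax_preserved_and_constant_zeroed(self, design_6x4):
        mat, annot, res = self._setup(design_6x4)
        hm = heatmap_matrix(mat, annot, res, ["early", "flat"])
        assert hm.loc["early"].to_numpy().argmax() == 1  # peak at t = 4
        np.testing.assert_array_equal(hm.loc["flat"].to_numpy(), 0.0)

    def test_empty_selection_rejected(self, design_6x4):
        mat, annot, res = self._setup(design_6x4)
        with pytest.raises(InvalidInputError):
            heatmap_matrix(mat, annot, res, [])


class TestDegAnova:
    def _cond(self, tvec, samples, shift=0.0, seed=0, n_genes=5):
        rng = np.random.default_rng(seed)
        rows = [cosine_gene(tvec, baseline=100.0 + shift)
                + rng.normal(0, 1.0, tvec.size) for _ in range(n_genes)]
        mat = pd.DataFrame(rows, index=[f"g{i}" for i in range(n_genes)],
                           columns=samples)
        return mat

    def test_identical_conditions_not_selected(self, design_6x4):
        samples, tvec, annot = design_6x4
        mat = self._cond(tvec, samples, seed=1)
        res = deg_anova({"A": (mat, annot), "B": (mat.copy(), annot)})
        assert res.selected == set()

    def test_large_shift_selected(self, design_6x4):
        samples, tvec, annot = design_6x4
        a = self._cond(tvec, samples, seed=2)
        b = self._cond(tvec, samples, shift=200.0, seed=3)
        res = deg_anova({"A": (a, annot), "B": (b, annot)})
        assert res.selected == set(a.index)
        assert res.degs_by_pair[("A", "B")] == set(a.index)

    def test_anova_p_matches_closed_form_toy(self, design_6x4):
        # three condition profiles (6 timepoints each); replicates within a
        # timepoint identical, so the mean profile is the stated toy vector
        profiles = [np.array([1.0, 2, 3, 2, 1, 2]),
                    np.array([2.0, 3, 4, 3, 2, 3]),
                    np.array([6.0, 7, 8, 7, 6, 7])]
        samples, tvec, annot = design_6x4
        mats = {}
        for label, prof in zip("ABC", profiles):
            vals = np.repeat(prof, 4)
            mats[label] = (pd.DataFrame([vals], index=["g0"],
                                        columns=samples), annot)
        res = deg_anova(mats, p_anova=0.5)
        # textbook one-way ANOVA sums of squares on the profiles
        grand = np.concatenate(profiles).mean()
        ss_between = sum(6 * (p.mean() - grand) ** 2 for p in profiles)
        ss_within = sum(((p - p.mean()) ** 2).sum() for p in profiles)
        f_closed = (ss_between / 2) / (ss_within / 15)
        from scipy.stats import f as fdist
        assert res.anova_p["g0"] == pytest.approx(float(fdist.sf(f_closed, 2, 15)))

    def test_single_condition_rejected(self, design_6x4):
        samples, _, annot = design_6x4
        mat = pd.DataFrame(np.ones((2, 24)), columns=samples)
        with pytest.raises(InvalidInputError):
            deg_anova({"A": (mat, annot)})
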