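import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tmsmap.map_model import GridSpec
from tmsmap.map_parameters import ParameterSpec
from tmsmap.session_stats import (
    CensoredSample,
    SignificanceDiagram,
    bicc,
    change_diagram,
    discriminate_sessions,
    gehan_test,
    histogram_overlap,
    page_trend_test,
    within_session_diagram,
)
from tmsmap.synthetic_data import (
    DriftSpec,
    default_surface,
    simulate_multisession,
    simulate_session,
)

from conftest import make_map


def censored_sample(observed, n_censored=0):
    return CensoredSample(np.asarray(observed, dtype=float), n_censored)


class TestGehanTest:
    def test_identical_samples(self):
        a = censored_sample([100, 200, 300])
        w, p = gehan_test(a, a)
        assert w == 0
        assert p == 1.0

    def test_fully_separated_censored_vs_observed(self):
        # all C(10,5)=252 assignments enumerable; only the two extreme
        # assignments reach |W| = 25
        a = censored_sample([], n_censored=5)
        b = censored_sample([100, 110, 120, 130, 140])
        result = gehan_test(a, b)
        assert result.statistic == -25
        assert result.method == "exact"
        assert result.p_value == pytest.approx(2 / 252)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = censored_sample(rng.uniform(50, 500, 6), n_censored=2)
        b = censored_sample(rng.uniform(50, 800, 4), n_censored=3)
        r_ab = gehan_test(a, b)
        r_ba = gehan_test(b, a)
        assert r_ab.statistic == -r_ba.statistic
        assert r_ab.p_value == pytest.approx(r_ba.p_value)

    def test_censored_pairs_indeterminate(self):
        # two all-censored samples carry no ordering information
        a = censored_sample([], n_censored=4)
        b = censored_sample([], n_censored=4)
        w, p = gehan_test(a, b)
        assert w == 0
        assert p == 1.0

    def test_equals_mann_whitney_without_censoring(self):
        # oracle: on fully observed data W = U1 - U2 of the Mann-Whitney test
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.uniform(50, 500, rng.integers(3, 8))
            y = rng.uniform(50, 500, rng.integers(3, 8))
            w, _ = gehan_test(censored_sample(x), censored_sample(y))
            u1 = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
            u2 = len(x) * len(y) - u1
            assert w == pytest.approx(u1 - u2)

    def test_montecarlo_close_to_exact(self):
        rng = np.random.default_rng(2)
        a = censored_sample([60, 80, 100, 400, 500], n_censored=1)
        b = censored_sample([55, 70, 90], n_censored=3)
        exact = gehan_test(a, b, method="exact")
        mc = gehan_test(a, b, method="montecarlo", n_permutations=20_000, rng=rng)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            CensoredSample(np.array([]), 0)

    def test_type_one_error_controlled(self):
        # permutation validity: under the null, P(p < alpha) <= alpha (+2 SE)
        rng = np.random.default_rng(3)
        n_rep, alpha = 500, 0.05
        rejections = 0
        for _ in range(n_rep):
            amps = rng.lognormal(4.5, 1.0, 10)
            sample = [
                censored_sample(half[half >= 50], int((half < 50).sum()))
                for half in (amps[:5], amps[5:])
            ]
            if gehan_test(sample[0], sample[1]).p_value < alpha:
                rejections += 1
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert rejections / n_rep <= alpha + 2 * se


class TestDiagrams:
    def _noisy_map(self, seed, n=10):
        grid = GridSpec(n_rows=3, n_cols=3, cell_side_mm=1.0)
        return simulate_session(
            default_surface(grid, sigma_mm=3.0), grid, n, np.random.default_rng(seed)
        )

    def test_self_comparison_all_zero(self):
        m = self._noisy_map(0)
        diagram = change_diagram(m, m)
        assert diagram.matrix.shape == (3, 3)
        assert np.all(diagram.matrix == 0)

    def test_single_changed_cell_flagged_positive(self):
        grid = GridSpec(n_rows=2, n_cols=2, cell_side_mm=1.0)
        base = {key: [100.0, 120.0, 90.0, 110.0, 105.0] for key in grid.cell_keys()}
        changed = dict(base)
        changed[(1, 1)] = [500.0, 600.0, 700.0, 800.0, 900.0]
        a = make_map({k: v for k, v in base.items()}, grid=grid)
        a.cells[(1, 1)] = [
            type(a.cells[(0, 0)][0])(0.0, True) for _ in range(5)
        ]  # all censored in first session
        b = make_map(changed, grid=grid)
        diagram = change_diagram(a, b, n_per_cell=5, alpha=0.05)
        assert diagram.matrix[1, 1] == 1
        assert diagram.n_significant() == 1

    def test_direction_convention(self):
        grid = GridSpec(n_rows=1, n_cols=1, cell_side_mm=1.0)
        low = make_map({(0, 0): [0.0] * 5}, grid=grid)
        high = make_map({(0, 0): [500.0, 600.0, 700.0, 800.0, 900.0]}, grid=grid)
        assert change_diagram(low, high).matrix[0, 0] == 1
        assert change_diagram(high, low).matrix[0, 0] == -1

    def test_grid_mismatch_rejected(self):
        a = make_map({(0, 0): [100.0] * 5})
        b = make_map(
            {(0, 0): [100.0] * 5, (0, 1): [100.0] * 5},
            grid=GridSpec(n_rows=1, n_cols=2, cell_side_mm=1.0),
        )
        with pytest.raises(ValueError):
            change_diagram(a, b)

    def test_within_session_deterministic_map_all_zero(self):
        grid = GridSpec(n_rows=2, n_cols=2, cell_side_mm=1.0)
        m = make_map({key: [200.0] * 10 for key in grid.cell_keys()}, grid=grid)
        diagram = within_session_diagram(m)
        assert diagram.matrix.shape == (2, 2)
        assert np.all(diagram.matrix == 0)

    def test_within_session_requires_ten_samples(self):
        m = make_map({(0, 0): [100.0] * 9})
        with pytest.raises(ValueError, match=r"\(0, 0\)"):
            within_session_diagram(m)

    def test_null_false_positive_rate(self):
        # both halves i.i.d. -> nonzero fraction bounded by alpha
        n_maps, alpha = 60, 0.05
        total, nonzero = 0, 0
        for seed in range(n_maps):
            m = self._noisy_map(1000 + seed)
            diagram = within_session_diagram(m, alpha=alpha)
            total += diagram.matrix.size
            nonzero += diagram.n_significant()
        rate = nonzero / total
        se = np.sqrt(alpha * (1 - alpha) / total)
        assert rate <= alpha + 2 * se

    def test_entries_restricted(self):
        with pytest.raises(ValueError):
            SignificanceDiagram(np.array([[2]]), 0.05, "x")


class TestHistogramOverlap:
    def test_identity_and_disjoint(self):
        assert histogram_overlap([1, 2, 3], [1, 2, 3]) == 1.0
        assert histogram_overlap([0.0, 1.0], [5.0, 6.0]) == 0.0

    def test_uniform_half_overlap(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, 100_000)
        b = rng.uniform(0.5, 1.5, 100_000)
        # bins aligned to multiples of 0.5 -> analytic overlap is 0.5
        assert histogram_overlap(a, b, n_bins=30) == pytest.approx(0.5, abs=0.05)

    def test_n_bins_validation(self):
        with pytest.raises(ValueError):
            histogram_overlap([1, 2], [3, 4], n_bins=1)

    @given(
        a=st.lists(st.floats(-100, 100), min_size=1, max_size=30),
        b=st.lists(st.floats(-100, 100), min_size=1, max_size=30),
    )
    @settings(max_examples=40, deadline=None)
    def test_symmetry_and_range(self, a, b):
        o_ab = histogram_overlap(a, b)
        o_ba = histogram_overlap(b, a)
        assert 0.0 <= o_ab <= 1.0 + 1e-9
        assert o_ab == pytest.approx(o_ba)

    def test_affine_invariance(self):
        # continuous data keeps values off the bin edges, where exact
        # invariance cannot hold under floating-point rescaling
        rng = np.random.default_rng(44)
        a = rng.normal(size=300)
        b = rng.normal(loc=0.7, size=200)
        o = histogram_overlap(a, b)
        for scale, shift in [(0.3, 12.0), (25.0, -4.5)]:
            assert histogram_overlap(scale * a + shift, scale * b + shift) == (
                pytest.approx(o, abs=1e-9)
            )


class TestBICC:
    def test_constant_distinct_groups(self):
        assert bicc([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]) == 1.0

    def test_iid_groups_near_zero(self):
        rng = np.random.default_rng(5)
        values = [np.abs(bicc([rng.normal(size=1000) for _ in range(3)]))
                  for _ in range(100)]
        assert np.median(values) < 0.05
        assert np.mean(np.asarray(values) < 0.05) > 0.5

    def test_equal_variance_components_give_half(self):
        # E[MSB] = n σb² + σw², E[MSW] = σw² -> ICC -> 0.5 when σb = σw;
        # many groups are needed for MSB to concentrate
        rng = np.random.default_rng(6)
        n, n_groups = 2000, 20
        estimates = []
        for _ in range(30):
            groups = [
                rng.normal(loc=rng.normal(), scale=1.0, size=n)
                for _ in range(n_groups)
            ]
            estimates.append(bicc(groups))
        assert np.median(estimates) == pytest.approx(0.5, abs=0.07)

    def test_matches_anova_identity(self):
        # oracle: recompute from scipy one-way ANOVA mean squares
        rng = np.random.default_rng(7)
        groups = [rng.normal(loc=mu, size=50) for mu in (0.0, 0.5, 1.2)]
        data = np.vstack(groups)
        n = data.shape[1]
        grand = data.mean()
        msb = n * ((data.mean(axis=1) - grand) ** 2).sum() / (data.shape[0] - 1)
        msw = ((data - data.mean(axis=1, keepdims=True)) ** 2).sum() / (
            data.shape[0] * (n - 1)
        )
        expected = (msb - msw) / (msb + (n - 1) * msw)
        assert bicc(groups) == pytest.approx(expected)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(loc=mu, size=20) for mu in (0, 1, 2)]
        assert bicc(groups) == pytest.approx(bicc(groups[::-1]))

    def test_identical_values_undefined(self):
        with pytest.raises(ValueError):
            bicc([[1.0, 1.0], [1.0, 1.0]])

    def test_unequal_groups_rejected(self):
        with pytest.raises(ValueError):
            bicc([[1.0, 2.0], [1.0, 2.0, 3.0]])


class TestPageTrendTest:
    def test_two_blocks_perfectly_ordered(self):
        L, p = page_trend_test(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        assert L == 28
        assert p == pytest.approx((1 / 6) ** 2)

    def test_direction_reversal_symmetry(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(4, 5)) + np.arange(5)
        L_inc, p_inc = page_trend_test(data, direction="increasing")
        _, p_dec = page_trend_test(data[:, ::-1], direction="decreasing")
        assert p_inc == pytest.approx(p_dec)

    def test_strictly_decreasing_cv_trend(self):
        # 10 blocks of strictly decreasing values -> maximal L, p < 0.001
        data = np.tile(np.linspace(1.0, 0.1, 10), (10, 1))
        _, p = page_trend_test(data, direction="decreasing")
        assert p < 1e-3

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(10)
        data = rng.normal(size=(4, 4))
        L, p = page_trend_test(data, method="exact")
        res = sps.page_trend_test(data, method="exact")
        assert L == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(11)
        data = rng.normal(size=(6, 8)) + 0.4 * np.arange(8)
        L, p = page_trend_test(data, method="asymptotic")
        res = sps.page_trend_test(data, method="asymptotic")
        assert L == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)

    def test_exact_handles_ties_with_midranks(self):
        data = np.array([[1.0, 1.0, 2.0], [1.0, 2.0, 3.0]])
        L, p = page_trend_test(data, method="exact")
        assert 0 < p <= 1
        # mid-ranks: first block contributes (1.5, 1.5, 3)
        assert L == pytest.approx(1 * (1.5 + 1) + 2 * (1.5 + 2) + 3 * (3 + 3))

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            page_trend_test(np.array([[1.0, 2.0]]))


class TestDiscriminateSessions:
    GRID = GridSpec(n_rows=3, n_cols=3, cell_side_mm=7.63)

    def test_identical_replicated_maps_near_zero_bicc(self):
        # the strict null: three copies of one session differ only by
        # bootstrap noise -> BICC ~ 0, overlaps at their self-overlap level
        m = simulate_session(
            default_surface(self.GRID), self.GRID, 10, np.random.default_rng(12)
        )
        triple = []
        for i in range(3):
            clone = make_map({}, grid=self.GRID, session_id=f"d{i + 1}")
            clone.cells = dict(m.cells)
            triple.append(clone)
        disc = discriminate_sessions(
            triple,
            ParameterSpec("weighted_area", "probability"),
            k=10,
            B=1000,
            rng=np.random.default_rng(13),
        )
        assert abs(disc.bicc) < 0.05
        self_overlap = np.mean(
            [
                histogram_overlap(
                    np.random.default_rng(20 + i).normal(size=1000),
                    np.random.default_rng(30 + i).normal(size=1000),
                )
                for i in range(3)
            ]
        )
        for overlap in disc.pairwise_overlaps.values():
            assert overlap > self_overlap - 0.15

    def test_large_gain_drift_separates_sessions(self):
        surface = default_surface(self.GRID)
        drift = DriftSpec(gain_shift_log=2.5, mode="drift")
        ss = simulate_multisession(
            surface, drift, 3, self.GRID, 10, np.random.default_rng(14)
        )
        disc = discriminate_sessions(
            ss.maps_for_subject("sim"),
            ParameterSpec("weighted_area", "amplitude"),
            k=10,
            B=500,
            rng=np.random.default_rng(15),
        )
        assert disc.bicc > 0.9
        assert min(disc.pairwise_overlaps.values()) < 0.05

    def test_session_relabeling_invariance(self):
        m1 = simulate_session(
            default_surface(self.GRID), self.GRID, 10, np.random.default_rng(16),
            session_id="d1",
        )
        m2 = simulate_session(
            default_surface(self.GRID), self.GRID, 10, np.random.default_rng(17),
            session_id="d2",
        )
        m3 = simulate_session(
            default_surface(self.GRID), self.GRID, 10, np.random.default_rng(18),
            session_id="d3",
        )
        spec = ParameterSpec("weighted_area", "probability")
        d_fwd = discriminate_sessions(
            [m1, m2, m3], spec, 5, 400, np.random.default_rng(19)
        )
        d_rev = discriminate_sessions(
            [m3, m2, m1], spec, 5, 400, np.random.default_rng(19)
        )
        assert d_fwd.bicc == pytest.approx(d_rev.bicc, abs=0.1)
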