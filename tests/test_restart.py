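"""Delta/delta bias, restart-fraction mapping, progression, comparison."""

import numpy as np
import pytest

from forkrestart import (
    AnalysisWindows,
    ComparisonError,
    ParameterError,
    ProgressionEstimate,
    ProgressionUndefinedError,
    RestartEstimate,
    Track,
    WindowError,
    bias_to_restart_fraction,
    compare_strains,
    delta_delta_bias,
    estimate_baseline,
    estimate_progression,
    estimate_restart,
)
from .conftest import mixture_usage


def bias_from_values(values, bin_width=50, mask=None):
    return Track(ref_name="c", bin_width=bin_width, start=0, values=values, mask=mask)


class TestDeltaDeltaBias:
    @pytest.mark.parametrize("uw, uc, expected", [
        (1.0, 1.0, 1.0),   # both strands fully delta: restarted synthesis
        (0.0, 1.0, 0.5),   # canonical rightward fork: leading eps Watson, lagging delta Crick
        (0.6, 0.8, 0.7),
    ])
    def test_mean_of_strand_usages(self, uw, uc, expected):
        u = mixture_usage(0.0, n_bins=10, barrier_bin=10)
        u.u_delta_watson.values[:] = uw
        u.u_delta_crick.values[:] = uc
        b = delta_delta_bias(u)
        assert b.values[0] == pytest.approx(expected)

    def test_mask_propagates_from_either_strand(self):
        u = mixture_usage(0.0, n_bins=4, barrier_bin=4)
        u.u_delta_watson.mask[1] = True
        u.u_delta_crick.mask[2] = True
        b = delta_delta_bias(u)
        assert list(b.mask) == [False, True, True, False]


class TestBiasMapping:
    def test_full_bias_is_full_restart(self):
        assert bias_to_restart_fraction(1.0, 0.5) == pytest.approx(1.0)

    def test_canonical_bias_is_no_restart(self):
        assert bias_to_restart_fraction(0.5, 0.5) == pytest.approx(0.0)

    def test_linear_midpoint(self):
        assert bias_to_restart_fraction(0.75, 0.5) == pytest.approx(0.5)

    def test_below_baseline_clips_to_zero(self):
        assert bias_to_restart_fraction(0.4, 0.5) == 0.0

    @pytest.mark.parametrize("b0", [1.0, 1.5, -0.1])
    def test_invalid_baseline_rejected(self, b0):
        with pytest.raises(ParameterError):
            bias_to_restart_fraction(0.8, b0)


class TestAnalysisWindows:
    def test_baseline_must_be_upstream(self):
        with pytest.raises(WindowError):
            AnalysisWindows(barrier_pos=30_000, baseline_window=(29_000, 31_000),
                            proximal_window=(30_500, 32_500), progression_range=20_000)

    def test_proximal_must_be_downstream(self):
        with pytest.raises(WindowError):
            AnalysisWindows(barrier_pos=30_000, baseline_window=(20_000, 28_000),
                            proximal_window=(29_000, 32_500), progression_range=20_000)


class TestEstimateBaseline:
    def test_constant_bias(self, default_windows):
        b = bias_from_values(np.full(1200, 0.5))
        est = estimate_baseline(b, default_windows, seed=0)
        assert est.value == pytest.approx(0.5)
        assert est.ci_low == pytest.approx(0.5)
        assert est.ci_high == pytest.approx(0.5)

    def test_fully_masked_window_rejected(self, default_windows):
        b = bias_from_values(np.full(1200, 0.5), mask=np.ones(1200, bool))
        with pytest.raises(WindowError):
            estimate_baseline(b, default_windows, seed=0)


class TestEstimateRestart:
    def test_noiseless_mixture_recovers_weight_exactly(self, default_windows):
        # exact identity: an r : (1-r) mixture of delta/delta and canonical
        # provenance must return f = r
        for r in (0.0, 0.25, 0.5, 0.75, 1.0):
            bias = delta_delta_bias(mixture_usage(r))
            est = estimate_restart(bias, default_windows, n_boot=50, seed=0)
            assert est.f == pytest.approx(r, abs=1e-9)

    def test_degenerate_full_bias_collapses_ci(self, default_windows):
        vals = np.full(1200, 0.5)
        vals[600:] = 1.0
        est = estimate_restart(bias_from_values(vals), default_windows, n_boot=200, seed=1)
        assert est.f == pytest.approx(1.0)
        assert est.ci_low == pytest.approx(1.0)
        assert est.ci_high == pytest.approx(1.0)

    def test_seed_reproducible(self, default_windows):
        rng = np.random.default_rng(42)
        vals = 0.5 + 0.05 * rng.standard_normal(1200)
        vals[600:] += 0.3
        b = bias_from_values(vals)
        e1 = estimate_restart(b, default_windows, n_boot=300, seed=7)
        e2 = estimate_restart(b, default_windows, n_boot=300, seed=7)
        assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)
        e3 = estimate_restart(b, default_windows, n_boot=300, seed=8)
        assert (e1.ci_low, e1.ci_high) != (e3.ci_low, e3.ci_high)


class TestEstimateProgression:
    def test_linear_decay_half_distance(self):
        # b(x) = b0 + delta0 * max(0, 1 - x/L) downstream -> d_half = L/2
        L = 10_000
        b0, delta0 = 0.5, 0.4
        win = AnalysisWindows(barrier_pos=30_000, baseline_window=(20_000, 28_000),
                              proximal_window=(30_000, 30_100), progression_range=20_000)
        centers = np.arange(1200) * 50 + 25.0
        x = centers - 30_000
        vals = np.where(x < 0, b0, b0 + delta0 * np.clip(1 - x / L, 0, 1))
        est = estimate_progression(bias_from_values(vals), win, b0=b0, b_prox=b0 + delta0)
        assert est.censored is False
        assert est.d_half == pytest.approx(L / 2, abs=50)

    def test_sustained_increment_censors(self, default_windows):
        vals = np.full(1200, 0.5)
        vals[600:] = 0.9
        est = estimate_progression(bias_from_values(vals), default_windows, b0=0.5)
        assert est.censored is True
        assert est.d_half == default_windows.progression_range

    def test_no_increment_is_undefined(self, default_windows):
        vals = np.full(1200, 0.5)
        with pytest.raises(ProgressionUndefinedError):
            estimate_progression(bias_from_values(vals), default_windows, b0=0.5)


def _estimates(f, d_half, windows, censored=False):
    rest = RestartEstimate(b0=0.5, b_prox=0.5 + f / 2, f=f, ci_low=f, ci_high=f,
                           windows=windows)
    prog = ProgressionEstimate(delta0=f / 2, d_half=d_half, censored=censored)
    return rest, prog


class TestCompareStrains:
    def test_identity(self, default_windows):
        a = _estimates(0.8, 9_000, default_windows)
        cmp = compare_strains(a, a)
        assert cmp.relative_restart == pytest.approx(1.0)
        assert cmp.relative_progression == pytest.approx(1.0)

    def test_half_restart(self, default_windows):
        ref = _estimates(0.8, 9_000, default_windows)
        mut = _estimates(0.4, 9_000, default_windows)
        assert compare_strains(ref, mut).relative_restart == pytest.approx(0.5)

    def test_zero_reference_rejected(self, default_windows):
        ref = _estimates(0.0, 9_000, default_windows)
        mut = _estimates(0.4, 9_000, default_windows)
        with pytest.raises(ComparisonError):
            compare_strains(ref, mut)

    def test_censoring_flags_propagate(self, default_windows):
        ref = _estimates(0.8, 20_000, default_windows, censored=True)
        mut = _estimates(0.8, 9_000, default_windows)
        cmp = compare_strains(ref, mut)
        assert cmp.ref_censored and not cmp.mut_censored
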