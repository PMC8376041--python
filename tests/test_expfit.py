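"""Multi-exponential fitting: recovery, canonical order, nesting, features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryograd import (
    MultiExpParams,
    compute_features,
    eval_model,
    fit_profile,
    generate_profile,
    select_model,
)
from embryograd.expfit import (
    ExpComponent,
    MultiExpFit,
    multiexp,
    order_components,
)
from embryograd.profiles import AxisProfile
from embryograd.synthetic import NoiseSpec

X = np.arange(0.0, 101.0)


def make_fit(comps, kind="2exp", background=0.0, window=(10.0, 90.0)):
    return MultiExpFit(
        kind=kind,
        components=[ExpComponent(*c) for c in comps],
        background=background,
        window=window,
        converged=True,
    )


class TestEvalModel:
    def test_sum_at_origin(self):
        fit = make_fit([(100.0, -0.2), (10.0, -0.01)])
        assert eval_model(fit, np.array([0.0]))[0] == pytest.approx(110.0)

    def test_zero_amplitude_1expB_is_constant_background(self):
        fit = make_fit([(1e-300, -0.1)], kind="1expB", background=5.0)
        np.testing.assert_allclose(eval_model(fit, X), 5.0)

    def test_matches_direct_formula(self):
        fit = make_fit([(120.0, -0.15), (8.0, -0.02)])
        mid = np.array([50.0])
        direct = 120.0 * np.exp(-0.15 * 50) + 8.0 * np.exp(-0.02 * 50)
        assert eval_model(fit, mid)[0] == pytest.approx(direct, rel=1e-14)


class TestFitProfile:
    def test_noiseless_1expB_recovery(self):
        prof = generate_profile(MultiExpParams([(100.0, -0.1)]), X)
        fit = fit_profile(prof, "1expB", (10, 90))
        c = fit.anterior
        assert abs(c.c0 - 100.0) / 100.0 < 1e-6
        assert abs(c.alpha + 0.1) < 1e-8
        assert abs(fit.background) < 1e-6
        assert fit.converged

    def test_noiseless_2exp_recovery_and_gridsearch_oracle(self):
        prof = generate_profile(MultiExpParams([(200.0, -0.2), (20.0, -0.01)]), X)
        fit = fit_profile(prof, "2exp", (10, 90))
        np.testing.assert_allclose(fit.c0, [200.0, 20.0], rtol=1e-4)
        np.testing.assert_allclose(fit.alpha, [-0.2, -0.01], rtol=1e-4)
        # independent oracle: dense (alpha1, alpha2) grid with linear C-solve
        sel = (prof.positions >= 10) & (prof.positions <= 90)
        x, y = prof.positions[sel], prof.intensities[sel]
        best = np.inf
        for a1 in np.linspace(-0.4, -0.1, 31):
            for a2 in np.linspace(-0.05, -0.002, 25):
                A = np.column_stack([np.exp(a1 * x), np.exp(a2 * x)])
                coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
                sse = float(np.sum((A @ coef - y) ** 2))
                best = min(best, sse)
        assert fit.sse <= best + 1e-9

    def test_posterior_rise_needs_third_component(self):
        params = MultiExpParams([(100.0, -0.15), (10.0, -0.01), (0.5, 0.05)])
        prof = generate_profile(params, X, NoiseSpec(additive_sd=0.5, seed=3))
        fit3 = fit_profile(prof, "3exp", (10, 80))
        fit2 = fit_profile(prof, "2exp", (10, 80))
        assert fit3.components[-1].alpha > 0
        assert fit3.sse < fit2.sse

    def test_too_few_points_rejected(self):
        prof = AxisProfile(np.array([10.0, 20, 30, 40]), np.ones(4))
        with pytest.raises(ValueError):
            fit_profile(prof, "2exp", (10, 90))

    def test_all_zero_rejected(self):
        prof = AxisProfile(X, np.zeros_like(X))
        with pytest.raises(ValueError):
            fit_profile(prof, "2exp", (10, 90))

    def test_missing_samples_skipped(self):
        y = multiexp(X, [100.0], [-0.1])
        y[20:40] = np.nan
        prof = AxisProfile(X, y)
        fit = fit_profile(prof, "1expB", (10, 90))
        assert fit.n_points == np.isfinite(y[(X >= 10) & (X <= 90)]).sum()
        assert abs(fit.anterior.alpha + 0.1) < 1e-6

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(k=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_equivariance(self, k):
        # C0 scales with the data; alpha does not
        prof = generate_profile(
            MultiExpParams([(100.0, -0.1), (10.0, -0.008)]),
            X,
            NoiseSpec(additive_sd=2.0, seed=11),
        )
        scaled = AxisProfile(prof.positions, prof.intensities * k)
        f1 = fit_profile(prof, "2exp", (10, 90))
        f2 = fit_profile(scaled, "2exp", (10, 90))
        np.testing.assert_allclose(f2.c0, k * f1.c0, rtol=1e-8)
        np.testing.assert_allclose(f2.alpha, f1.alpha, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sse_nesting_on_noisy_profiles(self, seed):
        # 1expB is the alpha2=0 boundary of 2exp; 2exp the C3=0 boundary of 3exp
        prof = generate_profile(
            MultiExpParams([(100.0, -0.1), (10.0, -0.008)]),
            X,
            NoiseSpec(additive_sd=2.0, seed=seed),
        )
        s1 = fit_profile(prof, "1expB", (10, 90)).sse
        s2 = fit_profile(prof, "2exp", (10, 90)).sse
        s3 = fit_profile(prof, "3exp", (10, 90)).sse
        assert s2 <= s1 * (1 + 1e-9)
        assert s3 <= s2 * (1 + 1e-9)

    def test_lambda_alpha_consistency(self):
        prof = generate_profile(MultiExpParams([(50.0, -0.07), (5.0, -0.005)]), X)
        fit = fit_profile(prof, "2exp", (10, 90))
        for c in fit.components:
            assert c.lam == np.exp(c.alpha)


class TestOrderComponents:
    def test_swaps_shallow_first(self):
        fit = make_fit([(10.0, -0.01), (100.0, -0.2)])
        ordered = order_components(fit)
        assert ordered.anterior.c0 == 100.0

    def test_tie_broken_by_steeper_alpha(self):
        lo = 10.0
        # equal contributions at the window start
        c_steep = 100.0
        c_shallow = c_steep * np.exp(-0.2 * lo) / np.exp(-0.01 * lo)
        fit = make_fit([(c_shallow, -0.01), (c_steep, -0.2)])
        ordered = order_components(fit)
        assert ordered.anterior.alpha == -0.2

    def test_rising_component_always_last(self):
        fit = make_fit(
            [(1000.0, 0.05), (100.0, -0.2), (10.0, -0.01)], kind="3exp"
        )
        ordered = order_components(fit)
        assert ordered.components[-1].alpha == 0.05
        assert ordered.anterior.alpha == -0.2


class TestSelectModel:
    def test_pure_two_component_selects_2exp(self):
        prof = generate_profile(
            MultiExpParams([(100.0, -0.15), (10.0, -0.01)]),
            X,
            NoiseSpec(additive_sd=1.0, seed=5),
        )
        assert select_model(prof, (10, 90)) == "2exp"

    def test_strong_posterior_rise_selects_3exp(self):
        params = MultiExpParams([(100.0, -0.15), (5.0, -0.01), (0.2, 0.07)])
        prof = generate_profile(params, X, NoiseSpec(additive_sd=0.2, seed=6))
        assert select_model(prof, (10, 80)) == "3exp"

    def test_flat_profile_rejection_propagates(self):
        prof = AxisProfile(X, np.zeros_like(X))
        with pytest.raises(ValueError):
            select_model(prof, (10, 90))


class TestFeatures:
    def test_cab_log_ratio(self):
        fa = make_fit([(2.0, -0.1), (1.0, -0.01)])
        fb = make_fit([(1.0, -0.1), (1.0, -0.01)])
        fv = compute_features(fa, fb)
        assert fv.cab == pytest.approx(np.log(2.0), rel=1e-12)

    def test_identical_layers_give_identity_features(self):
        f = make_fit([(100.0, -0.1), (10.0, -0.01)])
        fv = compute_features(f, f)
        assert fv.cab == 0.0
        assert fv.shallow_ratio == pytest.approx(1.0)

    def test_early1_early2_ratio_ordering_preserved(self):
        # apical:basal anterior ratios 1.487 (Early1) vs 2.678 (Early2)
        def pair(ratio):
            fa = make_fit([(100.0 * ratio, -0.05), (10.0, -0.01)])
            fb = make_fit([(100.0, -0.05), (10.0, -0.01)])
            return compute_features(fa, fb)

        assert pair(2.678).cab > pair(1.487).cab > 0

    def test_missing_shallow_flagged_nan(self):
        fa = make_fit([(100.0, -0.1), (10.0, -0.01)])
        fb = make_fit([(100.0, -0.1), (10.0, 0.0)])  # boundary: no slope info
        fv = compute_features(fa, fb)
        assert not fv.has_shallow and np.isnan(fv.shallow_ratio)

    def test_features_invariant_under_common_rescaling(self):
        prof_a = generate_profile(
            MultiExpParams([(100.0, -0.1), (10.0, -0.008)]),
            X,
            NoiseSpec(additive_sd=2.0, seed=21),
        )
        prof_b = generate_profile(
            MultiExpParams([(70.0, -0.09), (12.0, -0.006)]),
            X,
            NoiseSpec(additive_sd=2.0, seed=22),
        )
        k = 13.7
        fv1 = compute_features(
            fit_profile(prof_a, "2exp", (10, 90)),
            fit_profile(prof_b, "2exp", (10, 90)),
        )
        fv2 = compute_features(
            fit_profile(AxisProfile(X, prof_a.intensities * k), "2exp", (10, 90)),
            fit_profile(AxisProfile(X, prof_b.intensities * k), "2exp", (10, 90)),
        )
        assert abs(fv1.cab - fv2.cab) <= 1e-8
        assert abs(fv1.shallow_ratio - fv2.shallow_ratio) <= 1e-8
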