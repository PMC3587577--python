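"""Ensemble pipeline tests: slopes, curve assembly, model fits."""

import math

import numpy as np
import pytest
from scipy import stats

from quenchkit import (
    FluorAbsSeries,
    QuenchCurve,
    SternVolmerModel,
    TwoStateParams,
    TwoStateQuenchModel,
    approx_ratio,
    build_quench_curve,
    compare_models,
    fit_stern_volmer,
    fit_two_state,
    gen_quench_curve,
    relative_quantum_yield,
)
from quenchkit.ensemble import propagate_ratio_sigma

CONC = np.linspace(0.0, 20e-6, 21)


def make_curve(ratio, sigma=None, conc=CONC):
    return QuenchCurve(conc=conc, ratio=np.asarray(ratio, dtype=float),
                       sigma=None if sigma is None else np.asarray(sigma, dtype=float))


class TestRelativeQuantumYield:
    def test_exact_proportionality(self):
        s = FluorAbsSeries(0.0, np.array([0.01, 0.02, 0.03]), np.array([10.0, 20.0, 30.0]))
        phi, se = relative_quantum_yield(s)
        assert phi == pytest.approx(1000.0, rel=1e-12)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_slope_is_linear_in_fluorescence(self):
        s = FluorAbsSeries(0.0, np.array([0.01, 0.02, 0.03]), np.array([5.0, 10.0, 15.0]))
        assert relative_quantum_yield(s)[0] == pytest.approx(500.0, rel=1e-12)

    def test_degenerate_abscissa_rejected(self):
        s = FluorAbsSeries(0.0, np.array([0.02, 0.02, 0.02]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            relative_quantum_yield(s)

    def test_three_point_slope_coverage_matches_t1_pivot(self):
        """With n=3 the slope/se pivot is t(1 dof): P(|t| < 3) ≈ 0.795.

        A Monte-Carlo check that the returned standard error has the
        frequentist meaning expected of an OLS slope error.
        """
        rng = np.random.default_rng(11)
        a = np.array([0.01, 0.02, 0.03])
        hits = 0
        n_rep = 800
        for _ in range(n_rep):
            s = FluorAbsSeries(0.0, a, 1000.0 * a * (1 + 0.01 * rng.standard_normal(3)))
            phi, se = relative_quantum_yield(s)
            if abs(phi - 1000.0) <= 3 * se:
                hits += 1
        expected = 2 / math.pi * math.atan(3)  # t(1) cdf width
        assert hits / n_rep == pytest.approx(expected, abs=0.05)


class TestBuildQuenchCurve:
    def make_series(self, conc, scale):
        a = np.array([0.01, 0.02, 0.03])
        return FluorAbsSeries(conc, a, 1000.0 * scale * a)

    def test_identical_series_give_unit_ratios(self):
        curve = build_quench_curve([self.make_series(c, 1.0) for c in (0.0, 5e-6, 1e-5)])
        np.testing.assert_allclose(curve.ratio, 1.0, rtol=1e-10)

    def test_ratio_is_slope_quotient(self):
        # phi0 = 1000, phi(20 µM) = 55 -> ratio = 18.18...
        curve = build_quench_curve([self.make_series(0.0, 1.0), self.make_series(2e-5, 0.055)])
        assert curve.ratio[curve.conc == 2e-5][0] == pytest.approx(1000.0 / 55.0, rel=1e-9)

    def test_sigma_propagation_formula(self):
        # phi0 = 1000 +/- 10, phi = 500 +/- 10 -> ratio 2, sigma 0.0447
        assert propagate_ratio_sigma(1000.0, 10.0, 500.0, 10.0) == pytest.approx(
            math.sqrt((10 / 500) ** 2 + (1000 * 10 / 500**2) ** 2), rel=1e-12
        )
        assert propagate_ratio_sigma(1000.0, 10.0, 500.0, 10.0) == pytest.approx(0.0447, abs=2e-4)

    def test_missing_reference_series_rejected(self):
        with pytest.raises(ValueError):
            build_quench_curve([self.make_series(5e-6, 1.0)])


class TestTwoStateFit:
    def test_noiseless_self_consistency(self):
        p = TwoStateParams(K=10**6.95, f=0.05)
        curve = make_curve(approx_ratio(p, CONC), sigma=np.full(CONC.size, 1e-3))
        res = TwoStateQuenchModel(curve).fit()
        assert res.logK == pytest.approx(6.95, abs=1e-4)
        assert res.f == pytest.approx(0.05, abs=1e-4)
        assert res.chi2_red < 1e-10
        assert "logK" in res.summary()

    def test_noisy_recovery_median(self):
        p = TwoStateParams(K=10**6.95, f=0.05)
        errs = [
            fit_two_state(gen_quench_curve(p, noise_frac=0.02, seed=s)).logK - 6.95
            for s in range(40)
        ]
        assert abs(np.median(errs)) < 0.05

    def test_linear_data_is_nested_limit(self):
        """The two-state model nests Stern-Volmer (f -> 0 gives 1 + K c),
        so on linear data the two fits tie in reduced chi2."""
        rng = np.random.default_rng(3)
        truth = 1.0 + 1e5 * CONC
        ratio = truth * (1 + 0.02 * np.clip(rng.standard_normal(CONC.size), -2.99, 2.99))
        curve = make_curve(ratio, sigma=0.02 * truth)
        sv, ts = fit_stern_volmer(curve), fit_two_state(curve)
        assert ts.chi2_red == pytest.approx(sv.chi2_red, rel=0.25)
        np.testing.assert_allclose(
            approx_ratio(TwoStateParams(K=10**ts.logK, f=ts.f), CONC), truth, rtol=0.05
        )

    def test_too_few_points_rejected(self):
        curve = make_curve([1.0, 1.5, 2.0], conc=np.array([0.0, 1e-6, 2e-6]))
        with pytest.raises(ValueError):
            TwoStateQuenchModel(curve)

    def test_unweighted_curve_warns(self):
        p = TwoStateParams(K=1e6, f=0.3)
        curve = make_curve(approx_ratio(p, CONC))
        with pytest.warns(UserWarning, match="unit weights"):
            TwoStateQuenchModel(curve).fit()

    def test_precise_fit_removes_depletion_bias(self):
        """At K = 1e7 and L0 = 0.5 µM, quencher depletion biases the
        dilute-probe fitter low; the mass-balance fitter does not."""
        p = TwoStateParams(K=1e7, f=0.05)
        L0 = 0.5e-6
        errs_a, errs_p = [], []
        for s in range(25):
            c = gen_quench_curve(p, noise_frac=0.02, seed=s, model="precise", L0=L0)
            errs_a.append(fit_two_state(c).logK - 7.0)
            errs_p.append(fit_two_state(c, use_precise=True, L0=L0).logK - 7.0)
        assert abs(np.median(errs_p)) < 0.05
        assert np.median(errs_a) < -0.1  # the bias the precise fitter removes


class TestSternVolmerFit:
    def test_exact_line(self):
        truth = 1.0 + 1e5 * CONC
        res = SternVolmerModel(make_curve(truth, sigma=np.full(CONC.size, 1e-3))).fit()
        assert res.ksv == pytest.approx(1e5, rel=1e-9)

    def test_two_state_data_fits_sv_badly(self):
        p = TwoStateParams(K=10**6.95, f=0.05)
        curve = gen_quench_curve(p, noise_frac=0.02, seed=12)
        sv, ts = fit_stern_volmer(curve), fit_two_state(curve)
        assert sv.chi2_red > 5 * ts.chi2_red

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            SternVolmerModel(make_curve([1.0], conc=np.array([0.0])))


class TestCompareModels:
    def test_two_state_data_ranks_two_state_first(self):
        p = TwoStateParams(K=10**6.5, f=0.2)
        ranked = compare_models(gen_quench_curve(p, noise_frac=0.02, seed=5))
        assert ranked[0].model_tag == "approx_two_state"

    def test_linear_data_models_tie(self):
        rng = np.random.default_rng(9)
        truth = 1.0 + 8e4 * CONC
        ratio = truth * (1 + 0.02 * np.clip(rng.standard_normal(CONC.size), -2.99, 2.99))
        ranked = compare_models(make_curve(ratio, sigma=0.02 * truth))
        chi2s = sorted(r.chi2_red for r in ranked)
        assert chi2s[1] / chi2s[0] < 1.5

    def test_single_point_curve_rejected(self):
        with pytest.raises(ValueError):
            compare_models(make_curve([1.0], conc=np.array([0.0])))


class TestQuenchCurveValidation:
    def test_unphysical_brightening_rejected(self):
        with pytest.raises(ValueError):
            make_curve([1.0, 0.5, 2.0], sigma=[0.01, 0.01, 0.01],
                       conc=np.array([0.0, 1e-6, 2e-6]))

    def test_chi2_is_scale_free(self):
        """Doubling sigma quarters chi2_red: weights behave as 1/sigma^2."""
        p = TwoStateParams(K=1e6, f=0.3)
        rng = np.random.default_rng(21)
        truth = approx_ratio(p, CONC)
        ratio = truth + 0.02 * truth * rng.standard_normal(CONC.size)
        r1 = fit_two_state(make_curve(ratio, sigma=0.02 * truth))
        r2 = fit_two_state(make_curve(ratio, sigma=0.04 * truth))
        assert r2.chi2_red == pytest.approx(r1.chi2_red / 4.0, rel=0.05)
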