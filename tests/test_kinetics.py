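"""Uptake curve models, fitting, and derived-parameter propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import swbair as sb
from swbair.kinetics import (
    EquilibriumStatus,
    InsufficientDataError,
    ModelForm,
    ValueSD,
)
from swbair.synthetic_data import ChamberScenario, ChemicalTruth


def make_series(benzene, sampler, ksa, ke, ca=1000.0, noise_cv=0.0, seed=0,
                timepoints=None, n_rep=1):
    kwargs = {}
    if timepoints is not None:
        kwargs["timepoints"] = timepoints
    sc = ChamberScenario(
        truths=(ChemicalTruth(benzene, ksa=ksa, ke_per_day=ke, ca_ng_per_l=ca),),
        sampler=sampler, noise_cv=noise_cv, seed=seed, n_replicate_series=n_rep,
        **kwargs,
    )
    return sb.simulate_uptake_series(sc)[0]


class TestForwardModels:
    def test_first_order_limits(self):
        assert sb.predict_uptake_first_order(0.0, 500.0, 1.2) == 0.0
        assert sb.predict_uptake_first_order(1e6, 500.0, 1.2) == pytest.approx(500.0)
        t_half = math.log(2) / 1.2
        assert sb.predict_uptake_first_order(t_half, 500.0, 1.2) == pytest.approx(250.0)

    def test_mm_half_saturation_and_hand_value(self):
        assert sb.predict_uptake_mm(1.0, 100.0, 1.0) == pytest.approx(50.0)
        assert sb.predict_uptake_mm(0.0, 100.0, 1.0) == 0.0
        assert sb.predict_uptake_mm(3.0, 100.0, 1.0) == pytest.approx(75.0)

    @given(st.floats(0.01, 50.0), st.floats(0.01, 50.0))
    @settings(deadline=None, max_examples=50)
    def test_first_order_monotone_and_bounded(self, t1, t2):
        lo, hi = sorted((t1, t2))
        y_lo = sb.predict_uptake_first_order(lo, 500.0, 0.7)
        y_hi = sb.predict_uptake_first_order(hi, 500.0, 0.7)
        assert 0.0 <= y_lo <= y_hi <= 500.0

    @pytest.mark.parametrize("fn", [sb.predict_uptake_first_order, sb.predict_uptake_mm])
    def test_negative_inputs_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(-1.0, 100.0, 1.0)
        with pytest.raises(ValueError):
            fn(1.0, -100.0, 1.0)


class TestFitUptake:
    def test_noiseless_first_order_exact_recovery(self, benzene, sampler):
        series = make_series(benzene, sampler, ksa=500.0, ke=1.2)
        fit = sb.fit_uptake(series, ModelForm.FIRST_ORDER, robust=False)
        true_nseq = 1000.0 * sampler.volume_l * 500.0
        assert fit.ns_eq_ng.value == pytest.approx(true_nseq, rel=1e-6)
        assert fit.km_or_ke.value == pytest.approx(1.2, rel=1e-6)
        assert fit.equilibrium_status is EquilibriumStatus.EQUILIBRIUM
        # noiseless data: the fitted curve interpolates every observation
        for obs in series.observations:
            pred = sb.predict_uptake_first_order(obs.t, fit.ns_eq_ng.value, fit.km_or_ke.value)
            assert pred == pytest.approx(obs.amount_ng, rel=1e-6, abs=1e-9)

    def test_robust_fit_resists_single_outlier(self, benzene, sampler):
        series = make_series(benzene, sampler, ksa=500.0, ke=1.2)
        true_nseq = 1000.0 * sampler.volume_l * 500.0
        # corrupt one mid-curve observation by 5x
        obs = list(series.observations)
        k = len(obs) // 2
        obs[k] = sb.UptakeObservation(obs[k].t, obs[k].amount_ng * 5.0, obs[k].replicate)
        bad = sb.UptakeSeries(series.chemical, series.sampler, series.ca_ng_per_l, tuple(obs))
        fit_robust = sb.fit_uptake(bad, ModelForm.FIRST_ORDER, robust=True)
        fit_plain = sb.fit_uptake(bad, ModelForm.FIRST_ORDER, robust=False)
        assert abs(fit_robust.ns_eq_ng.value / true_nseq - 1.0) < 0.05
        # the non-robust fit shows visibly larger bias on the same data
        assert abs(fit_plain.ns_eq_ng.value / true_nseq - 1.0) > \
            abs(fit_robust.ns_eq_ng.value / true_nseq - 1.0)

    def test_robust_matches_plain_on_clean_data(self, benzene, sampler):
        series = make_series(benzene, sampler, ksa=2000.0, ke=0.6, noise_cv=0.05, seed=3)
        r = sb.fit_uptake(series, ModelForm.FIRST_ORDER, robust=True)
        p = sb.fit_uptake(series, ModelForm.FIRST_ORDER, robust=False)
        assert r.ns_eq_ng.value == pytest.approx(p.ns_eq_ng.value, rel=0.01)

    def test_monte_carlo_nseq_recovery(self, benzene, sampler):
        """Median log10 plateau error under 10% noise stays below 0.05."""
        errs = []
        for i in range(100):
            series = make_series(benzene, sampler, ksa=1000.0, ke=0.8,
                                 noise_cv=0.1, seed=5000 + i)
            fit = sb.fit_uptake(series, ModelForm.FIRST_ORDER, robust=True)
            true_nseq = 1000.0 * sampler.volume_l * 1000.0
            errs.append(abs(math.log10(fit.ns_eq_ng.value / true_nseq)))
        assert np.median(errs) < 0.05

    def test_sqrt_time_fit_capped_at_curvilinear(self, benzene, sampler):
        series = make_series(benzene, sampler, ksa=500.0, ke=1.2)
        fit = sb.fit_uptake(series, ModelForm.MM, sqrt_time=True)
        assert fit.sqrt_time_used
        assert fit.equilibrium_status is not EquilibriumStatus.EQUILIBRIUM

    def test_insufficient_data_raises(self, benzene, sampler):
        obs = tuple(sb.UptakeObservation(t, 10.0 * t) for t in (1.0, 2.0, 3.0))
        series = sb.UptakeSeries(benzene, sampler, 100.0, obs)
        with pytest.raises(InsufficientDataError):
            sb.fit_uptake(series, ModelForm.FIRST_ORDER)

    def test_rs_ksa_ke_consistent(self, benzene, sampler):
        """R_s = k_e * V_s * K_sa holds after derivation, for both curve forms."""
        series = make_series(benzene, sampler, ksa=800.0, ke=0.5, noise_cv=0.05, seed=11)
        for form in (ModelForm.FIRST_ORDER, ModelForm.MM):
            fit = sb.fit_uptake(series, form, robust=True)
            assert fit.rs_l_per_day.value == pytest.approx(
                fit.ke_per_day.value * sampler.volume_l * fit.ksa.value, rel=1e-9)


class TestDerivedQuantities:
    def test_ksa_hand_arithmetic(self, sampler):
        ksa = sb.compute_ksa(4327.0, sampler, 1000.0)
        assert ksa.value == pytest.approx(1000.0, rel=2e-3)

    def test_ksa_scaling(self, sampler):
        base = sb.compute_ksa(100.0, sampler, 10.0)
        assert sb.compute_ksa(200.0, sampler, 10.0).value == pytest.approx(2 * base.value)
        assert sb.compute_ksa(100.0, sampler, 20.0).value == pytest.approx(base.value / 2)

    def test_ksa_sd_from_nseq_only(self, sampler):
        ksa = sb.compute_ksa(ValueSD(100.0, 10.0), sampler, 10.0)
        assert ksa.sd / ksa.value == pytest.approx(0.1)

    def test_sampling_rate_exact_line(self, benzene, sampler):
        obs = tuple(sb.UptakeObservation(t, 5.0 * t) for t in (0.5, 1.0, 1.5, 2.0))
        series = sb.UptakeSeries(benzene, sampler, 2.0, obs)
        rs = sb.estimate_sampling_rate(series)
        assert rs.value == pytest.approx(2.5)
        assert rs.sd == pytest.approx(0.0, abs=1e-9)

    def test_sampling_rate_recovers_initial_slope(self, benzene, sampler):
        """Early-window slope / C_a matches R_s = ke*V_s*K_sa on noiseless data."""
        ksa, ke, ca = 5000.0, 0.08, 200.0
        # deep-kinetic timepoints (uptake < 5% of equilibrium, ke*t < 0.05):
        # the secant slope of the exponential then sits within a few percent
        # of the true initial slope
        series = make_series(benzene, sampler, ksa, ke, ca=ca,
                             timepoints=(0.05, 0.15, 0.3, 0.45, 0.6))
        rs = sb.estimate_sampling_rate(series)
        assert rs.value == pytest.approx(ke * sampler.volume_l * ksa, rel=0.05)

    def test_sampling_rate_needs_quantified_points(self, benzene, sampler):
        obs = tuple(sb.UptakeObservation(t, 0.5, below_lod=True) for t in (1.0, 2.0, 3.0))
        series = sb.UptakeSeries(benzene, sampler, 2.0, obs)
        with pytest.raises(InsufficientDataError):
            sb.estimate_sampling_rate(series)

    def test_derive_ke_identity_and_hand_value(self, sampler):
        unit = sb.SamplerSpec(mass_g=1000.0, density_g_per_ml=1.0)  # V_s = 1 L
        assert sb.derive_ke(1.0, unit, 1.0).value == pytest.approx(1.0)
        ke = sb.derive_ke(2.5, sampler, 1000.0)
        assert ke.value == pytest.approx(2.5 / (sampler.volume_l * 1000.0), rel=1e-12)
        assert ke.value == pytest.approx(0.578, rel=2e-3)

    def test_ke_substitution_makes_equations_agree(self, benzene, sampler):
        """k_e = R_s/(V_s*K_sa) makes the two air-equivalency forms coincide."""
        ksa, rs = 1234.0, 3.3
        record = sb.DeploymentRecord(benzene, 50.0, sampler, 2.0)
        ke = sb.derive_ke(rs, sampler, ksa).value
        via_ke = sb.air_equivalent_conc(record, ksa, ke=ke)
        via_rs = sb.air_equivalent_conc_rs(record, ksa, rs=rs)
        assert via_ke.ca_ng_per_l == pytest.approx(via_rs.ca_ng_per_l, rel=1e-12)


class TestUncertaintyPropagation:
    def test_quotient_zero_sd(self):
        assert sb.propagate_quotient_sd(ValueSD(10, 0), ValueSD(5, 0)).sd == 0.0

    def test_quotient_hand_arithmetic(self):
        out = sb.propagate_quotient_sd(ValueSD(10.0, 1.0), ValueSD(5.0, 0.5))
        assert out.value == pytest.approx(2.0)
        assert out.sd == pytest.approx(2.0 * math.sqrt(0.01 + 0.01), rel=1e-12)

    def test_quotient_matches_monte_carlo(self):
        rng = np.random.default_rng(99)
        x, sx, y, sy = 10.0, 0.8, 5.0, 0.4
        draws = rng.normal(x, sx, 10**6) / rng.normal(y, sy, 10**6)
        assert sb.propagate_quotient_sd(ValueSD(x, sx), ValueSD(y, sy)).sd == \
            pytest.approx(float(np.std(draws)), rel=0.03)

    def test_quotient_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sb.propagate_quotient_sd(ValueSD(-1.0, 0.1), ValueSD(5.0, 0.1))

    def test_log10_hand_arithmetic(self):
        assert sb.log10_with_sd(ValueSD(100.0, 0.0)) == (2.0, 0.0)
        out = sb.log10_with_sd(ValueSD(100.0, 23.03))
        assert out.value == 2.0
        assert out.sd == pytest.approx(0.100, rel=1e-3)

    @given(st.floats(0.01, 0.5), st.floats(0.51, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_log_sd_monotone_in_relative_sd(self, rel_small, rel_big):
        x = 42.0
        small = sb.log10_with_sd(ValueSD(x, rel_small * x)).sd
        big = sb.log10_with_sd(ValueSD(x, rel_big * x)).sd
        assert small < big
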