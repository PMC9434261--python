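"""Coupled-assay rates, kinetic model fits, pH bells, specificity statistics."""

import math

import numpy as np
import pytest

from murkit.kinetics import (
    AssayConfig,
    AssayTrace,
    FitError,
    MichaelisMentenRegressor,
    PHProfile,
    RateSeries,
    SpecificityPanel,
    SubstrateInhibitionRegressor,
    UnidentifiableProfileError,
    catalytic_efficiency,
    compare_models,
    coupling_control_check,
    fit_michaelis_menten,
    fit_ph_bell,
    fit_substrate_inhibition,
    initial_rate,
    michaelis_menten,
    specificity_test,
    substrate_inhibition,
)
from murkit.simulate import (
    simulate_ph_profile,
    simulate_rate_series,
    simulate_trace,
)


class TestInitialRate:
    def test_unit_conversion_example(self):
        """Slope -0.00622 A/s at eps 6220, l 1 cm, [E] 100 nM gives 10 ADP/s."""
        cfg = AssayConfig(enzyme_m=1e-7)
        t = np.arange(0, 30.0, 1.0)
        trace = AssayTrace(time_s=t, a340=1.0 - 0.00622 * t, config=cfg)
        ir = initial_rate(trace)
        assert ir.v0 == pytest.approx(10.0, rel=1e-9)
        assert not ir.negative_flagged

    def test_flat_trace_zero_rate(self):
        cfg = AssayConfig(enzyme_m=1e-7)
        trace = AssayTrace(time_s=np.arange(10.0), a340=np.full(10, 0.9), config=cfg)
        assert initial_rate(trace).v0 == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_five_percent(self):
        cfg = AssayConfig(enzyme_m=1e-7)
        trace, _ = simulate_trace(
            v0=2.5, config=cfg, duration_s=60, sigma_a=0.001, seed=7
        )
        assert initial_rate(trace).v0 == pytest.approx(2.5, rel=0.05)

    def test_negative_rate_flagged_not_clamped(self):
        cfg = AssayConfig(enzyme_m=1e-7)
        t = np.arange(0, 10.0)
        trace = AssayTrace(time_s=t, a340=0.5 + 0.001 * t, config=cfg)
        ir = initial_rate(trace)
        assert ir.v0 < 0 and ir.negative_flagged

    def test_window_and_monotonic_time_validation(self):
        cfg = AssayConfig(enzyme_m=1e-7)
        with pytest.raises(ValueError, match="strictly increasing"):
            AssayTrace(time_s=np.array([0.0, 1.0, 1.0]), a340=np.zeros(3), config=cfg)
        trace = AssayTrace(time_s=np.arange(10.0), a340=np.ones(10), config=cfg)
        with pytest.raises(ValueError, match="outside"):
            initial_rate(trace, window=(5.0, 20.0))
        with pytest.raises(ValueError, match="3 points"):
            initial_rate(trace, window=(0.0, 1.0))

    def test_stoichiometric_unit_conservation(self):
        """v0 * [E] * volume * time equals mol ADP formed (NADH consumed)."""
        cfg = AssayConfig(enzyme_m=2e-7, volume_l=2e-4)
        trace, _ = simulate_trace(v0=3.0, config=cfg, duration_s=50, seed=0)
        ir = initial_rate(trace)
        delta_a = trace.a340[0] - trace.a340[-1]
        mol_nadh = delta_a / (cfg.epsilon * cfg.path_cm) * cfg.volume_l
        mol_adp = ir.v0 * cfg.enzyme_m * cfg.volume_l * (trace.time_s[-1] - trace.time_s[0])
        assert mol_adp == pytest.approx(mol_nadh, rel=1e-9)


class TestMichaelisMenten:
    def test_noiseless_exact_recovery(self):
        rs, _ = simulate_rate_series(
            "MM", dict(vmax=2.0, km=50.0), np.geomspace(5, 500, 10), sigma=0.0
        )
        f = fit_michaelis_menten(rs)
        assert f.vmax == pytest.approx(2.0, rel=1e-6)
        assert f.km == pytest.approx(50.0, rel=1e-6)
        assert f.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_half_saturation_property(self):
        assert michaelis_menten(50.0, 2.0, 50.0) == pytest.approx(1.0)

    def test_median_km_bias_small_under_noise(self):
        """Over 200 noisy datasets (sigma = 5% Vmax), median KM bias < 10%."""
        biases = []
        s = np.geomspace(5, 500, 10)
        for i in range(200):
            rs, _ = simulate_rate_series(
                "MM", dict(vmax=2.0, km=50.0), s, sigma=0.05, seed=5000 + i
            )
            biases.append((fit_michaelis_menten(rs).km - 50.0) / 50.0)
        assert abs(float(np.median(biases))) < 0.10

    def test_too_few_distinct_concentrations(self):
        with pytest.raises(ValueError):
            fit_michaelis_menten(RateSeries(s_um=[10.0, 10.0], v0=[1.0, 1.0]))

    def test_sklearn_estimator_contract(self):
        est = MichaelisMentenRegressor()
        assert est.get_params() == {"max_nfev": 10000}
        s = np.geomspace(5, 500, 8)
        est.fit(s.reshape(-1, 1), michaelis_menten(s, 2.0, 50.0))
        assert est.vmax_ == pytest.approx(2.0, rel=1e-6)
        pred = est.predict(np.array([[50.0]]))
        assert pred[0] == pytest.approx(1.0, rel=1e-6)


class TestSubstrateInhibition:
    def test_noiseless_exact_recovery(self):
        rs, _ = simulate_rate_series(
            "SI", dict(vmax=3.0, km=20.0, ki=400.0), np.geomspace(2, 2000, 12), sigma=0.0
        )
        f = fit_substrate_inhibition(rs)
        assert f.vmax == pytest.approx(3.0, rel=1e-6)
        assert f.km == pytest.approx(20.0, rel=1e-6)
        assert f.ki == pytest.approx(400.0, rel=1e-6)

    def test_curve_maximum_at_sqrt_km_ki(self):
        km, ki = 20.0, 400.0
        s_star = math.sqrt(km * ki)
        s = np.linspace(1, 2000, 20000)
        v = substrate_inhibition(s, 3.0, km, ki)
        assert s[np.argmax(v)] == pytest.approx(s_star, rel=1e-3)
        est = SubstrateInhibitionRegressor().fit(
            np.geomspace(2, 2000, 12),
            substrate_inhibition(np.geomspace(2, 2000, 12), 3.0, km, ki),
        )
        assert est.s_optimum_ == pytest.approx(s_star, rel=1e-5)

    def test_reduces_to_mm_at_large_ki(self):
        """With Ki -> infinity the SI curve is MM; fits are indistinguishable."""
        s = np.geomspace(5, 500, 10)
        v_si = substrate_inhibition(s, 2.0, 50.0, 1e9)
        v_mm = michaelis_menten(s, 2.0, 50.0)
        assert np.allclose(v_si, v_mm, rtol=1e-5)
        rs = RateSeries(s_um=s, v0=v_mm)
        mm = fit_michaelis_menten(rs)
        si = fit_substrate_inhibition(rs)
        assert abs(si.r_squared - mm.r_squared) < 1e-6


class TestModelComparison:
    def test_si_truth_selected_by_r2(self):
        s = np.geomspace(5, 1000, 10)
        wins = 0
        for i in range(50):
            rs, _ = simulate_rate_series(
                "SI", dict(vmax=2.0, km=50.0, ki=250.0), s, sigma=0.05, seed=100 + i
            )
            c = compare_models(fit_michaelis_menten(rs), fit_substrate_inhibition(rs))
            wins += c.selected == "SI"
        assert wins >= 45

    def test_mm_truth_aicc_prefers_mm(self):
        s = np.geomspace(5, 500, 10)
        wins = 0
        for i in range(50):
            rs, _ = simulate_rate_series(
                "MM", dict(vmax=2.0, km=50.0), s, sigma=0.05, seed=200 + i
            )
            c = compare_models(fit_michaelis_menten(rs), fit_substrate_inhibition(rs))
            wins += c.selected_by_aicc == "MM"
        assert wins >= 40

    def test_identical_fits_declared_tie(self):
        s = np.geomspace(5, 500, 10)
        rs = RateSeries(s_um=s, v0=michaelis_menten(s, 2.0, 50.0))
        mm = fit_michaelis_menten(rs)
        si = fit_substrate_inhibition(rs)
        assert compare_models(mm, si).selected == "tie"

    def test_different_data_rejected(self):
        s = np.geomspace(5, 500, 10)
        rs1 = RateSeries(s_um=s, v0=michaelis_menten(s, 2.0, 50.0))
        rs2 = RateSeries(s_um=s[:-1], v0=michaelis_menten(s[:-1], 2.0, 50.0))
        with pytest.raises(ValueError):
            compare_models(fit_michaelis_menten(rs1), fit_michaelis_menten(rs2))


class TestCatalyticEfficiency:
    def test_division_and_units(self):
        rs, _ = simulate_rate_series(
            "MM", dict(vmax=2.0, km=50.0), np.geomspace(5, 500, 10), sigma=0.0
        )
        kcat, eff = catalytic_efficiency(fit_michaelis_menten(rs))
        assert kcat == pytest.approx(2.0, rel=1e-6)
        assert eff == pytest.approx(0.04, rel=1e-6)  # uM^-1 s^-1
        assert eff * 1e6 == pytest.approx(4.0e4, rel=1e-6)  # M^-1 s^-1

    def test_recovery_on_noisy_si_data(self):
        rs, _ = simulate_rate_series(
            "SI", dict(vmax=2.0, km=50.0, ki=500.0),
            np.geomspace(5, 1000, 12), sigma=0.05, replicates=3, seed=11,
        )
        f = fit_substrate_inhibition(rs)
        truth_eff = 2.0 / 50.0
        assert f.kcat_over_km == pytest.approx(truth_eff, rel=0.15)


class TestPHBell:
    def test_noiseless_recovery_optimum(self):
        prof, _ = simulate_ph_profile(1.0, 6.5, 8.5, np.arange(5.0, 10.01, 0.25))
        f = fit_ph_bell(prof)
        assert f.optimum == pytest.approx(7.5, abs=1e-6)
        assert f.pka1 < f.pka2
        assert f.vopt == pytest.approx(1.0, rel=1e-6)

    def test_midpoint_equals_argmax_of_fitted_curve(self):
        from murkit.kinetics import ph_bell

        prof, _ = simulate_ph_profile(2.0, 6.0, 9.0, np.arange(4.5, 10.51, 0.25))
        f = fit_ph_bell(prof)
        grid = np.linspace(4, 11, 20001)
        curve = ph_bell(grid, f.vopt, f.pka1, f.pka2)
        assert grid[np.argmax(curve)] == pytest.approx(f.optimum, abs=1e-3)

    def test_noisy_optimum_within_two_tenths(self):
        """100 noisy replicates at 5% noise: optimum within +/-0.2 pH units."""
        errs = []
        grid = np.arange(5.5, 9.76, 0.25)
        for i in range(100):
            prof, _ = simulate_ph_profile(1.0, 6.5, 8.5, grid, sigma=0.05, seed=300 + i)
            errs.append(abs(fit_ph_bell(prof).optimum - 7.5))
        assert max(errs) <= 0.2

    def test_one_sided_data_flagged_unidentifiable(self):
        prof, _ = simulate_ph_profile(1.0, 8.5, 10.5, np.arange(4.0, 7.01, 0.5))
        with pytest.raises(UnidentifiableProfileError):
            fit_ph_bell(prof)


class TestCouplingControl:
    def test_identical_series_independent(self):
        r = [1.0, 1.1, 0.9, 1.05]
        rep = coupling_control_check(r, r)
        assert rep.mean_ratio == pytest.approx(1.0)
        assert rep.independent

    def test_systematic_shift_flags_dependence(self, rng):
        r1 = 2.0 + rng.normal(0, 0.05, 8)
        rep = coupling_control_check(r1, 1.5 * r1 + rng.normal(0, 0.02, 8))
        assert not rep.independent
        assert rep.p_value < 0.05

    def test_equal_mean_noisy_series_mostly_independent(self):
        hits = 0
        for i in range(200):
            g = np.random.default_rng(700 + i)
            r1 = 2.0 + g.normal(0, 0.1, 6)
            r2 = 2.0 + g.normal(0, 0.1, 6)
            hits += coupling_control_check(r1, r2).independent
        assert hits >= 180

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            coupling_control_check([1.0, 2.0], [1.0])


class TestSpecificity:
    def test_identical_groups_t_zero_p_one(self):
        panel = SpecificityPanel(
            groups={"D,L-DAP": np.array([1.0, 1.0, 1.0]), "L-Lys": np.array([1.0, 1.0, 1.0])}
        )
        res = {g.substrate: g for g in specificity_test(panel, "D,L-DAP")}
        assert res["L-Lys"].t_vs_reference == 0.0
        assert res["L-Lys"].p_vs_reference == 1.0

    def test_strong_contrast_significant_at_one_percent(self, rng):
        """Means 10 vs 0.1 at sigma 0.5, n=5 mirrors the DAP-vs-Lys contrast."""
        panel = SpecificityPanel(
            groups={
                "D,L-DAP": 10.0 + rng.normal(0, 0.5, 5),
                "L-Lys": 0.1 + rng.normal(0, 0.5, 5),
            }
        )
        res = {g.substrate: g for g in specificity_test(panel, "D,L-DAP")}
        assert res["L-Lys"].p_vs_reference <= 0.01

    def test_ci_width_shrinks_with_sqrt_n(self, rng):
        widths = {}
        for n in (8, 32):
            x = rng.normal(5.0, 1.0, n * 50).reshape(50, n)
            w = [
                (lambda ci: ci[1] - ci[0])(
                    {g.substrate: g for g in specificity_test(
                        SpecificityPanel(groups={"a": row, "ref": row + 1}), "ref"
                    )}["a"].ci
                )
                for row in x
            ]
            widths[n] = float(np.mean(w))
        assert widths[32] == pytest.approx(widths[8] / 2.0, rel=0.2)

    def test_small_group_excluded_with_flag(self):
        panel = SpecificityPanel(
            groups={"D,L-DAP": np.array([1.0, 1.1, 0.9]), "D,D-DAP": np.array([0.5])}
        )
        res = {g.substrate: g for g in specificity_test(panel, "D,L-DAP")}
        assert res["D,D-DAP"].excluded

    def test_holm_adjustment_monotone(self, rng):
        panel = SpecificityPanel(
            groups={
                "D,L-DAP": 10.0 + rng.normal(0, 0.5, 5),
                "L-Lys": 0.1 + rng.normal(0, 0.5, 5),
                "D,D-DAP": 1.0 + rng.normal(0, 0.5, 5),
                "L,L-DAP": 0.6 + rng.normal(0, 0.5, 5),
            }
        )
        res = specificity_test(panel, "D,L-DAP", holm=True)
        for g in res:
            if g.p_adjusted is not None:
                assert g.p_adjusted >= g.p_vs_reference - 1e-15

    def test_ci_contains_mean(self, rng):
        panel = SpecificityPanel(groups={"D,L-DAP": rng.normal(3, 1, 6), "x": rng.normal(1, 1, 6)})
        for g in specificity_test(panel, "D,L-DAP"):
            assert g.ci[0] <= g.mean <= g.ci[1]


def test_fit_failure_raises_with_diagnostics():
    # pathological data: all-zero rates force a degenerate but convergent fit;
    # a constant nonzero series with one S value cannot even start
    with pytest.raises((FitError, ValueError)):
        fit_michaelis_menten(RateSeries(s_um=[1.0], v0=[1.0]))
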