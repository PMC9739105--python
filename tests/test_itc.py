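"""One-set-of-sites ITC: forward model, blank correction, fitting, thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mtxkit.itc import (
    BindingParams, ITCSchedule, OneSiteBindingModel, Titration,
    derive_thermodynamics, fit_one_site, predict_heats, subtract_blank,
)
from mtxkit.simulate import ITC_TRUTH, simulate_itc

TRUTH = ITC_TRUTH  # N = 2, Kd = 5.3 µM, dH = −40 kJ/mol, 20 °C
SCHED = ITCSchedule()  # 55 µM cell, 2.2 mM syringe, 19 x 2 µL


class TestPredictHeats:
    def test_zero_enthalpy_gives_zero_heats(self):
        assert np.all(predict_heats(BindingParams(N=2, Ka=1e5, dH=0.0), SCHED)
                      == 0.0)

    def test_tight_binding_limit(self):
        """With Ka -> inf every injected ligand molecule binds, so early
        heats equal dH times the moles injected (analytic oracle)."""
        params = BindingParams(N=2.0, Ka=1e12, dH=-40.0)
        q = predict_heats(params, SCHED)
        moles_per_inj = SCHED.syringe_conc * 1e-6 * 2.0 * 1e-6  # mol
        expected = -40.0 * 1000.0 * moles_per_inj * 1e6        # µJ
        assert q[0] == pytest.approx(expected, rel=5e-3)
        assert q[3] == pytest.approx(expected, rel=5e-3)

    def test_saturation_heats_vanish(self):
        sched = ITCSchedule(inj_volumes=(2.0,) * 60)
        q = predict_heats(TRUTH, sched)
        assert abs(q[-1]) < 0.02 * abs(q[0])

    def test_isotherm_inflection_near_stoichiometry(self):
        """With N = 2 the transition of the differential heat curve falls
        near molar ratio 2 in the cell."""
        q = predict_heats(TRUTH, SCHED)
        ratios = SCHED.molar_ratios()
        steepest = np.argmax(np.abs(np.diff(q)))  # largest drop in |heat|
        assert 1.5 <= ratios[steepest] <= 2.5

    @given(st.floats(min_value=0.2, max_value=4.0),
           st.floats(min_value=3.0, max_value=9.0),
           st.floats(min_value=-80.0, max_value=80.0))
    def test_heats_monotone_and_bounded(self, n, log_ka, dh):
        """Bound fraction stays in [0,1]: every differential heat has the
        sign of dH and the cumulative heat is monotone toward saturation."""
        params = BindingParams(N=n, Ka=10.0 ** log_ka, dH=dh)
        q = predict_heats(params, SCHED)
        if dh > 0:
            assert np.all(q >= -1e-9)
        elif dh < 0:
            assert np.all(q <= 1e-9)

    def test_total_heat_conservation(self):
        """Total bound-ligand heat converges to dH * N * M * V0 once the
        titration is far past saturation (accounting for displaced heat)."""
        sched = ITCSchedule(inj_volumes=(2.0,) * 100)
        params = BindingParams(N=2.0, Ka=1e9, dH=-40.0)
        ms, _, fs = np.array([]), None, None
        q = predict_heats(params, sched)
        # reconstruct the final bound moles from the recurrence
        # q_i = dH (B_i - B_{i-1}(1 - f_i))  =>  accumulate forward
        b = 0.0
        for qi, v in zip(q, sched.inj_volumes):
            f = v / sched.cell_volume
            b = qi / (params.dH * 1000.0 * 1e6) + b * (1 - f)
        m_final = sched.cell_conc * 1e-6 * np.prod(
            [1 - v / sched.cell_volume for v in sched.inj_volumes])
        sites = params.N * m_final * sched.cell_volume * 1e-6
        assert b == pytest.approx(sites, rel=1e-3)


class TestSubtractBlank:
    def test_blank_equal_to_experiment_gives_zero(self):
        tit = Titration(SCHED, heats=np.ones(19), blank_heats=np.ones(19))
        assert np.all(subtract_blank(tit).heats == 0.0)

    def test_constant_offset(self):
        tit = Titration(SCHED, heats=np.arange(19.0))
        out = subtract_blank(tit, offset=2.0)
        assert np.allclose(out.heats, np.arange(19.0) - 2.0)

    def test_roundtrip_with_simulated_dilution_offset(self):
        tit = simulate_itc(TRUTH, SCHED, noise_sd=0.0, dilution_offset=-0.7)
        corrected = subtract_blank(tit)
        assert np.allclose(corrected.heats, predict_heats(TRUTH, SCHED),
                           atol=1e-12)

    def test_missing_blank_rejected(self):
        with pytest.raises(ValueError):
            subtract_blank(Titration(SCHED, heats=np.zeros(19)))


class TestFitOneSite:
    def test_noiseless_recovery(self):
        tit = simulate_itc(TRUTH, SCHED, noise_sd=0.0)
        res = fit_one_site(tit)
        assert res.converged
        assert res.params.N == pytest.approx(TRUTH.N, rel=1e-3)
        assert res.params.Ka == pytest.approx(TRUTH.Ka, rel=1e-3)
        assert res.params.dH == pytest.approx(TRUTH.dH, rel=1e-3)

    def test_exothermic_fixture_has_negative_enthalpy(self, fixture_suite):
        outdir, manifest = fixture_suite
        from mtxkit import io as mio
        tit = mio.read_itc(outdir / "itc.csv", blank_path=outdir / "itc_blank.csv")
        res = fit_one_site(subtract_blank(tit))
        assert res.params.dH < 0

    def test_noisy_recovery_small_monte_carlo(self):
        q0 = predict_heats(TRUTH, SCHED)
        noise = 0.01 * float(np.max(np.abs(q0)))
        errs = []
        for seed in range(5):
            tit = simulate_itc(TRUTH, SCHED, noise_sd=noise, seed=seed)
            res = fit_one_site(tit)
            errs.append(abs(res.params.Kd - TRUTH.Kd) / TRUTH.Kd)
        assert np.median(errs) < 0.10

    def test_unit_rescaling_invariance(self):
        """Scaling the heats by 1000 (µJ -> nJ) scales dH by 1000 and
        leaves N and Ka unchanged."""
        tit = simulate_itc(TRUTH, SCHED, noise_sd=0.0)
        scaled = Titration(SCHED, heats=tit.heats * 1000.0)
        a, b = fit_one_site(tit).params, fit_one_site(scaled).params
        assert b.N == pytest.approx(a.N, rel=1e-6)
        assert b.Ka == pytest.approx(a.Ka, rel=1e-4)
        assert b.dH == pytest.approx(a.dH * 1000.0, rel=1e-6)

    def test_low_c_value_flagged(self):
        weak = BindingParams(N=1.0, Ka=5e3, dH=-30.0)
        tit = simulate_itc(weak, SCHED, noise_sd=0.0)
        res = fit_one_site(tit)
        assert res.c_value < 1.0
        assert any("c-value" in f for f in res.flags)

    def test_reports_standard_errors(self):
        q0 = predict_heats(TRUTH, SCHED)
        tit = simulate_itc(TRUTH, SCHED,
                           noise_sd=0.01 * float(np.max(np.abs(q0))), seed=3)
        res = fit_one_site(tit)
        assert set(res.params.se) >= {"N", "Ka", "dH"}
        assert res.params.se["N"] > 0
        assert "One-set-of-sites" in res.summary()

    def test_too_few_injections_rejected(self):
        sched = ITCSchedule(inj_volumes=(2.0,) * 4)
        with pytest.raises(ValueError):
            OneSiteBindingModel(Titration(sched, heats=np.zeros(4)))

    def test_discard_first_injection(self):
        tit = simulate_itc(TRUTH, SCHED, noise_sd=0.0)
        heats = tit.heats.copy()
        heats[0] *= 0.4  # a typical corrupted first injection
        res = fit_one_site(Titration(SCHED, heats=heats), discard_first=True)
        assert res.params.Kd == pytest.approx(TRUTH.Kd, rel=1e-3)


class TestDeriveThermodynamics:
    def test_micromolar_kd_free_energy(self):
        dg, ds, kd = derive_thermodynamics(N=2.0, Ka=1.0 / 5.3e-6, dH=-40.0,
                                           T=293.15)
        assert dg == pytest.approx(-29.6, abs=0.05)
        assert kd == pytest.approx(5.3e-6)

    def test_dh_equals_dg_gives_zero_entropy(self):
        dg, _, _ = derive_thermodynamics(N=1.0, Ka=1e5, dH=0.0, T=300.0)
        _, ds2, _ = derive_thermodynamics(N=1.0, Ka=1e5, dH=dg, T=300.0)
        assert ds2 == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(min_value=3.0, max_value=9.0),
           st.floats(min_value=-80.0, max_value=10.0),
           st.floats(min_value=273.0, max_value=320.0))
    def test_gibbs_helmholtz_identity(self, log_ka, dh, temp):
        dg, ds, _ = derive_thermodynamics(N=1.0, Ka=10.0 ** log_ka, dH=dh, T=temp)
        assert dg == pytest.approx(dh - temp * ds / 1000.0, abs=1e-9)

    def test_binding_params_expose_derived_quantities(self):
        p = BindingParams(N=2.0, Ka=1.0 / 5.3e-6, dH=-40.0, T=293.15)
        assert p.dG == pytest.approx(-29.6, abs=0.05)
        assert p.dG == pytest.approx(p.dH - p.T * p.dS / 1000.0, abs=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            derive_thermodynamics(1.0, 0.0, -40.0)
        with pytest.raises(ValueError):
            derive_thermodynamics(1.0, 1e5, -40.0, T=0.0)
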