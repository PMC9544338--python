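import math

import numpy as np
import pytest

from gtpkin import (
    FitOptions,
    KineticParams,
    KineticTrace,
    compare_rates,
    fit_k_bind,
    fit_k_diss,
    fit_k_hydr,
    fold_change,
    simulate_association,
    simulate_binding_hydrolysis,
    simulate_displacement,
)
from gtpkin.errors import (
    ComparisonUndefinedError,
    DegenerateFitError,
    DivisionUnstableError,
    InvalidInputError,
)
from gtpkin.trace_fitting import FitResult, batch_fit

from conftest import add_noise


def _result(k_bind=0.0, k_hydr=0.0, k_diss=0.0, errors=None, converged=True):
    """Hand-built FitResult for testing the derived comparisons."""
    return FitResult(
        params=KineticParams(k_bind=k_bind, k_hydr=k_hydr, k_diss=k_diss),
        param_errors=errors or {},
        rss=1.0,
        n_points=50,
        converged=converged,
    )


class TestFitKBind:
    def test_noiseless_round_trip(self):
        p = KineticParams(k_bind=0.05, F_free=100.0, A=100.0)
        tr = simulate_association(p, np.linspace(0.0, 300.0, 151))
        fr = fit_k_bind(tr)
        assert fr.converged
        assert fr.params.k_bind == pytest.approx(0.05, rel=1e-6)
        assert fr.params.F_free == pytest.approx(100.0, rel=1e-6)
        assert fr.params.A == pytest.approx(100.0, rel=1e-6)

    def test_monte_carlo_recovery(self):
        # 2% noise, 10-minute window
        p = KineticParams(k_bind=0.01, F_free=100.0, A=100.0)
        clean = simulate_association(p, np.linspace(0.0, 600.0, 301))
        rng = np.random.default_rng(42)
        rel_errors = []
        for _ in range(50):
            fr = fit_k_bind(add_noise(clean, 2.0, rng))
            rel_errors.append(abs(fr.params.k_bind - 0.01) / 0.01)
        assert np.median(rel_errors) < 0.05

    def test_flat_trace_degenerate(self):
        rng = np.random.default_rng(0)
        tr = KineticTrace(np.linspace(0, 600, 61), 100.0 + rng.normal(0, 2.0, 61), "association")
        with pytest.raises(DegenerateFitError):
            fit_k_bind(tr)

    def test_wrong_kind_rejected(self, wt_params):
        tr = simulate_binding_hydrolysis(wt_params, np.linspace(0, 600, 61))
        with pytest.raises(InvalidInputError):
            fit_k_bind(tr)

    def test_dead_time_fit(self):
        p = KineticParams(k_bind=0.08, F_free=100.0, A=100.0, t0=12.0)
        tr = simulate_association(p, np.linspace(0.0, 200.0, 201))
        fr = fit_k_bind(tr, FitOptions(fit_dead_time=True))
        assert fr.params.k_bind == pytest.approx(0.08, rel=1e-4)
        assert fr.params.t0 == pytest.approx(12.0, rel=1e-3)

    def test_se_consistency_with_empirical_sd(self):
        # reported standard errors within a factor 2 of the replicate SD
        p = KineticParams(k_bind=0.02, F_free=100.0, A=100.0)
        clean = simulate_association(p, np.linspace(0.0, 600.0, 61))
        rng = np.random.default_rng(7)
        ks, ses = [], []
        for _ in range(200):
            fr = fit_k_bind(add_noise(clean, 2.0, rng))
            ks.append(fr.params.k_bind)
            ses.append(fr.param_errors["k_bind"])
        empirical = np.std(ks, ddof=1)
        reported = np.median(ses)
        assert 0.5 < reported / empirical < 2.0


class TestFitKHydr:
    def test_round_trip_degenerate_rates(self, wt_params):
        tr = simulate_binding_hydrolysis(wt_params, np.linspace(0.0, 3600.0, 241))
        for mode in ("endpoint", "initial"):
            fr = fit_k_hydr(tr, mode)
            assert fr.converged
            assert fr.params.k_bind == pytest.approx(0.01, rel=1e-4)
            assert fr.params.k_hydr == pytest.approx(0.01, rel=1e-4)
            assert fr.params.rho == pytest.approx(0.2, rel=1e-3)

    def test_round_trip_separated_rates(self):
        p = KineticParams(k_bind=0.05, k_hydr=0.004, F_free=80.0, A=120.0, rho=0.25)
        tr = simulate_binding_hydrolysis(p, np.linspace(0.0, 3600.0, 361))
        fr = fit_k_hydr(tr, "endpoint")
        assert fr.params.k_bind == pytest.approx(0.05, rel=1e-4)
        assert fr.params.k_hydr == pytest.approx(0.004, rel=1e-4)

    def test_hydrolysis_dead_hits_lower_bound(self, dead_params):
        tr = simulate_binding_hydrolysis(dead_params, np.linspace(0.0, 600.0, 121))
        fr = fit_k_hydr(tr, "initial")
        assert fr.params.k_hydr <= 1e-6
        assert "k_hydr" in fr.param_errors

    def test_endpoint_mode_rejected_on_flat_top(self, dead_params):
        # endpoint anchoring contradicts a trace that never decays
        tr = simulate_binding_hydrolysis(dead_params, np.linspace(0.0, 600.0, 121))
        assert fit_k_hydr(tr, "initial").converged
        with pytest.raises(DegenerateFitError):
            fit_k_hydr(tr, "endpoint")

    def test_short_trace_flagged(self):
        p = KineticParams(k_bind=0.001, k_hydr=0.0005, F_free=100.0, A=100.0, rho=0.2)
        tr = simulate_binding_hydrolysis(p, np.linspace(0.0, 600.0, 121))
        fr = fit_k_hydr(tr, "initial")
        assert "binding phase unresolved" in fr.flags

    def test_unknown_mode_rejected(self, wt_params):
        tr = simulate_binding_hydrolysis(wt_params, np.linspace(0.0, 600.0, 61))
        with pytest.raises(InvalidInputError):
            fit_k_hydr(tr, "subtract")

    def test_programmed_fold_changes_noiseless(self):
        """Mutant/WT rate ratios {5, 11, 28} and reductions {100, 50, 300}."""
        wt = KineticParams(k_bind=0.01, k_hydr=0.01, F_free=100.0, A=100.0, rho=0.2)
        folds_bind = {"fast5x": 5.0, "fast11x": 11.0, "fast28x": 28.0}
        folds_hydr = {"fast5x": 100.0, "fast11x": 50.0, "fast28x": 300.0}
        t_assoc = np.linspace(0.0, 1200.0, 241)
        wt_bind = fit_k_bind(simulate_association(wt, t_assoc))
        t_hydr = np.linspace(0.0, 7200.0, 241)
        wt_hydr = fit_k_hydr(simulate_binding_hydrolysis(wt, t_hydr), "endpoint")
        for name in folds_bind:
            mut = wt.with_(k_bind=wt.k_bind * folds_bind[name], k_hydr=wt.k_hydr / folds_hydr[name])
            m_bind = fit_k_bind(simulate_association(mut, t_assoc))
            assert m_bind.params.k_bind / wt_bind.params.k_bind == pytest.approx(
                folds_bind[name], rel=0.02
            )
            m_hydr = fit_k_hydr(simulate_binding_hydrolysis(mut, t_hydr), "initial")
            assert wt_hydr.params.k_hydr / m_hydr.params.k_hydr == pytest.approx(
                folds_hydr[name], rel=0.10
            )


class TestFitKDiss:
    def _trace(self, **kw):
        base = dict(k_diss=0.02, F_free=100.0, A=100.0, f_ret=0.2, t_inj=100.0, d_inj=1.0)
        base.update(kw)
        p = KineticParams(**base)
        return simulate_displacement(p, np.linspace(0.0, 600.0, 121)), p

    def test_noiseless_round_trip(self):
        tr, _ = self._trace()
        fr = fit_k_diss(tr)
        assert fr.params.k_diss == pytest.approx(0.02, rel=1e-6)

    def test_constant_post_injection(self):
        tr, _ = self._trace(k_diss=0.0)
        fr = fit_k_diss(tr)
        assert fr.params.k_diss <= 1e-8
        assert fr.derived["retained_fraction"] == pytest.approx(1.0)

    def test_retained_fraction_definition(self):
        # F_pre=200, F_res=120, F_free=100 -> retained 0.2
        tr, _ = self._trace()
        fr = fit_k_diss(tr, FitOptions(F_free=100.0))
        assert fr.derived["F_pre"] == pytest.approx(200.0, rel=1e-6)
        assert fr.derived["F_res"] == pytest.approx(120.0, rel=1e-6)
        assert fr.derived["retained_fraction"] == pytest.approx(0.2, rel=1e-6)

    def test_retained_fraction_without_reference(self):
        tr, _ = self._trace()
        fr = fit_k_diss(tr)
        assert fr.derived["retained_fraction"] == pytest.approx(120.0 / 200.0, rel=1e-6)

    def test_dilution_correction(self):
        tr, _ = self._trace(d_inj=0.8)
        fr = fit_k_diss(tr, FitOptions(d_inj=0.8, F_free=100.0))
        assert fr.params.k_diss == pytest.approx(0.02, rel=1e-6)
        assert fr.derived["retained_fraction"] == pytest.approx(0.2, rel=1e-5)

    def test_too_few_post_injection_points(self):
        p = KineticParams(k_diss=0.02, F_free=100.0, A=100.0, f_ret=0.2, t_inj=580.0, d_inj=1.0)
        tr = simulate_displacement(p, np.linspace(0.0, 600.0, 121))
        with pytest.raises(InvalidInputError):
            fit_k_diss(tr)


class TestCompareRates:
    def test_identity_not_significant(self):
        d = _result(k_diss=0.05, errors={"k_diss": 0.002})
        b = _result(k_bind=0.05, errors={"k_bind": 0.002})
        cmp = compare_rates(d, b)
        assert cmp.ratio == pytest.approx(1.0)
        assert cmp.z == pytest.approx(0.0)
        assert not cmp.exceeds

    def test_closed_form_z(self):
        d = _result(k_diss=0.1, errors={"k_diss": 0.005})
        b = _result(k_bind=0.02, errors={"k_bind": 0.001})
        cmp = compare_rates(d, b)
        assert cmp.ratio == pytest.approx(5.0)
        assert cmp.z == pytest.approx(0.08 / math.sqrt(0.005**2 + 0.001**2), rel=1e-9)
        assert cmp.z == pytest.approx(15.689, abs=0.001)
        assert cmp.exceeds

    def test_zero_errors_undefined(self):
        d = _result(k_diss=0.1, errors={"k_diss": 0.0})
        b = _result(k_bind=0.02, errors={"k_bind": 0.0})
        with pytest.raises(ComparisonUndefinedError):
            compare_rates(d, b)

    def test_unconverged_rejected(self):
        d = _result(k_diss=0.1, errors={"k_diss": 0.005}, converged=False)
        b = _result(k_bind=0.02, errors={"k_bind": 0.001})
        with pytest.raises(InvalidInputError):
            compare_rates(d, b)

    def test_monte_carlo_fast_dissociation_regime(self):
        # fitted-from-trace comparison flags exceeds in a clearly separated regime
        rng = np.random.default_rng(11)
        t_assoc = np.linspace(0.0, 600.0, 121)
        t_disp = np.linspace(0.0, 400.0, 201)
        p_assoc = KineticParams(k_bind=0.02, F_free=100.0, A=100.0)
        p_disp = KineticParams(k_diss=0.1, F_free=100.0, A=100.0, f_ret=0.2, t_inj=100.0, d_inj=1.0)
        n_exceeds = 0
        for _ in range(15):
            b = fit_k_bind(add_noise(simulate_association(p_assoc, t_assoc), 2.0, rng))
            d = fit_k_diss(add_noise(simulate_displacement(p_disp, t_disp), 2.0, rng))
            if compare_rates(d, b).exceeds:
                n_exceeds += 1
        assert n_exceeds >= 14


class TestFoldChange:
    def test_identity(self):
        x = _result(k_bind=0.033, errors={"k_bind": 0.001})
        fc = fold_change(x, x, "k_bind")
        assert fc.ratio == 1.0

    def test_programmed_28fold_ratio(self):
        m = _result(k_bind=0.28, errors={"k_bind": 0.001})
        w = _result(k_bind=0.01, errors={"k_bind": 0.0005})
        assert fold_change(m, w, "k_bind").ratio == pytest.approx(28.0)

    def test_quadrature_propagation(self):
        m = _result(k_hydr=1.0, errors={"k_hydr": 0.03})
        w = _result(k_hydr=1.0, errors={"k_hydr": 0.04})
        fc = fold_change(m, w, "k_hydr")
        assert fc.rel_error == pytest.approx(0.05, rel=1e-9)

    def test_wildtype_at_lower_bound_unstable(self):
        m = _result(k_hydr=0.1, errors={"k_hydr": 0.001})
        w = _result(k_hydr=1e-8, errors={"k_hydr": 1e-9})
        with pytest.raises(DivisionUnstableError):
            fold_change(m, w, "k_hydr")


class TestBatchFit:
    def test_tidy_frame(self, wt_params, dead_params):
        t = np.linspace(0.0, 1800.0, 181)
        traces = {
            "A01": simulate_binding_hydrolysis(wt_params, t),
            "A02": simulate_binding_hydrolysis(dead_params, t),
        }
        df = batch_fit(traces, baseline_mode="initial")
        assert list(df["well"]) == ["A01", "A02"]
        assert df["converged"].all()
        assert df.loc[0, "k_bind"] == pytest.approx(0.01, rel=1e-3)

    def test_degenerate_well_flagged_not_fatal(self, wt_params):
        t = np.linspace(0.0, 1800.0, 181)
        traces = {
            "A01": simulate_binding_hydrolysis(wt_params, t),
            "A02": KineticTrace(t, np.full(t.size, 7.0), "binding_hydrolysis"),
        }
        df = batch_fit(traces, baseline_mode="initial")
        assert not df.loc[df["well"] == "A02", "converged"].iloc[0]
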