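"""Coupled Price-equation trait dynamics."""

import numpy as np
import pytest

from epievo import (EpiState, EvoState, ModelParams, TraitFloorError,
                    default_evo_init, default_init, endemic_equilibrium,
                    evo_equilibrium, evo_rhs, fitness_rates, integrate_epi,
                    integrate_evo)


def _state(sH, sL, iH, iL, eH, eL):
    return EvoState(EpiState(sH, sL, iH, iL), eH, eL)


class TestFitnessRates:
    def test_within_type_rate_arithmetic(self, baseline):
        r = fitness_rates(_state(1250, 0, 1, 1, 0.25, 0.25), baseline)
        assert r.rHH == pytest.approx(18.105, abs=1e-12)

    def test_no_susceptibles_only_losses(self, baseline):
        r = fitness_rates(_state(0.0, 10.0, 1, 1, 0.25, 0.25), baseline)
        assert r.rHH == pytest.approx(-0.645, abs=1e-12)
        assert r.rHH < 0

    def test_cross_type_rates_are_pure_transmission(self, baseline):
        r = fitness_rates(_state(100.0, 0.0, 1, 1, 0.3, 0.7), baseline)
        assert r.rLH == 0.0          # no low-yield susceptibles
        assert r.rHL >= 0.0
        # rHL uses the low-yield transmission function on sH
        bL = baseline.rho * (baseline.low.c + 0.7 ** baseline.x)
        assert r.rHL == pytest.approx(bL * 100.0, rel=1e-12)


class TestEvoRhs:
    def test_symmetric_state_arithmetic(self, baseline):
        """Within-type selection plus cross-type variance flow, both
        evaluated at eps = 0.25 (so eps**(x-1) = 2)."""
        d = evo_rhs(_state(1250, 1250, 1, 1, 0.25, 0.25), baseline)
        assert d[4] == pytest.approx(24.9, abs=1e-10)
        assert d[5] == pytest.approx(24.0, abs=1e-10)

    def test_zero_variance_equal_traits_freezes_traits(self, baseline):
        pp = baseline.with_updates(varH=0.0, varL=0.0)
        d = evo_rhs(_state(500, 700, 3, 5, 0.25, 0.25), pp)
        assert d[4] == 0.0 and d[5] == 0.0

    def test_pure_virulence_cost_without_susceptibles(self, baseline):
        d = evo_rhs(_state(0, 0, 1, 1, 0.25, 0.25), baseline)
        assert d[4] == pytest.approx(-baseline.high.y, abs=1e-12)
        assert d[5] == pytest.approx(-baseline.low.y, abs=1e-12)

    def test_nonpositive_trait_rejected(self, baseline):
        with pytest.raises(ValueError):
            evo_rhs(_state(1, 1, 1, 1, 0.0, 0.25), baseline)

    def test_selection_sign_without_mixing(self, baseline):
        """With the between-type terms off, the trait moves with the
        sign of the selection gradient rho*x*eps**(x-1)*s - y."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            sH = rng.uniform(0, 100)
            eH = rng.uniform(0.05, 3.0)
            st = _state(sH, 50.0, 1.0, 1.0, eH, 0.5)
            d = evo_rhs(st, baseline, include_mixing=False)
            grad = (baseline.rho * baseline.x * eH ** (baseline.x - 1) * sH
                    - baseline.high.y)
            assert np.sign(d[4]) == np.sign(grad)

    def test_mixing_guard_when_infected_class_empty(self, baseline):
        """iL/iH is singular at iH=0; the guard zeroes the import term
        instead of dividing by (near) zero."""
        d = evo_rhs(_state(100, 100, 0.0, 5.0, 0.3, 0.9), baseline)
        assert np.isfinite(d).all()


class TestIntegrateEvo:
    def test_zero_variance_reduces_to_fixed_trait_model(self, baseline):
        pp = baseline.with_updates(varH=0.0, varL=0.0)
        grid = np.linspace(0, 300, 301)
        evo = integrate_evo(default_evo_init(pp), pp, 300.0, grid)
        epi = integrate_epi(default_init(pp), 0.25, 0.25, pp, 300.0, grid)
        assert np.allclose(evo.frame["epsH"], 0.25, atol=1e-12)
        assert np.allclose(evo.frame["epsL"], 0.25, atol=1e-12)
        a = evo.frame[["sH", "sL", "iH", "iL"]].to_numpy()
        b = epi.frame[["sH", "sL", "iH", "iL"]].to_numpy()
        assert np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-6)) < 1e-6

    def test_trait_rise_dip_and_positive_equilibrium(self, baseline):
        """Early selection pushes both traits well above the start;
        susceptible depletion then pulls them back; the system settles
        at an elevated equilibrium with the traits nearly equal early."""
        traj = integrate_evo(default_evo_init(baseline), baseline,
                             1500.0, np.linspace(0, 1500, 6001))
        f = traj.frame
        early = f[f.time <= 2.0]
        assert early.epsH.max() > 4 * 0.25
        assert (early.epsH - early.epsL).abs().max() < early.epsH.max()
        peak_H = f.epsH.max()
        after_peak = f.epsH.to_numpy()[f.epsH.to_numpy().argmax():]
        assert after_peak.min() < 0.95 * peak_H          # a dip exists
        assert f.epsH.iloc[-1] > 0.25 and f.epsL.iloc[-1] > 0.25
        assert (f[["epsH", "epsL"]].to_numpy() > 0).all()

    def test_equilibrium_trait_divergence_grows_with_virulence_gap(
            self, baseline):
        gaps = []
        for yL in (0.5, 1.0, 1.5):
            pp = baseline.with_updates(yL=yL)
            eq = evo_equilibrium(pp)
            gaps.append(eq.state.epsH - eq.state.epsL)
        assert gaps[0] < gaps[1] < gaps[2]

    def test_tolerance_halving_stability(self, baseline):
        kw = dict(t_end=100.0, grid=np.array([0.0, 100.0]))
        y1 = integrate_evo(default_evo_init(baseline), baseline,
                           **kw).final_state().as_array()
        y2 = integrate_evo(default_evo_init(baseline), baseline,
                           rtol=5e-9, atol=5e-11, **kw).final_state().as_array()
        assert np.max(np.abs(y1 - y2) / np.abs(y1)) < 1e-6

    def test_trait_floor_raises(self, baseline):
        """With no susceptibles and no influx of them, virulence drags
        the trait linearly toward zero: the floor must raise, not
        clamp silently."""
        pp = baseline.with_updates(p=1.0)
        init = EvoState(EpiState(0.0, 2500.0, 0.5, 0.5), 0.25, 0.25)
        with pytest.raises(TraitFloorError):
            integrate_evo(init, pp, 50.0, 101)


def test_host_type_relabelling_symmetry(baseline):
    """Swapping the two host types' trade-off coefficients together
    with p <-> 1-p and the initial conditions swaps the trajectory
    components exactly."""
    pp = baseline.with_updates(p=0.3)
    swapped = ModelParams.from_dict({
        "cH": pp.low.c, "cL": pp.high.c, "yH": pp.low.y, "yL": pp.high.y,
        "x": pp.x, "rho": pp.rho, "lam": pp.lam, "p": 1 - pp.p,
        "delta": pp.delta, "gamma": pp.gamma,
        "varH": pp.varL, "varL": pp.varH,
    })
    init = EvoState(EpiState(1750.0, 750.0, 0.2, 0.1), 0.3, 0.2)
    init_sw = EvoState(EpiState(750.0, 1750.0, 0.1, 0.2), 0.2, 0.3)
    grid = np.linspace(0, 50, 201)
    a = integrate_evo(init, pp, 50.0, grid).frame
    b = integrate_evo(init_sw, swapped, 50.0, grid).frame
    for col, swp in [("sH", "sL"), ("iH", "iL"), ("epsH", "epsL")]:
        assert np.allclose(a[col], b[swp], rtol=1e-6, atol=1e-8)
        assert np.allclose(a[swp], b[col], rtol=1e-6, atol=1e-8)


class TestEvoEquilibrium:
    def test_matches_terminal_integration(self, baseline):
        eq = evo_equilibrium(baseline)
        assert eq.residual < 1e-8
        traj = integrate_evo(default_evo_init(baseline), baseline,
                             5000.0, np.array([0.0, 5000.0]))
        y_int = traj.final_state().as_array()
        y_root = eq.state.as_array()
        assert np.max(np.abs(y_int - y_root) / np.abs(y_root)) < 1e-4

    def test_zero_variance_reduces_to_fixed_trait_equilibrium(
            self, baseline):
        pp = baseline.with_updates(varH=0.0, varL=0.0)
        eq = evo_equilibrium(pp)
        fixed = endemic_equilibrium(0.25, 0.25, pp)
        assert eq.state.epsH == 0.25 and eq.state.epsL == 0.25
        assert np.allclose(eq.state.epi.as_array(),
                           fixed.state.as_array(), rtol=1e-8)

    def test_symmetric_hosts_equal_traits(self, baseline):
        pp = baseline.with_updates(cH=0.5, cL=0.5, yH=0.4, yL=0.4, p=0.5)
        eq = evo_equilibrium(pp)
        assert eq.state.epsH == pytest.approx(eq.state.epsL, rel=1e-8)
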