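"""Scenario presets and scan drivers.

Presets bundle the parameter sets of the study's reference scenarios
(a baseline heterogeneous host population, two host-quality-gap
variants with no evolution, and the composition/quality-gap scan
bases).  The scan drivers map the model over host-composition grids
(``scan_host_composition``), composition x quality-gap grids
(``scan_quality_grid``) and trait-variance grids (``scan_variance``),
reporting equilibrium transmission-dispersion summaries as tidy
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dispersion import annotate_trajectory, dispersion, DispersionSummary
from .epi import endemic_equilibrium, integrate_epi
from .evo import (DEFAULT_EPS0, EvoEquilibrium, default_evo_init,
                  evo_equilibrium, integrate_evo)
from .params import ModelParams
from .states import EvoState, Trajectory

__all__ = [
    "Scenario",
    "ScenarioResult",
    "PRESETS",
    "get_preset",
    "run_scenario",
    "scan_host_composition",
    "scan_quality_grid",
    "scan_variance",
]

#: default simulation horizon when a scenario does not set one; long
#: enough for the baseline scenarios to settle close to equilibrium
DEFAULT_T_END = 2000.0
DEFAULT_N_OUT = 2001


@dataclass(frozen=True)
class Scenario:
    """A named, fully specified simulation setup."""

    name: str
    params: ModelParams
    evolution: bool = True
    eps0: float = DEFAULT_EPS0
    i0: float = 0.1
    t_end: float = DEFAULT_T_END
    n_out: int = DEFAULT_N_OUT

    def initial_state(self) -> EvoState:
        return default_evo_init(self.params, eps0=self.eps0, i0=self.i0)


def _fig1_common(**over) -> ModelParams:
    base = dict(x=0.5, lam=50.0, delta=0.02, gamma=0.6, rho=1e-2,
                varH=1.0, varL=1.0, p=0.5)
    base.update(over)
    return ModelParams.from_dict(base)


PRESETS: dict[str, Scenario] = {
    # baseline heterogeneous population, evolution on
    "fig3_baseline": Scenario("fig3_baseline", ModelParams.baseline()),
    # fixed-trait host-quality-gap scenarios (no evolution, eps = 0.25)
    "fig1_Re_gap_small": Scenario(
        "fig1_Re_gap_small",
        _fig1_common(cH=0.1, cL=0.0, yH=0.1, yL=0.2), evolution=False),
    "fig1_Re_gap_large": Scenario(
        "fig1_Re_gap_large",
        _fig1_common(cH=1.0, cL=0.0, yH=0.1, yL=1.0), evolution=False),
    # composition scan base (same parameters as the baseline)
    "fig6": Scenario("fig6", ModelParams.baseline()),
    # quality-gap grid base
    "fig7": Scenario(
        "fig7", _fig1_common(cH=0.5, cL=0.0, yH=0.1, yL=1.0)),
}


def get_preset(name: str, **overrides) -> Scenario:
    try:
        sc = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; "
                       f"known: {sorted(PRESETS)}") from None
    return replace(sc, **overrides) if overrides else sc


@dataclass(frozen=True)
class ScenarioResult:
    """Annotated trajectory plus the equilibrium and its dispersion."""

    scenario: Scenario
    trajectory: Trajectory
    equilibrium: EvoEquilibrium
    equilibrium_dispersion: DispersionSummary


def run_scenario(scenario: Scenario) -> ScenarioResult:
    """Integrate a scenario, annotate its trajectory with fitness and
    dispersion metrics, and locate its endemic equilibrium."""
    params = scenario.params
    init = scenario.initial_state()
    if scenario.evolution:
        traj = integrate_evo(init, params, scenario.t_end, scenario.n_out)
        eq = evo_equilibrium(params, init_guess=init)
    else:
        traj = integrate_epi(init.epi, scenario.eps0, scenario.eps0,
                             params, scenario.t_end, scenario.n_out)
        epi_eq = endemic_equilibrium(scenario.eps0, scenario.eps0, params,
                                     init=init.epi)
        eq = EvoEquilibrium(
            EvoState(epi_eq.state, scenario.eps0, scenario.eps0),
            epi_eq.disease_free, epi_eq.residual)
    ann = annotate_trajectory(traj, params, epsH=scenario.eps0,
                              epsL=scenario.eps0)
    disp = dispersion(eq.state, params)
    return ScenarioResult(scenario, ann, eq, disp)


def _eq_dispersion(params: ModelParams, eps0: float,
                   evolution: bool) -> tuple[EvoEquilibrium, DispersionSummary]:
    if evolution:
        eq = evo_equilibrium(params,
                             init_guess=default_evo_init(params, eps0=eps0))
    else:
        epi_eq = endemic_equilibrium(eps0, eps0, params)
        eq = EvoEquilibrium(EvoState(epi_eq.state, eps0, eps0),
                            epi_eq.disease_free, epi_eq.residual)
    return eq, dispersion(eq.state, params)


def scan_host_composition(params: ModelParams, p_grid: Sequence[float],
                          eps0: float = DEFAULT_EPS0,
                          evolution: bool = True) -> pd.DataFrame:
    """Evolved (or fixed-trait) equilibrium dispersion across host
    compositions.

    One row per influx proportion p: the equilibrium percentage of
    low-yield susceptibles, vmr(Re), traits and a disease-free flag.
    """
    rows = []
    for p in p_grid:
        if not 0 <= p <= 1:
            raise ValueError(f"p values must lie in [0, 1], got {p}")
        pp = params.with_updates(p=float(p))
        eq, disp = _eq_dispersion(pp, eps0, evolution)
        st = eq.state
        s_tot = st.sH + st.sL
        rows.append({
            "p": float(p),
            "pct_SL": st.sL / s_tot if s_tot > 0 else np.nan,
            "vmr": disp.vmr,
            "Re": disp.Re,
            "epsH": st.epsH,
            "epsL": st.epsL,
            "disease_free": eq.disease_free,
        })
    return pd.DataFrame(rows)


def scan_quality_grid(base_params: ModelParams, p_grid: Sequence[float],
                      axis: str, axis_values: Sequence[float],
                      eps_fixed: float = DEFAULT_EPS0) -> pd.DataFrame:
    """Delta-vmr surface over host composition and a host-quality axis.

    For every (p, axis value) cell, computes the equilibrium vmr with
    evolution and with the trait fixed at ``eps_fixed``, and their
    difference.  ``axis`` is any flat parameter key (typically ``cH``
    or ``yL``).  Per-cell failures are recorded (``error`` column) and
    the scan continues.
    """
    if len(p_grid) == 0 or len(axis_values) == 0:
        raise ValueError("scan grids must be nonempty")
    rows = []
    for v in axis_values:
        for p in p_grid:
            pp = base_params.with_updates(**{axis: float(v), "p": float(p)})
            row = {"p": float(p), axis: float(v)}
            try:
                _, d_evo = _eq_dispersion(pp, eps_fixed, evolution=True)
                _, d_fix = _eq_dispersion(pp, eps_fixed, evolution=False)
                row.update(vmr_evolved=d_evo.vmr, vmr_fixed=d_fix.vmr,
                           delta_vmr=d_evo.vmr - d_fix.vmr, error="")
            except Exception as exc:  # noqa: BLE001 - scan must continue
                row.update(vmr_evolved=np.nan, vmr_fixed=np.nan,
                           delta_vmr=np.nan, error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def _early_peak(times: np.ndarray, vmr: np.ndarray,
                i_tot: np.ndarray) -> tuple[float, float]:
    """Max vmr before the first local minimum of total infections."""
    # first interior local min of iH+iL; fall back to the full range
    idx = len(i_tot)
    for j in range(1, len(i_tot) - 1):
        if i_tot[j] <= i_tot[j - 1] and i_tot[j] < i_tot[j + 1]:
            idx = j + 1
            break
    window = vmr[:idx]
    j_peak = int(np.nanargmax(window))
    return float(window[j_peak]), float(times[j_peak])


def scan_variance(params: ModelParams, var_grid: Sequence[float],
                  eps0: float = DEFAULT_EPS0, early_window: float = 30.0,
                  n_out: int = 3001) -> pd.DataFrame:
    """Effect of the phenotypic trait variance (set equally in both
    host types) on early and equilibrium transmission dispersion.

    One row per variance value: the peak vmr before the first dip in
    total infections, its time, and the equilibrium vmr and traits.
    The early peak is resolved on a dense grid over ``early_window``
    (the initial trait surge is much faster than the epidemic's
    relaxation to equilibrium).
    """
    rows = []
    for var in var_grid:
        if var < 0:
            raise ValueError("variances must be >= 0")
        pp = params.with_updates(varH=float(var), varL=float(var))
        if var == 0:
            traj = integrate_epi(default_evo_init(pp, eps0=eps0).epi,
                                 eps0, eps0, pp, early_window, n_out)
        else:
            traj = integrate_evo(default_evo_init(pp, eps0=eps0), pp,
                                 early_window, n_out)
        ann = annotate_trajectory(traj, pp, epsH=eps0, epsL=eps0)
        f = ann.frame
        peak, t_peak = _early_peak(f["time"].to_numpy(),
                                   f["vmr"].to_numpy(),
                                   (f["iH"] + f["iL"]).to_numpy())
        eq, disp = _eq_dispersion(pp, eps0, evolution=var > 0)
        rows.append({
            "var": float(var),
            "early_peak_vmr": peak,
            "t_peak": t_peak,
            "eq_vmr": disp.vmr,
            "eq_epsH": eq.state.epsH,
            "eq_epsL": eq.state.epsL,
        })
    return pd.DataFrame(rows)
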