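"""Coupled epidemiological–evolutionary dynamics.

The mean within-host growth rate among infections of each host type
evolves by a Price-equation approximation (mutation ignored, trait
variances held constant), in which cov(eps, r) is replaced by
var_j(eps) * dr/deps:

    deps_H/dt = varH*(rho*x*epsH**(x-1)*sH - yH)
              + (iL/iH)*( beta_L*sH*(epsL - epsH)
                          + varL*rho*x*epsL**(x-1)*sH )

and symmetrically for eps_L.  The first bracket is within-type
selection — susceptible abundance selects the trait up, virulence
selects it down.  The (iL/iH)-weighted bracket is trait flow between
host types: migration of trait values when the two means differ, plus
selection during cross-type transmission.

The four epidemiological derivatives are those of :mod:`epievo.epi`
evaluated at the current means.  Together this is a 6-dimensional ODE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .dispersion import reproduction_number
from .epi import (DEFAULT_ATOL, DEFAULT_RTOL, EndemicEquilibrium,
                  IntegrationError, _clip_negatives, _epi_rhs, _make_grid,
                  _settle, default_init, disease_free_equilibrium,
                  endemic_equilibrium)
from .params import ModelParams
from .states import EVO_COLUMNS, EpiState, EvoState, Trajectory

__all__ = [
    "TraitFloorError",
    "FitnessRates",
    "EvoEquilibrium",
    "default_evo_init",
    "fitness_rates",
    "evo_rhs",
    "integrate_evo",
    "evo_equilibrium",
]

log = logging.getLogger(__name__)

#: hard lower bound on mean traits; eps**(x-1) is singular at 0 for x<1
#: and selection is not expected to drive the trait to 0
EPS_FLOOR = 1e-6

#: infected densities below this floor disable the corresponding
#: between-type mixing term (no infections of that type to import from)
I_FLOOR = 1e-10

DEFAULT_EPS0 = 0.25


class TraitFloorError(IntegrationError):
    """A mean trait fell below the positivity floor during integration."""


def default_evo_init(params: ModelParams, eps0: float = DEFAULT_EPS0,
                     i0: float = 0.1) -> EvoState:
    """Default start: epidemiological default plus equal initial means."""
    return EvoState(default_init(params, i0=i0), eps0, eps0)


@dataclass(frozen=True)
class FitnessRates:
    """Per-capita rates of production of new infections.

    ``rHH``: from high-yield infections into high-yield hosts (net of
    removal); ``rLL`` likewise within low-yield; ``rHL`` and ``rLH``
    are the pure cross-type transmission terms (no removal)."""

    rHH: float
    rHL: float
    rLL: float
    rLH: float


def fitness_rates(state: EvoState, params: ModelParams) -> FitnessRates:
    state.validate()
    bH = params.rho * (params.high.c + state.epsH ** params.x)
    bL = params.rho * (params.low.c + state.epsL ** params.x)
    aH = params.high.y * state.epsH
    aL = params.low.y * state.epsL
    out = params.delta + params.gamma
    return FitnessRates(
        rHH=bH * state.sH - (out + aH),
        rHL=bL * state.sH,
        rLL=bL * state.sL - (out + aL),
        rLH=bH * state.sL,
    )


def _evo_rhs(t, y, params: ModelParams, include_mixing: bool = True,
             i_floor: float = I_FLOOR):
    sH, sL, iH, iL, eH, eL = y
    d_epi = _epi_rhs(t, y[:4], eH, eL, params)
    x, rho = params.x, params.rho
    gH = rho * x * eH ** (x - 1.0)
    gL = rho * x * eL ** (x - 1.0)
    bH = rho * (params.high.c + eH ** x)
    bL = rho * (params.low.c + eL ** x)
    deH = params.varH * (gH * sH - params.high.y)
    deL = params.varL * (gL * sL - params.low.y)
    if include_mixing:
        if iH > i_floor:
            deH += (iL / iH) * (bL * sH * (eL - eH) + params.varL * gL * sH)
        if iL > i_floor:
            deL += (iH / iL) * (bH * sL * (eH - eL) + params.varH * gH * sL)
    return np.concatenate([d_epi, [deH, deL]])


def evo_rhs(state: EvoState, params: ModelParams,
            include_mixing: bool = True,
            i_floor: float = I_FLOOR) -> tuple[float, ...]:
    """Six time-derivatives (dsH, dsL, diH, diL, depsH, depsL).

    ``include_mixing=False`` drops the between-type trait-flow terms,
    exposing the pure within-type selection gradient.
    """
    state.validate()
    return tuple(_evo_rhs(0.0, state.as_array(), params,
                          include_mixing, i_floor))


def integrate_evo(init: EvoState, params: ModelParams, t_end: float,
                  grid=None, rtol: float = DEFAULT_RTOL,
                  atol: float = DEFAULT_ATOL,
                  method: str = "LSODA") -> Trajectory:
    """Integrate the coupled 6-dimensional system over [0, t_end].

    Raises :class:`TraitFloorError` if either mean trait reaches the
    positivity floor (selection is driving the trait toward the
    singular point of the transmission gradient).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    init.validate()
    t_eval = _make_grid(t_end, grid)

    def floor_H(t, y, *args):
        return y[4] - EPS_FLOOR

    def floor_L(t, y, *args):
        return y[5] - EPS_FLOOR

    floor_H.terminal = True
    floor_L.terminal = True

    sol = solve_ivp(_evo_rhs, (0.0, t_end), init.as_array(),
                    t_eval=t_eval, args=(params,), method=method,
                    rtol=rtol, atol=atol, events=[floor_H, floor_L])
    if sol.status == 1:
        t_hit = min(float(te[0]) for te in sol.t_events if len(te))
        raise TraitFloorError(
            f"mean trait fell to the positivity floor {EPS_FLOOR:g} "
            f"at t={t_hit:.4g}")
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    y = sol.y.T.copy()
    y[:, :4] = _clip_negatives(y[:, :4], "integrate_evo")
    return Trajectory.from_arrays(sol.t, y, EVO_COLUMNS)


@dataclass(frozen=True)
class EvoEquilibrium:
    """Stationary state of the coupled system (see EndemicEquilibrium)."""

    state: EvoState
    disease_free: bool
    residual: float


def _reduced_equilibrium(params: ModelParams, present: str,
                         eps0: float, absent_eps: float,
                         residual_tol: float) -> EvoEquilibrium:
    """Single-host-type endemic equilibrium with evolving trait.

    Used at the composition boundaries p=0 (only high-yield hosts) and
    p=1 (only low-yield hosts), where the full system's trait equation
    for the absent type is meaningless.  The absent type's densities
    are 0 and its trait is reported at ``absent_eps``.
    """
    host = params.high if present == "H" else params.low
    var = params.varH if present == "H" else params.varL
    influx = params.lam * (1 - params.p if present == "H" else params.p)
    out = params.delta + params.gamma

    if var == 0.0:
        eq = endemic_equilibrium(eps0, eps0, params)
        st = EvoState(eq.state, eps0, eps0)
        return EvoEquilibrium(st, eq.disease_free, eq.residual)

    def rhs(t, y):
        s, i, e = y
        b = params.rho * (host.c + e ** params.x)
        a = host.y * e
        g = params.rho * params.x * e ** (params.x - 1.0)
        return np.array([influx - b * i * s - params.delta * s,
                         b * i * s - (out + a) * i,
                         var * (g * s - host.y)])

    y0 = np.array([influx / params.delta, 0.1, eps0])
    warm, _ = _settle(rhs, y0)
    sol = root(lambda y: rhs(0.0, y), warm, method="hybr", tol=1e-13)
    y = sol.x if sol.success else warm
    res = float(np.max(np.abs(rhs(0.0, y))))
    if res > residual_tol:
        raise IntegrationError(
            f"boundary equilibrium residual {res:.3e} exceeds "
            f"{residual_tol:g}")
    s, i, e = y
    disease_free = i < 1e-8
    if present == "H":
        st = EvoState(EpiState(max(s, 0.0), 0.0, max(i, 0.0), 0.0),
                      e, absent_eps)
    else:
        st = EvoState(EpiState(0.0, max(s, 0.0), 0.0, max(i, 0.0)),
                      absent_eps, e)
    return EvoEquilibrium(st, disease_free, res)


def evo_equilibrium(params: ModelParams,
                    init_guess: EvoState | None = None,
                    residual_tol: float = 1e-8) -> EvoEquilibrium:
    """Joint epidemiological–evolutionary equilibrium.

    Warm-starts by integrating the coupled system until it flattens,
    then polishes with a root solve on the full 6-dimensional RHS.
    At the composition boundaries (p = 0 or 1) the reduced
    single-host-type system is solved instead.
    """
    guess = init_guess if init_guess is not None else default_evo_init(params)
    guess.validate()

    if params.p == 0.0:
        return _reduced_equilibrium(params, "H", guess.epsH, guess.epsL,
                                    residual_tol)
    if params.p == 1.0:
        return _reduced_equilibrium(params, "L", guess.epsL, guess.epsH,
                                    residual_tol)

    if params.varH == 0.0 and params.varL == 0.0 and guess.epsH == guess.epsL:
        # traits cannot move: reduces to the fixed-trait model
        eq = endemic_equilibrium(guess.epsH, guess.epsL, params,
                                 init=guess.epi)
        st = EvoState(eq.state, guess.epsH, guess.epsL)
        return EvoEquilibrium(st, eq.disease_free, eq.residual)

    dfe = disease_free_equilibrium(params)
    if reproduction_number(dfe, params, epsH=guess.epsH,
                           epsL=guess.epsL) <= 1.0:
        st = EvoState(dfe, guess.epsH, guess.epsL)
        return EvoEquilibrium(st, True, 0.0)

    def rhs(t, y):
        return _evo_rhs(t, y, params)

    def floor_evt(t, y):
        return min(y[4], y[5]) - EPS_FLOOR

    floor_evt.terminal = True

    warm, _ = _settle(rhs, guess.as_array(), events=[floor_evt])
    sol = root(lambda y: rhs(0.0, y), warm, method="hybr", tol=1e-13)
    y = np.asarray(sol.x if sol.success else warm)
    res = float(np.max(np.abs(rhs(0.0, y))))
    if res > residual_tol:
        raise IntegrationError(
            f"evolutionary equilibrium residual {res:.3e} exceeds "
            f"{residual_tol:g} (best residual reported)")
    y[:4] = _clip_negatives(y[:4], "evo_equilibrium")
    st = EvoState.from_array(y)
    return EvoEquilibrium(st, st.iH + st.iL < 1e-8, res)
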