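"""Fixed-trait (no-evolution) epidemiological dynamics.

The two-host-type SI system with demographic turnover:

    dsH/dt = lam*(1-p) - (beta_H*iH + beta_L*iL)*sH - delta*sH
    dsL/dt = lam*p     - (beta_H*iH + beta_L*iL)*sL - delta*sL
    diH/dt = (beta_H*iH + beta_L*iL)*sH - (delta + gamma + alpha_H)*iH
    diL/dt = (beta_H*iH + beta_L*iL)*sL - (delta + gamma + alpha_L)*iL

Transmission depends on the source (infected) host type: beta_H and
alpha_H are evaluated at the trait carried by high-yield infections,
beta_L and alpha_L at the trait of low-yield infections.  Here both
traits are fixed; the coupled evolving system lives in
:mod:`epievo.evo`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .dispersion import reproduction_number
from .params import ModelParams, transmission_rate, virulence_rate
from .states import EPI_COLUMNS, EpiState, Trajectory

__all__ = [
    "IntegrationError",
    "EndemicEquilibrium",
    "default_init",
    "disease_free_equilibrium",
    "epi_rhs",
    "integrate_epi",
    "endemic_equilibrium",
]

log = logging.getLogger(__name__)

#: undershoot more negative than this aborts with an error; smaller
#: undershoot is clipped to zero with a warning
NEG_TOL = 1e-7

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces an invalid state."""


def default_init(params: ModelParams, i0: float = 0.1) -> EpiState:
    """Default initial condition: susceptibles at the disease-free
    equilibrium, seeded with a small infected density in each type."""
    dfe = disease_free_equilibrium(params)
    return EpiState(dfe.sH, dfe.sL, i0, i0)


def disease_free_equilibrium(params: ModelParams) -> EpiState:
    """sH = lam*(1-p)/delta, sL = lam*p/delta, no infections."""
    return EpiState(params.lam * (1 - params.p) / params.delta,
                    params.lam * params.p / params.delta, 0.0, 0.0)


def _epi_rhs(t, y, epsH, epsL, params: ModelParams):
    sH, sL, iH, iL = y
    bH = params.rho * (params.high.c + epsH ** params.x)
    bL = params.rho * (params.low.c + epsL ** params.x)
    aH = params.high.y * epsH
    aL = params.low.y * epsL
    foi = bH * iH + bL * iL
    return np.array([
        params.lam * (1 - params.p) - foi * sH - params.delta * sH,
        params.lam * params.p - foi * sL - params.delta * sL,
        foi * sH - (params.delta + params.gamma + aH) * iH,
        foi * sL - (params.delta + params.gamma + aL) * iL,
    ])


def epi_rhs(state: EpiState, epsH: float, epsL: float,
            params: ModelParams) -> tuple[float, float, float, float]:
    """Time derivatives (dsH, dsL, diH, diL) at a state with fixed traits."""
    state.validate()
    if epsH < 0 or epsL < 0:
        raise ValueError("traits must be >= 0")
    # go through the trade-off functions so their domain checks apply
    transmission_rate(epsH, params.high, params)
    virulence_rate(epsL, params.low)
    return tuple(_epi_rhs(0.0, state.as_array(), epsH, epsL, params))


def _clip_negatives(y: np.ndarray, what: str) -> np.ndarray:
    low = y.min()
    if low < -NEG_TOL:
        raise IntegrationError(
            f"{what}: state component fell to {low:.3e} (below -{NEG_TOL:g})")
    if low < 0:
        log.warning("%s: clipping small negative undershoot (min %.3e) to 0",
                    what, low)
        y = np.clip(y, 0.0, None)
    return y


def _make_grid(t_end: float, grid) -> np.ndarray:
    if grid is None:
        return np.linspace(0.0, t_end, 501)
    if np.isscalar(grid):
        return np.linspace(0.0, t_end, int(grid))
    return np.asarray(grid, dtype=float)


def integrate_epi(init: EpiState, epsH: float, epsL: float,
                  params: ModelParams, t_end: float, grid=None,
                  rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                  method: str = "LSODA") -> Trajectory:
    """Integrate the fixed-trait system over [0, t_end].

    ``grid`` may be None (501 equispaced output points), an integer
    number of points, or an explicit array of output times.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    init.validate()
    t_eval = _make_grid(t_end, grid)
    sol = solve_ivp(_epi_rhs, (0.0, t_end), init.as_array(),
                    t_eval=t_eval, args=(epsH, epsL, params),
                    method=method, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    y = _clip_negatives(sol.y.T, "integrate_epi")
    return Trajectory.from_arrays(sol.t, y, EPI_COLUMNS)


def _settle(rhs, y0, *, chunk: float = 500.0, t_max: float = 2e5,
            tol: float = 1e-9, rtol: float = DEFAULT_RTOL,
            atol: float = DEFAULT_ATOL, events=None):
    """Integrate in chunks until the RHS norm drops below ``tol``.

    Returns (state, time_reached).  Used as a warm start for
    equilibrium root-finding.
    """
    t, y = 0.0, np.asarray(y0, dtype=float)
    while t < t_max:
        sol = solve_ivp(rhs, (t, t + chunk), y, method="LSODA",
                        rtol=rtol, atol=atol, events=events)
        if not sol.success:
            raise IntegrationError(f"equilibrium search failed: {sol.message}")
        if sol.status == 1:  # terminal event fired
            raise IntegrationError(
                "equilibrium search terminated by solver event")
        y = sol.y[:, -1]
        t = sol.t[-1]
        if np.max(np.abs(rhs(t, y))) < tol:
            break
    return y, t


@dataclass(frozen=True)
class EndemicEquilibrium:
    """Root-found stationary state.

    ``disease_free`` is True when no positive-infection equilibrium
    exists (Re at the disease-free state <= 1, or the root collapsed
    onto it); ``residual`` is the max absolute RHS component at the
    returned state.
    """

    state: EpiState
    disease_free: bool
    residual: float


def endemic_equilibrium(epsH: float, epsL: float, params: ModelParams,
                        init: EpiState | None = None,
                        residual_tol: float = 1e-8) -> EndemicEquilibrium:
    """Stationary state of the fixed-trait system.

    Integrates from ``init`` (default :func:`default_init`) until the
    dynamics flatten, then polishes with a Newton-type root solve and
    verifies the residual.
    """
    dfe = disease_free_equilibrium(params)
    re0 = reproduction_number(dfe, params, epsH=epsH, epsL=epsL)
    if re0 <= 1.0:
        return EndemicEquilibrium(dfe, True, 0.0)

    y0 = (init if init is not None else default_init(params)).as_array()

    def rhs(t, y):
        return _epi_rhs(t, y, epsH, epsL, params)

    warm, _ = _settle(rhs, y0)
    sol = root(lambda y: rhs(0.0, y), warm, method="hybr", tol=1e-13)
    y = sol.x if sol.success else warm
    y = _clip_negatives(np.asarray(y), "endemic_equilibrium")
    res = float(np.max(np.abs(rhs(0.0, y))))
    if res > residual_tol:
        raise IntegrationError(
            f"endemic equilibrium residual {res:.3e} exceeds {residual_tol:g}")
    if y[2] + y[3] < 1e-8:
        return EndemicEquilibrium(dfe, True, res)
    return EndemicEquilibrium(EpiState.from_array(y), False, res)
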