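"""Parasite fitness and transmission-dispersion metrics.

The expected number of new infections produced by an infected host at
time t is

    Re(t) = beta_H * sH / (delta + gamma + alpha_H)
          + beta_L * sL / (delta + gamma + alpha_L),

and transmission dispersion is the variance-to-mean ratio of Re across
the two infected host types (a superspreading proxy in the sense of
Lloyd-Smith):

    vmr(Re) = var(Re) / Re,
    var(Re) = sum_j  i_j/(iH+iL) * (Re - Re_j)^2 .

Two conventions for the per-type reproduction number Re_j are
supported.  The default "expanded" form uses the total susceptible
pool, Re_j = beta_j*(sH+sL)/(delta+gamma+alpha_j); the "compact" form
uses the type-own pool, Re_j = beta_j*s_j/(delta+gamma+alpha_j).  Note
the expanded form's var(Re) is a weighted second moment about Re, which
coincides with the central variance of the two-point distribution only
when Re equals that distribution's mean (e.g. when sH = sL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParams, transmission_rate, virulence_rate
from .states import EpiState, EvoState, Trajectory

__all__ = ["DispersionSummary", "reproduction_number", "dispersion",
           "annotate_trajectory"]

#: infected densities below this are treated as "no infections present"
I_FLOOR = 1e-10


@dataclass(frozen=True)
class DispersionSummary:
    """Fitness and dispersion metrics at one time point.

    ``ReH_pop``/``ReL_pop`` are the type-specific totals
    beta_j*(sH+sL)/(delta+gamma+alpha_j).  ``infections_present`` is
    False when iH+iL is below the floor, in which case ``varRe`` and
    ``vmr`` are reported as 0 (undefined, no infections).
    """

    Re: float
    ReH_pop: float
    ReL_pop: float
    varRe: float
    vmr: float
    infections_present: bool = True


def _rates(epsH: float, epsL: float, params: ModelParams):
    bH = transmission_rate(epsH, params.high, params)
    bL = transmission_rate(epsL, params.low, params)
    dH = params.delta + params.gamma + virulence_rate(epsH, params.high)
    dL = params.delta + params.gamma + virulence_rate(epsL, params.low)
    return bH, bL, dH, dL


def _unpack(state, epsH, epsL):
    if isinstance(state, EvoState):
        return state.epi, state.epsH, state.epsL
    if epsH is None or epsL is None:
        raise ValueError("fixed traits epsH, epsL required with an EpiState")
    return state, float(epsH), float(epsL)


def reproduction_number(state: EvoState | EpiState, params: ModelParams,
                        *, epsH: float | None = None,
                        epsL: float | None = None) -> float:
    """Expected new infections per infected host, Re(t)."""
    epi, eH, eL = _unpack(state, epsH, epsL)
    bH, bL, dH, dL = _rates(eH, eL, params)
    return bH * epi.sH / dH + bL * epi.sL / dL


def dispersion(state: EvoState | EpiState, params: ModelParams,
               *, epsH: float | None = None, epsL: float | None = None,
               form: str = "expanded",
               i_floor: float = I_FLOOR) -> DispersionSummary:
    """Re, per-type reproduction numbers, var(Re) and vmr(Re).

    Parameters
    ----------
    form : {"expanded", "compact"}
        Which per-type Re_j enters the deviation terms of var(Re);
        see the module docstring.
    """
    if form not in ("expanded", "compact"):
        raise ValueError(f"unknown dispersion form {form!r}")
    epi, eH, eL = _unpack(state, epsH, epsL)
    bH, bL, dH, dL = _rates(eH, eL, params)
    s_tot = epi.sH + epi.sL
    re = bH * epi.sH / dH + bL * epi.sL / dL
    reH_pop = bH * s_tot / dH
    reL_pop = bL * s_tot / dL

    i_tot = epi.iH + epi.iL
    if i_tot <= i_floor:
        return DispersionSummary(re, reH_pop, reL_pop, 0.0, 0.0,
                                 infections_present=False)

    if form == "expanded":
        devH, devL = re - reH_pop, re - reL_pop
    else:
        devH = re - bH * epi.sH / dH
        devL = re - bL * epi.sL / dL
    wH, wL = epi.iH / i_tot, epi.iL / i_tot
    var_re = wH * devH ** 2 + wL * devL ** 2
    if re == 0.0:
        if var_re > 0.0:
            raise ZeroDivisionError(
                "vmr undefined: Re = 0 with var(Re) > 0")
        return DispersionSummary(re, reH_pop, reL_pop, var_re, 0.0)
    return DispersionSummary(re, reH_pop, reL_pop, var_re, var_re / re)


def annotate_trajectory(traj: Trajectory, params: ModelParams,
                        *, epsH: float | None = None,
                        epsL: float | None = None,
                        form: str = "expanded") -> Trajectory:
    """Append Re, ReH_pop, ReL_pop, varRe, vmr (and a definedness flag)
    at every time point of a trajectory.

    For trajectories without trait columns the fixed traits must be
    supplied and are also recorded as constant ``epsH``/``epsL``
    columns, so every annotated trajectory shares one schema.
    """
    frame = traj.frame
    has_traits = "epsH" in frame.columns
    if not has_traits and (epsH is None or epsL is None):
        raise ValueError("fixed traits epsH, epsL required for an "
                         "epidemiological-only trajectory")
    rows = []
    for i in range(len(frame)):
        row = frame.iloc[i]
        epi = EpiState(row["sH"], row["sL"], row["iH"], row["iL"])
        eH = row["epsH"] if has_traits else epsH
        eL = row["epsL"] if has_traits else epsL
        d = dispersion(epi, params, epsH=eH, epsL=eL, form=form)
        rows.append((eH, eL, d.Re, d.ReH_pop, d.ReL_pop, d.varRe, d.vmr,
                     d.infections_present))
    extra = pd.DataFrame(
        rows, columns=["epsH", "epsL", "Re", "ReH_pop", "ReL_pop",
                       "varRe", "vmr", "vmr_defined"])
    extra["vmr_defined"] = extra["vmr_defined"].astype(bool)
    if has_traits:
        extra = extra.drop(columns=["epsH", "epsL"])
    return traj.with_columns(extra)
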