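"""Model parameters and the transmission–virulence trade-off functions.

The parasite trait under selection is its within-host growth rate
``eps``.  Higher within-host growth buys transmission at the price of
virulence (parasite-induced host mortality).  The two host types —
"high yield" (H) and "low yield" (L) from the parasite's perspective —
share the trade-off shape but differ in its coefficients:

* transmission rate   ``beta_j(eps) = rho * (c_j + eps**x)``
* virulence           ``alpha_j(eps) = y_j * eps``

with ``j in {H, L}``.  ``x`` (0 < x <= 1) controls the concavity of the
transmission return on within-host growth; ``rho`` is an overall
transmission scaling; ``c_j >= 0`` is a host-type transmission set
point and ``y_j >= 0`` the rate at which virulence rises with the
trait.  Densities and time are in the arbitrary "model units" implied
by the demographic parameters (influx ``lam``, mortality ``delta``).

Parameters round-trip through a flat mapping with keys
``cH, cL, yH, yL, x, rho, lam, p, delta, gamma, varH, varL``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "HostTypeParams",
    "ModelParams",
    "transmission_rate",
    "transmission_gradient",
    "virulence_rate",
]

FLAT_KEYS = ("cH", "cL", "yH", "yL", "x", "rho", "lam", "p",
             "delta", "gamma", "varH", "varL")


@dataclass(frozen=True)
class HostTypeParams:
    """Trade-off coefficients for one host type.

    Parameters
    ----------
    c : float
        Transmission set point (dimensionless, >= 0).  Higher in
        high-yield hosts when transmission differs between types.
    y : float
        Rate at which virulence increases with the within-host growth
        rate (per unit trait per time, >= 0).  Higher in low-yield
        hosts when virulence differs between types.
    """

    c: float
    y: float

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"transmission set point c must be >= 0, got {self.c}")
        if self.y < 0:
            raise ValueError(f"virulence slope y must be >= 0, got {self.y}")


@dataclass(frozen=True)
class ModelParams:
    """All rate constants of the two-host-type host–parasite system.

    Defaults are the baseline heterogeneous-host scenario used
    throughout: a high-yield host with high transmission and low
    virulence (cH=1, yH=0.1) against a low-yield host with the
    converse (cL=0.1, yL=1), equal influx of the two types (p=0.5),
    and unit phenotypic trait variance in both types.

    Attributes
    ----------
    high, low : HostTypeParams
        Trade-off coefficients of the two host types.
    x : float
        Concavity exponent of the transmission function, 0 < x <= 1.
    rho : float
        Transmission scaling (per host density per time, > 0).
    lam : float
        Influx rate of new susceptible hosts (hosts per time, > 0).
    p : float
        Proportion of the influx that is low-yield, in [0, 1].
    delta : float
        Natural (background) host mortality rate (per time, > 0).
    gamma : float
        Recovery rate of infected hosts (per time, >= 0).
    varH, varL : float
        Phenotypic variance of the within-host growth rate among
        infections of each host type (trait^2, >= 0).  Held constant
        in time; it scales the strength of selection.
    """

    high: HostTypeParams = HostTypeParams(c=1.0, y=0.1)
    low: HostTypeParams = HostTypeParams(c=0.1, y=1.0)
    x: float = 0.5
    rho: float = 1e-2
    lam: float = 50.0
    p: float = 0.5
    delta: float = 0.02
    gamma: float = 0.6
    varH: float = 1.0
    varL: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.x <= 1:
            raise ValueError(f"concavity exponent x must be in (0, 1], got {self.x}")
        for name in ("rho", "lam", "delta"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not 0 <= self.p <= 1:
            raise ValueError(f"influx proportion p must be in [0, 1], got {self.p}")
        if self.varH < 0 or self.varL < 0:
            raise ValueError("phenotypic variances must be >= 0")

    # -- flat-config round trip -------------------------------------------
    def to_dict(self) -> dict[str, float]:
        """Flat mapping with the canonical config keys."""
        return {
            "cH": self.high.c, "cL": self.low.c,
            "yH": self.high.y, "yL": self.low.y,
            "x": self.x, "rho": self.rho, "lam": self.lam, "p": self.p,
            "delta": self.delta, "gamma": self.gamma,
            "varH": self.varH, "varL": self.varL,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParams":
        unknown = set(d) - set(FLAT_KEYS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        base = cls.baseline().to_dict()
        base.update(d)
        return cls(
            high=HostTypeParams(c=base["cH"], y=base["yH"]),
            low=HostTypeParams(c=base["cL"], y=base["yL"]),
            x=base["x"], rho=base["rho"], lam=base["lam"], p=base["p"],
            delta=base["delta"], gamma=base["gamma"],
            varH=base["varH"], varL=base["varL"],
        )

    def with_updates(self, **flat: float) -> "ModelParams":
        """Return a copy with flat-key parameters replaced."""
        d = self.to_dict()
        unknown = set(flat) - set(FLAT_KEYS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        d.update(flat)
        return ModelParams.from_dict(d)

    @classmethod
    def baseline(cls) -> "ModelParams":
        """The baseline heterogeneous-host parameter set (class defaults)."""
        return cls()

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)


def transmission_rate(eps, host: HostTypeParams, params: ModelParams):
    """Average transmission rate ``beta_j(eps) = rho * (c_j + eps**x)``.

    Accepts scalar or array ``eps``; ``eps`` must be >= 0 (fractional
    powers of negative trait values are undefined).
    """
    eps = np.asarray(eps, dtype=float)
    if np.any(eps < 0):
        raise ValueError("within-host growth rate eps must be >= 0")
    out = params.rho * (host.c + eps ** params.x)
    return out if out.ndim else float(out)


def transmission_gradient(eps, params: ModelParams):
    """Marginal transmission gain ``d beta / d eps = rho * x * eps**(x-1)``.

    Singular at ``eps = 0`` for ``x < 1``; requires ``eps > 0``.
    """
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0):
        raise ValueError("transmission gradient requires eps > 0 (eps**(x-1) "
                         "is singular at 0 for x < 1)")
    out = params.rho * params.x * eps ** (params.x - 1.0)
    return out if out.ndim else float(out)


def virulence_rate(eps, host: HostTypeParams):
    """Parasite-induced mortality ``alpha_j(eps) = y_j * eps`` (per time)."""
    eps = np.asarray(eps, dtype=float)
    if np.any(eps < 0):
        raise ValueError("within-host growth rate eps must be >= 0")
    out = host.y * eps
    return out if out.ndim else float(out)
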