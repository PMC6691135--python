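"""Time-dependent membrane flux laws and their spatial localization.

Receptor/channel activity at the plasma membrane is modeled as a
biexponential pulse

    J_PM(t) = |gamma| * (exp(-t/alpha) - exp(-t/beta)),

the spine-apparatus (ER) membrane releases a delayed, scaled copy

    J_ER(t) = zeta * J_PM(t - t_ER)   (zero before the delay),

and the spine neck drains concentration-proportionally (a Robin outlet)

    J_N(t) = K_N * C|_neck.

Sign convention: fluxes are reported positive when mass flows *into* the
cytosol, at both membranes.  A literature-style signed amplitude (gamma < 0
with an outward-normal Neumann condition) is absorbed into ``gamma_abs``.
Units: uM*um/ms for fluxes, ms for time constants, um/ms for K_N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import (
    BoundaryLayout,
    TAG_AXIS,
    TAG_ER,
    TAG_PM_EFFLUX,
    TAG_PM_INERT,
    TAG_PM_INFLUX,
    TAG_PM_NECK,
)

__all__ = ["FluxModel", "j_pm", "j_er", "boundary_flux_field"]


@dataclass(frozen=True)
class FluxModel:
    """Parameters of the membrane flux laws.

    Defaults are the baseline pulse used throughout: alpha=2.5 ms,
    beta=2 ms, |gamma|=1.14e-6 uM*um/ms, zeta=0.2, t_ER=20 ms, and a neck
    velocity of 1 um/s.  Under linear kinetics every gradient metric is
    invariant to the overall amplitude, so only the time constants shape
    the results.
    """

    gamma_abs: float = 1.14e-6  # uM*um/ms
    alpha: float = 2.5  # ms
    beta: float = 2.0  # ms
    zeta: float = 0.2
    t_ER: float = 20.0  # ms
    K_N: float = 1.0e-3  # um/ms (= 1 um/s)
    influx_positive: bool = True

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if math.isclose(self.alpha, self.beta, rel_tol=1e-12, abs_tol=0.0):
            raise ValueError(
                "alpha == beta collapses the biexponential pulse to zero"
            )
        if self.gamma_abs < 0:
            raise ValueError("gamma_abs stores |gamma| and must be >= 0")
        if self.zeta < 0 or self.t_ER < 0 or self.K_N < 0:
            raise ValueError("zeta, t_ER and K_N must be non-negative")

    # convenience wrappers
    def j_pm(self, t):
        return j_pm(t, self)

    def j_er(self, t):
        return j_er(t, self)

    def j_pm_rate(self, t):
        """Time derivative of J_PM (needed by the series solutions)."""
        t = np.asarray(t, dtype=float)
        s = 1.0 if self.influx_positive else -1.0
        out = s * self.gamma_abs * (
            -np.exp(-t / self.alpha) / self.alpha + np.exp(-t / self.beta) / self.beta
        )
        return np.where(t < 0, np.nan, out)

    def j_er_rate(self, t):
        t = np.asarray(t, dtype=float)
        return np.where(t < self.t_ER, 0.0, self.zeta * self.j_pm_rate(
            np.maximum(t - self.t_ER, 0.0)
        ))

    def peak_time(self) -> float:
        """Time of the J_PM maximum, (alpha*beta/(alpha-beta))*ln(alpha/beta)."""
        a, b = self.alpha, self.beta
        return a * b / (a - b) * math.log(a / b)

    def pulse_integral(self) -> float:
        """Closed-form integral of |J_PM| over [0, inf) = |gamma|*(alpha-beta)."""
        return abs(self.gamma_abs * (self.alpha - self.beta))


def j_pm(t, model: FluxModel):
    """Plasma-membrane influx density at time t (ms); errors for t < 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("flux is undefined before stimulus onset (t < 0)")
    s = 1.0 if model.influx_positive else -1.0
    out = s * model.gamma_abs * (np.exp(-t / model.alpha) - np.exp(-t / model.beta))
    return out if out.ndim else float(out)


def j_er(t, model: FluxModel):
    """ER influx density: zeta * J_PM(t - t_ER), clamped to 0 before the delay."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("flux is undefined before stimulus onset (t < 0)")
    shifted = np.maximum(t - model.t_ER, 0.0)
    out = np.where(t < model.t_ER, 0.0, model.zeta * j_pm(shifted, model))
    return out if out.ndim else float(out)


def boundary_flux_field(
    t: float,
    point_tag: str,
    layout: BoundaryLayout,
    model: FluxModel,
    C_value: float = 0.0,
) -> float:
    """Flux density (positive into the cytosol) at a tagged boundary point.

    The Robin neck term needs the local concentration ``C_value``; the
    prescribed efflux cap of the anti-periodic layout mirrors -J_PM.
    """
    if point_tag == TAG_PM_INFLUX:
        return float(j_pm(t, model))
    if point_tag == TAG_ER:
        return float(j_er(t, model))
    if point_tag == TAG_PM_NECK:
        return -model.K_N * C_value
    if point_tag == TAG_PM_EFFLUX:
        if layout.influx != "antiperiodic":
            raise ValueError("PM_efflux tag only meaningful for antiperiodic layout")
        return -float(j_pm(t, model))
    if point_tag in (TAG_PM_INERT, TAG_AXIS):
        return 0.0
    raise ValueError(f"unknown boundary tag {point_tag!r}")
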