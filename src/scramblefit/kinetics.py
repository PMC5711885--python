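"""Dithionite fluorescence-quench trace kinetics.

Fluorescence traces (normalized to 1 at the moment of dithionite addition)
are fit to an exponential decay toward a plateau with a shallow linear
drift:

    F(t) = (1 - Plateau) * exp(-K * t) + Plateau - S * t

The plateau is the protected fluorescence fraction and yields the
end-point percentage reduction 100*(1 - Plateau) used by the occupancy
analysis; the half-life 0.69/K reports the dithionite reduction rate,
which is the same with or without scramblase (the chemistry, not
scrambling, is rate limiting); S absorbs slow drift such as photobleaching
or residual dithionite permeation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Model

__all__ = [
    "DithioniteTrace",
    "TraceFit",
    "trace_model",
    "fit_trace",
    "endpoint_reduction",
    "HALF_LIFE_CONSTANT",
]

# The conventional rounded constant (not ln 2) so half-lives match the
# assay literature digit for digit.
HALF_LIFE_CONSTANT = 0.69


@dataclass(frozen=True)
class DithioniteTrace:
    """Time series of normalized fluorescence, t=0 at dithionite addition."""

    times: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.ndim != 1 or t.shape != f.shape:
            raise ValueError("times and fluorescence must be 1-D and equal length")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing with >=2 samples")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", f)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class TraceFit:
    """Fit parameters for one quench trace."""

    plateau: float
    k: float
    s_slope: float
    plateau_se: float
    k_se: float
    s_slope_se: float

    @property
    def half_life(self) -> float:
        return HALF_LIFE_CONSTANT / self.k

    @property
    def half_life_se(self) -> float:
        return HALF_LIFE_CONSTANT * self.k_se / self.k**2


def trace_model(t, plateau: float, k: float, s_slope: float):
    """F(t) = (1 - Plateau)*exp(-K*t) + Plateau - S*t; F(0) = 1."""
    t = np.asarray(t, dtype=float)
    out = (1.0 - plateau) * np.exp(-k * t) + plateau - s_slope * t
    return out if out.ndim else float(out)


def fit_trace(trace: DithioniteTrace) -> TraceFit:
    """Least-squares fit of plateau, K and S to a quench trace.

    Deterministic initialization: plateau from the mean of the last decile
    of samples, K from a log-linear fit of the early decaying points, S
    from zero.  A fit with K less certain than its own SE triggers a
    quality warning rather than an error.
    """
    t, f = trace.times, trace.fluorescence
    n = t.size
    if n < 10:
        raise ValueError("trace too short to fit (need >=10 samples)")

    plateau0 = float(np.clip(np.mean(f[-max(n // 10, 2) :]), 0.0, 0.99))
    decaying = f - plateau0
    early = (decaying > 0.05 * (1 - plateau0)) & (t > 0)
    if early.sum() >= 2:
        slope = np.polyfit(t[early], np.log(decaying[early]), 1)[0]
        k0 = float(np.clip(-slope, 1e-4, 10.0))
    else:
        k0 = 0.03
    # unbounded Levenberg-Marquardt: bound transforms degrade convergence
    # and SE estimation here; the deterministic start keeps K positive
    model = Model(trace_model, independent_vars=["t"])
    params = model.make_params(plateau=plateau0, k=k0, s_slope=0.0)
    result = model.fit(f, params, t=t)
    if not result.success:
        raise RuntimeError(f"trace fit failed to converge: {result.message}")

    def err(name: str) -> float:
        se = result.params[name].stderr
        return float(se) if se is not None else np.nan

    fit = TraceFit(
        plateau=float(result.params["plateau"].value),
        k=float(result.params["k"].value),
        s_slope=float(result.params["s_slope"].value),
        plateau_se=err("plateau"),
        k_se=err("k"),
        s_slope_se=err("s_slope"),
    )
    if np.isfinite(fit.k_se) and fit.k_se > fit.k:
        warnings.warn(
            f"poorly determined rate: K={fit.k:.3g} with SE {fit.k_se:.3g}",
            stacklevel=2,
        )
    return fit


def endpoint_reduction(fit: TraceFit) -> float:
    """End-point percentage fluorescence reduction, 100*(1 - plateau).

    This is the F fed to the occupancy transformation; the fitted plateau,
    not the last raw sample, defines the end point.
    """
    return 100.0 * (1.0 - fit.plateau)
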