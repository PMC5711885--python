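"""Poisson vesicle-occupancy analysis of scramblase reconstitution assays.

Proteoliposomes reconstituted at a protein/phospholipid ratio (PPR, mg
protein per mmol lipid, dimensionally g/mol) acquire scramblase activity
when they carry at least one functional scramblase.  The number of
scramblases per vesicle is Poisson distributed with a mean proportional to
the vesicle's membrane area, so for a vesicle of radius ``r`` (nm) the
expected occupancy is ``alpha * x * r**2 / 2`` where ``x`` is the
refractory-corrected ratio PPR* and ``alpha = 16 / (M * epsilon**2)``
encodes the molar mass ``M`` of the functional unit and the phospholipid
cross-sectional radius ``epsilon``.

Averaging the Poisson zero-class over a Gaussian vesicle-size distribution
(mean radius 88 nm, SD 28 nm) gives the closed form

    p(>=1) = 1 - (1 + alpha*x*sigma**2)**-0.5
                 * exp(-alpha*x*rbar**2/2 / (1 + alpha*x*sigma**2))

whose coefficients evaluate to exactly 784 nm^2 (sigma**2) and 3872 nm^2
(rbar**2/2) for the default population.  Fitting measured p(>=1) versus
PPR* yields alpha, hence the molar mass and oligomeric order of the
scramblase as it functions in the membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lmfit import Model
from scipy import stats

__all__ = [
    "VesiclePopulation",
    "AssayPoint",
    "OligomerAssignment",
    "OccupancyFit",
    "normalize_reduction",
    "ppr_star",
    "mean_occupancy",
    "predict_p_at_least_one",
    "fit_alpha",
    "alpha_to_mass",
    "mass_to_alpha",
    "oligomer_order",
]

#: Molar mass of an opsin monomer, g/mol.
OPSIN_MONOMER_MASS = 41_700.0


class ConfigurationError(ValueError):
    """Inconsistent population parameters (e.g. f_max <= f_o)."""


class DegenerateDataError(ValueError):
    """Assay data carry no occupancy signal (e.g. all p equal zero)."""


@dataclass(frozen=True)
class VesiclePopulation:
    """Ensemble model of the reconstituted vesicle population.

    Parameters
    ----------
    mean_radius, sd_radius : float
        Gaussian vesicle-radius distribution, nm.
    refractory_fraction : float
        Fraction of vesicles refractory to protein reconstitution; the
        measured PPR is rescaled to PPR* = PPR / (1 - refractory_fraction).
    lipid_radius_epsilon : float
        Cross-sectional radius of a phospholipid, nm.
    f_o : float
        End-point percentage fluorescence reduction of protein-free
        liposomes (outer-leaflet pool only), percent.
    f_max : float
        Maximum percentage reduction at saturating protein load, percent.
    """

    mean_radius: float = 88.0
    sd_radius: float = 28.0
    refractory_fraction: float = 0.35
    lipid_radius_epsilon: float = 0.472
    f_o: float = 45.0
    f_max: float = 82.5

    def __post_init__(self) -> None:
        if self.mean_radius <= 0:
            raise ConfigurationError("mean_radius must be positive")
        if self.sd_radius < 0:
            raise ConfigurationError("sd_radius must be nonnegative")
        if not 0.0 <= self.refractory_fraction < 1.0:
            raise ConfigurationError("refractory_fraction must lie in [0, 1)")
        if self.lipid_radius_epsilon <= 0:
            raise ConfigurationError("lipid_radius_epsilon must be positive")
        if not 0.0 <= self.f_o < self.f_max <= 100.0:
            raise ConfigurationError("require 0 <= f_o < f_max <= 100")

    @property
    def sigma_sq(self) -> float:
        """sigma**2, nm^2 — 784 for the default population."""
        return self.sd_radius**2

    @property
    def half_mean_radius_sq(self) -> float:
        """rbar**2 / 2, nm^2 — 3872 for the default population."""
        return self.mean_radius**2 / 2.0


@dataclass(frozen=True)
class AssayPoint:
    """One end-point measurement of the dithionite scramblase assay."""

    ppr: float
    ppr_star: float
    f_end: float | None
    p_active: float

    def __post_init__(self) -> None:
        if self.ppr < 0:
            raise ValueError("ppr must be nonnegative")
        if not 0.0 <= self.p_active <= 1.0:
            raise ValueError("p_active must lie in [0, 1]")

    @classmethod
    def from_measurement(
        cls, ppr: float, f_end: float, population: VesiclePopulation
    ) -> "AssayPoint":
        return cls(
            ppr=ppr,
            ppr_star=ppr_star(ppr, population),
            f_end=f_end,
            p_active=normalize_reduction(f_end, population),
        )


def normalize_reduction(f_end: float, population: VesiclePopulation) -> float:
    """Map an end-point percentage reduction F onto p(>=1 scramblase).

    p = (F - F_o) / (F_max - F_o), clamped to [0, 1].  Values below the
    protein-free baseline F_o (measurement noise) clamp to 0 with a warning.
    """
    span = population.f_max - population.f_o
    if span <= 0:
        raise ConfigurationError("f_max must exceed f_o")
    p = (f_end - population.f_o) / span
    if p < 0:
        warnings.warn(
            f"f_end={f_end} below baseline f_o={population.f_o}; clamping p to 0",
            stacklevel=2,
        )
    return float(np.clip(p, 0.0, 1.0))


def ppr_star(ppr: float, population: VesiclePopulation) -> float:
    """Correct the measured PPR for the refractory vesicle fraction."""
    if ppr < 0:
        raise ValueError("ppr must be nonnegative")
    active = 1.0 - population.refractory_fraction
    if active <= 0:
        raise ConfigurationError("refractory_fraction must be < 1")
    return ppr / active


def mean_occupancy(radius, alpha: float, x: float):
    """Expected scramblase count for a vesicle of the given radius (nm).

    mu(r) = alpha * x * r**2 / 2, equivalently (8 r^2 / eps^2) * (x / M):
    the number of lipids in the vesicle bilayer times the protein-to-lipid
    molar ratio.
    """
    radius = np.asarray(radius, dtype=float)
    if alpha < 0 or x < 0 or np.any(radius < 0):
        raise ValueError("mean_occupancy arguments must be nonnegative")
    return alpha * x * radius**2 / 2.0


def predict_p_at_least_one(
    x, alpha: float, population: VesiclePopulation | None = None
):
    """Closed-form p(>=1 scramblase) at refractory-corrected ratio x.

    Expectation of ``1 - exp(-mu(r))`` over r ~ Normal(rbar, sigma) taken
    over the whole real line:

        p = 1 - (1 + a*sigma^2)^(-1/2) * exp(-a*rbar^2/2 / (1 + a*sigma^2))

    with a = alpha*x.  Monotone nondecreasing in both alpha and x; p(0)=0.
    """
    if population is None:
        population = VesiclePopulation()
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    ax = alpha * x
    denom = 1.0 + ax * population.sigma_sq
    p = 1.0 - denom**-0.5 * np.exp(-ax * population.half_mean_radius_sq / denom)
    return p if p.ndim else float(p)


def alpha_to_mass(alpha: float, epsilon: float = 0.472) -> float:
    """Molar mass (g/mol) of the functional scramblase: M = 16/(alpha*eps^2)."""
    if alpha <= 0 or epsilon <= 0:
        raise ValueError("alpha and epsilon must be positive")
    return 16.0 / (alpha * epsilon**2)


def mass_to_alpha(molar_mass: float, epsilon: float = 0.472) -> float:
    """Inverse of :func:`alpha_to_mass`."""
    if molar_mass <= 0 or epsilon <= 0:
        raise ValueError("molar_mass and epsilon must be positive")
    return 16.0 / (molar_mass * epsilon**2)


@dataclass(frozen=True)
class OligomerAssignment:
    """Integer oligomeric order, with a ">=" flag when the mass ratio
    exceeds the assigned order by more than the margin."""

    order: int
    at_least: bool
    ratio: float

    def __str__(self) -> str:  # e.g. ">=2" for WT opsin
        return f">={self.order}" if self.at_least else str(self.order)


def oligomer_order(
    molar_mass: float,
    monomer_mass: float = OPSIN_MONOMER_MASS,
    margin: float = 0.05,
) -> OligomerAssignment:
    """Assign an oligomeric order from the fitted molar mass.

    The mass ratio is rounded to the nearest integer >= 1; when the ratio
    exceeds that integer by more than ``margin`` the assignment is flagged
    as a lower bound (">=n").
    """
    if molar_mass <= 0 or monomer_mass <= 0:
        raise ValueError("masses must be positive")
    ratio = molar_mass / monomer_mass
    order = max(1, int(round(ratio)))
    return OligomerAssignment(order=order, at_least=ratio > order + margin, ratio=ratio)


@dataclass
class OccupancyFit:
    """Result of fitting the closed-form occupancy curve to assay points."""

    alpha: float
    alpha_se: float
    molar_mass: float
    molar_mass_se: float
    oligomer: OligomerAssignment
    n_points: int
    population: VesiclePopulation = field(repr=False, default_factory=VesiclePopulation)

    def predict(self, x):
        return predict_p_at_least_one(x, self.alpha, self.population)

    def ci_band(self, x, confidence: float = 0.95):
        """Pointwise confidence band from the t-quantile on the alpha SE.

        The model is monotone in alpha, so curves at alpha -/+ t*SE bound
        the band.
        """
        dof = max(self.n_points - 1, 1)
        t = stats.t.ppf(0.5 + confidence / 2.0, dof)
        lo_alpha = max(self.alpha - t * self.alpha_se, 1e-12)
        hi_alpha = self.alpha + t * self.alpha_se
        return (
            predict_p_at_least_one(x, lo_alpha, self.population),
            predict_p_at_least_one(x, hi_alpha, self.population),
        )


def fit_alpha(
    points: Sequence[AssayPoint],
    population: VesiclePopulation | None = None,
    monomer_mass: float = OPSIN_MONOMER_MASS,
) -> OccupancyFit:
    """Nonlinear least-squares fit of alpha to p(>=1) versus PPR* data.

    Unit weights; standard error from the Jacobian at the optimum; the
    molar-mass SE is propagated to first order (SE_M/M = SE_alpha/alpha).
    """
    if population is None:
        population = VesiclePopulation()
    points = list(points)
    if len(points) < 3:
        raise ValueError("need at least 3 assay points")
    x = np.array([pt.ppr_star for pt in points], dtype=float)
    p = np.clip(np.array([pt.p_active for pt in points], dtype=float), 0.0, 1.0)
    if len(np.unique(x)) < 2:
        raise ValueError("assay points must span more than one distinct x")
    if not np.any(p > 0):
        raise DegenerateDataError("all p(>=1) values are zero; cannot fit alpha")

    model = Model(
        lambda x, alpha: predict_p_at_least_one(x, alpha, population),
        independent_vars=["x"],
    )
    # crude moment start: invert the small-ax expansion p ~ ax*(rbar^2/2+sigma^2/2)
    scale = population.half_mean_radius_sq + population.sigma_sq / 2.0
    pos = (x > 0) & (p > 0) & (p < 1)
    alpha0 = float(np.median(-np.log1p(-p[pos] * 0.999) / (x[pos] * scale))) if pos.any() else 1e-3
    result = model.fit(p, x=x, alpha=max(alpha0, 1e-8))
    if not result.success:
        raise RuntimeError(f"occupancy fit failed to converge: {result.message}")
    alpha = float(result.params["alpha"].value)
    alpha_se = float(result.params["alpha"].stderr or np.nan)
    mass = alpha_to_mass(alpha, population.lipid_radius_epsilon)
    mass_se = mass * alpha_se / alpha if np.isfinite(alpha_se) else np.nan
    return OccupancyFit(
        alpha=alpha,
        alpha_se=alpha_se,
        molar_mass=mass,
        molar_mass_se=mass_se,
        oligomer=oligomer_order(mass, monomer_mass),
        n_points=len(points),
        population=population,
    )
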