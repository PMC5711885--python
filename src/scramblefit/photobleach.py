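"""Single-molecule photobleaching step counting and oligomer inference.

Surface-immobilized, fluorophore-labeled protein complexes are imaged by
TIRF microscopy until every fluorophore bleaches.  The number of discrete
downward intensity steps in a spot's trace counts the active fluorophores
and hence the subunits.  An n-mer with per-protomer labeling efficiency q
shows Binomial(n, q) labeled subunits conditioned on being visible (>=1);
occasional coincidental co-localization of a second molecule within a
diffraction-limited spot adds an independent binomial contribution.

Steps are counted automatically by binary-segmentation change-point
detection on a piecewise-constant-plus-Gaussian-noise model instead of the
manual classification traditional in the field; traces that re-brighten or
are too noisy to segment are classed "uncountable", mirroring manual
practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom

__all__ = [
    "SpotTrace",
    "StepConfig",
    "StepDetection",
    "StepDistribution",
    "OligomerInference",
    "detect_steps",
    "estimate_unit_step",
    "count_movie_steps",
    "step_distribution",
    "expected_step_distribution",
    "infer_oligomer",
]


@dataclass(frozen=True)
class SpotTrace:
    """Background-subtracted intensity trace of one diffraction-limited spot."""

    intensity: np.ndarray
    frame_rate: float = 20.0

    def __post_init__(self) -> None:
        y = np.asarray(self.intensity, dtype=float)
        if y.ndim != 1:
            raise ValueError("intensity must be 1-D")
        object.__setattr__(self, "intensity", y)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


@dataclass(frozen=True)
class StepConfig:
    """Thresholds for automated step counting.

    min_step_sigma : steps smaller than this multiple of the noise SD are
        not split out (default 3).
    min_dwell : minimum segment length in frames (default 5).
    rebright_fraction : an upward level change larger than this fraction of
        the typical downward step marks the trace uncountable (default 0.5).
    max_residual_ratio : trace is uncountable when the residual noise SD
        exceeds step_size/this (default 3).
    max_countable : counts above this are uncountable (default 5).
    """

    min_step_sigma: float = 3.0
    min_dwell: int = 5
    rebright_fraction: float = 0.5
    max_residual_ratio: float = 3.0
    max_countable: int = 5


@dataclass(frozen=True)
class StepDetection:
    """Segmentation result for one spot trace."""

    n_steps: int
    change_points: tuple[int, ...]
    levels: tuple[float, ...]
    uncountable: bool
    reason: str = ""

    @property
    def countable(self) -> bool:
        return not self.uncountable


def _noise_sd(y: np.ndarray) -> float:
    """Robust noise SD from the MAD of first differences."""
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def _best_split(y: np.ndarray, min_dwell: int) -> tuple[int, float]:
    """Best single change point by SSE reduction; (-1, 0) if none allowed."""
    n = y.size
    if n < 2 * min_dwell:
        return -1, 0.0
    c1 = np.cumsum(y)
    c2 = np.cumsum(y**2)
    total = c2[-1] - c1[-1] ** 2 / n
    i = np.arange(min_dwell, n - min_dwell + 1)
    left = c2[i - 1] - c1[i - 1] ** 2 / i
    sum_r = c1[-1] - c1[i - 1]
    sq_r = c2[-1] - c2[i - 1]
    right = sq_r - sum_r**2 / (n - i)
    cost = left + right
    j = int(np.argmin(cost))
    return int(i[j]), float(total - cost[j])


def _segment(y: np.ndarray, min_step: float, min_dwell: int) -> list[int]:
    """Recursive binary segmentation; returns sorted change-point indices."""
    out: list[int] = []
    stack = [(0, y.size)]
    while stack:
        lo, hi = stack.pop()
        seg = y[lo:hi]
        cut, _ = _best_split(seg, min_dwell)
        if cut < 0:
            continue
        if abs(seg[:cut].mean() - seg[cut:].mean()) < min_step:
            continue
        out.append(lo + cut)
        stack.append((lo, lo + cut))
        stack.append((lo + cut, hi))
    return sorted(out)


def detect_steps(
    trace: SpotTrace,
    config: StepConfig | None = None,
    unit_step: float | None = None,
) -> StepDetection:
    """Count downward bleaching steps in a spot trace.

    The trace is segmented into piecewise-constant levels; the step count
    is the number of downward level transitions.  When ``unit_step`` (the
    single-fluorophore intensity, e.g. estimated movie-wide with
    :func:`estimate_unit_step`) is given, each downward transition is
    quantized to round(drop / unit_step) steps, so two fluorophores
    bleaching within one dwell time are still counted as two.  Scale
    invariant: the noise SD and all thresholds derived from it scale with
    the data.
    """
    if config is None:
        config = StepConfig()
    y = trace.intensity
    if y.size < max(20, 2 * config.min_dwell):
        raise ValueError("trace too short for step detection")

    sigma = _noise_sd(y)
    min_step = config.min_step_sigma * sigma if sigma > 0 else np.ptp(y) * 1e-9
    if min_step == 0:  # perfectly flat trace
        return StepDetection(0, (), (float(y[0]),), True, "no intensity change")
    cps = _segment(y, min_step, config.min_dwell)
    bounds = [0, *cps, y.size]
    levels = np.array([y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    dlev = np.diff(levels)
    down = -dlev[dlev < 0]
    if unit_step is not None and unit_step > 0:
        # quantize levels to integer fluorophore counts; a transition then
        # contributes its drop in quantized units, so near-simultaneous
        # bleaches merged by the dwell limit are still counted and blended
        # partial levels do not inflate the count
        q = np.round(levels / unit_step)
        n_down = int(np.maximum(0, -np.diff(q)).sum())
    else:
        n_down = int(down.size)

    if n_down == 0:
        return StepDetection(0, tuple(cps), tuple(levels), True, "no bleaching step")
    typical = float(np.median(down))
    up = dlev[dlev > 0]
    if up.size and float(up.max()) > config.rebright_fraction * typical:
        return StepDetection(
            n_down, tuple(cps), tuple(levels), True, "re-brightening"
        )
    fit = np.repeat(levels, np.diff(bounds))
    resid_sd = float(np.std(y - fit))
    if resid_sd > typical / config.max_residual_ratio:
        return StepDetection(
            n_down, tuple(cps), tuple(levels), True, "residual noise exceeds step size"
        )
    if n_down > config.max_countable:
        return StepDetection(n_down, tuple(cps), tuple(levels), True, "too many steps")
    return StepDetection(n_down, tuple(cps), tuple(levels), False)


def estimate_unit_step(
    traces: Sequence[SpotTrace], config: StepConfig | None = None
) -> float:
    """Movie-wide single-fluorophore step height.

    All spots in a movie share the same fluorophore, so the unit bleaching
    step is common; it is estimated as the median of the final downward
    level transition of each segmentable trace (the last fluorophore to
    bleach is almost always alone).
    """
    finals = []
    for tr in traces:
        try:
            det = detect_steps(tr, config)
        except ValueError:
            continue
        lv = np.array(det.levels)
        if lv.size >= 2:
            drops = -np.diff(lv)
            drops = drops[drops > 0]
            if drops.size:
                finals.append(drops[-1])
    if not finals:
        raise ValueError("no trace with a detectable bleaching step")
    return float(np.median(finals))


def count_movie_steps(
    traces: Sequence[SpotTrace],
    config: StepConfig | None = None,
    unit_step: float | None = None,
) -> list[int | None]:
    """Per-spot step counts for one movie (None marks uncountable spots).

    Two-pass analysis: the movie-wide unit step height is estimated first,
    then every trace is counted with height quantization.
    """
    if unit_step is None:
        unit_step = estimate_unit_step(traces, config)
    counts: list[int | None] = []
    for tr in traces:
        det = detect_steps(tr, config, unit_step=unit_step)
        counts.append(det.n_steps if det.countable else None)
    return counts


@dataclass(frozen=True)
class StepDistribution:
    """Fractions of spots bleaching in 1..k steps, averaged across movies."""

    fractions: dict[int, float]
    uncountable_fraction: float
    sem: dict[int, float]
    n_movies: int
    per_movie_counts: tuple[tuple[int, ...], ...] = field(default=(), repr=False)

    def countable_fractions(self) -> dict[int, float]:
        """Fractions renormalized over countable spots only."""
        total = sum(self.fractions.values())
        if total == 0:
            return dict(self.fractions)
        return {k: v / total for k, v in self.fractions.items()}


def step_distribution(
    movie_counts: Sequence[Sequence[int | None]], max_steps: int = 5
) -> StepDistribution:
    """Aggregate per-spot step counts (None = uncountable) across movies.

    Fractions are computed per movie over all spots (countable plus
    uncountable), then averaged; the SEM is the across-movie sample SD
    divided by sqrt(n_movies).
    """
    per_movie = []
    kept_counts = []
    for i, counts in enumerate(movie_counts):
        counts = list(counts)
        if not counts:
            warnings.warn(f"movie {i} has no spots; dropped", stacklevel=2)
            continue
        n = len(counts)
        countable = [c for c in counts if c is not None and 1 <= c <= max_steps]
        if not countable:
            warnings.warn(f"movie {i} has no countable spots; dropped", stacklevel=2)
            continue
        fr = {k: sum(c == k for c in countable) / n for k in range(1, max_steps + 1)}
        fr["unc"] = (n - len(countable)) / n
        per_movie.append(fr)
        kept_counts.append(tuple(c if c is not None else -1 for c in counts))
    if not per_movie:
        raise ValueError("no movie with countable spots")
    m = len(per_movie)
    keys = list(range(1, max_steps + 1))
    mean = {k: float(np.mean([fr[k] for fr in per_movie])) for k in keys}
    sem = {
        k: float(np.std([fr[k] for fr in per_movie], ddof=1) / np.sqrt(m)) if m > 1 else 0.0
        for k in keys
    }
    return StepDistribution(
        fractions=mean,
        uncountable_fraction=float(np.mean([fr["unc"] for fr in per_movie])),
        sem=sem,
        n_movies=m,
        per_movie_counts=tuple(kept_counts),
    )


def expected_step_distribution(
    n_mer: int, label_eff: float, coincidence_p: float = 0.0
) -> dict[int, float]:
    """Model distribution of visible step counts for an n-mer.

    Visible fluorophores per spot: Binomial(n_mer, label_eff) conditioned
    on >=1, plus — with probability ``coincidence_p`` — one coincident
    molecule contributing an independent Binomial(n_mer, label_eff).
    Returns fractions over 1..2*n_mer summing to 1.
    """
    if n_mer < 1:
        raise ValueError("n_mer must be >= 1")
    if not 0 < label_eff <= 1:
        raise ValueError("label_eff must lie in (0, 1]")
    if not 0 <= coincidence_p < 1:
        raise ValueError("coincidence_p must lie in [0, 1)")
    k = np.arange(n_mer + 1)
    pmf = binom.pmf(k, n_mer, label_eff)
    primary = pmf.copy()
    primary[0] = 0.0
    primary /= primary.sum()
    extra = (1 - coincidence_p) * np.eye(1, n_mer + 1, 0).ravel() + coincidence_p * pmf
    total = np.convolve(primary, extra)
    return {int(i): float(total[i]) for i in range(1, 2 * n_mer + 1)}


@dataclass(frozen=True)
class OligomerInference:
    """Best-matching oligomeric state and its goodness of fit."""

    n_mer: int
    distance: float
    distances: dict[int, float]
    inconclusive: bool


def infer_oligomer(
    observed: StepDistribution | Mapping[int, float],
    label_eff: float = 0.8,
    coincidence_p: float = 0.08,
    max_n: int = 4,
) -> OligomerInference:
    """Pick the n-mer whose expected step distribution best matches.

    Observed fractions (countable spots, renormalized) are compared with
    :func:`expected_step_distribution` for n in 1..max_n by squared
    distance over step categories.  Nearly tied candidates are flagged
    inconclusive.
    """
    if isinstance(observed, StepDistribution):
        obs = observed.countable_fractions()
    else:
        total = sum(observed.values())
        obs = {int(k): v / total for k, v in observed.items()}
    kmax = max(max(obs), 2 * max_n)
    obs_vec = np.array([obs.get(k, 0.0) for k in range(1, kmax + 1)])
    distances = {}
    for n in range(1, max_n + 1):
        exp = expected_step_distribution(n, label_eff, coincidence_p)
        exp_vec = np.array([exp.get(k, 0.0) for k in range(1, kmax + 1)])
        distances[n] = float(np.sum((obs_vec - exp_vec) ** 2))
    ranked = sorted(distances, key=distances.get)
    best, second = ranked[0], ranked[1]
    inconclusive = (distances[second] - distances[best]) < 1e-4
    return OligomerInference(
        n_mer=best,
        distance=distances[best],
        distances=distances,
        inconclusive=inconclusive,
    )
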