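"""Bayesian ideal observer for heading estimation.

The observer receives a noisy measurement M of the true heading X and
combines a Gaussian likelihood with a prior that is the product of two
components: a Gaussian ego-centric prior centered on the straight-ahead
direction, and a prior reflecting the previous heading distribution.
On a discretized heading grid the posterior is

    p(X_j | M)  ∝  N(M; X_j, σ_m²) · N(X_j; θ_ego, σ_ego²) · p_dis(X_j)

normalized to sum to one over the grid. When the distribution prior is
uniform it is a constant and cancels from the normalized posterior, so
predictions reduce to the ego-prior-only observer — the analytic
identity this module makes executable. A nonuniform distribution prior
does not cancel and pulls estimates toward its dense region, i.e. the
model predicts a central-tendency-like attraction.

All angles are degrees; the likelihood is Gaussian in degrees, which is
adequate in the small-angle regime (|heading| ≤ 33°) this model serves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np

from .design import HeadingDistribution

__all__ = [
    "PriorSpec",
    "PosteriorGrid",
    "uniform_prior_constant",
    "posterior",
    "predict_ph",
    "predicted_slope",
]

GRID_MIN, GRID_MAX = -90.0, 90.0  # >= 5 SD beyond the extreme ±33° headings
DEFAULT_GRID_STEP = 0.1


@dataclass(frozen=True)
class PriorSpec:
    """Prior specification: ego-centric component × distribution component.

    Parameters
    ----------
    ego_center
        θ_ego, the ego-centric (straight-ahead) direction in degrees.
    ego_sigma
        Width (SD, degrees) of the Gaussian ego-centric prior.
    dist_prior
        ``"uniform"`` for a flat distribution prior, or a
        :class:`~headingbias.design.HeadingDistribution` whose counts
        define a nonuniform prior density.
    dist_smooth_sigma
        Gaussian kernel width (degrees) used to turn discrete trial
        counts into a density; 0 places mass on the nearest grid points.
    """

    ego_center: float = 0.0
    ego_sigma: float = 20.0
    dist_prior: Union[HeadingDistribution, str] = "uniform"
    dist_smooth_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.ego_sigma <= 0:
            raise ValueError("ego_sigma must be > 0")
        if self.dist_smooth_sigma < 0:
            raise ValueError("dist_smooth_sigma must be >= 0")
        if isinstance(self.dist_prior, str) and self.dist_prior != "uniform":
            raise ValueError('dist_prior must be a HeadingDistribution or "uniform"')


@dataclass(frozen=True)
class PosteriorGrid:
    """Discretized posterior p(X | M) over candidate headings."""

    grid: np.ndarray
    mass: np.ndarray
    measurement: float

    def __post_init__(self) -> None:
        if np.any(self.mass < 0):
            raise ValueError("posterior mass must be nonnegative")
        if abs(float(self.mass.sum()) - 1.0) > 1e-9:
            raise ValueError("posterior mass must sum to 1")

    @property
    def mean(self) -> float:
        return float(np.sum(self.grid * self.mass))

    @property
    def map(self) -> float:
        return float(self.grid[int(np.argmax(self.mass))])


def uniform_prior_constant(dist: HeadingDistribution) -> float:
    """Flat prior density 1/(range width) for a uniform design, per degree.

    For the wide ±33° design the heading range spans 66°, giving 1/66.
    """
    return 1.0 / (max(dist.headings) - min(dist.headings))


def _dist_log_density(
    grid: np.ndarray, prior: PriorSpec, grid_step: float
) -> np.ndarray:
    """Log of the distribution-prior density on the grid (unnormalized)."""
    if isinstance(prior.dist_prior, str):  # "uniform": constant, cancels
        return np.zeros_like(grid)
    dist = prior.dist_prior
    h = np.asarray(dist.headings, dtype=float)
    c = np.asarray(dist.counts, dtype=float)
    if prior.dist_smooth_sigma > 0:
        s = prior.dist_smooth_sigma
        dens = np.sum(
            c[None, :] * np.exp(-0.5 * ((grid[:, None] - h[None, :]) / s) ** 2),
            axis=1,
        )
    else:
        dens = np.zeros_like(grid)
        idx = np.clip(
            np.round((h - grid[0]) / grid_step).astype(int), 0, len(grid) - 1
        )
        np.add.at(dens, idx, c)
    with np.errstate(divide="ignore"):
        return np.log(dens)


def posterior(
    measurement: float,
    prior: PriorSpec,
    meas_sigma: float,
    grid_step: float = DEFAULT_GRID_STEP,
) -> PosteriorGrid:
    """Posterior over headings for one noisy measurement.

    Computed in log space (likelihood × ego prior × distribution prior)
    and normalized over a fixed grid spanning [-90°, 90°].
    """
    if meas_sigma <= 0:
        raise ValueError("meas_sigma must be > 0")
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    n = int(round((GRID_MAX - GRID_MIN) / grid_step))
    grid = GRID_MIN + grid_step * np.arange(n + 1)
    with np.errstate(over="ignore"):
        logp = (
            -0.5 * ((measurement - grid) / meas_sigma) ** 2
            - 0.5 * ((grid - prior.ego_center) / prior.ego_sigma) ** 2
            + _dist_log_density(grid, prior, grid_step)
        )
    finite = np.isfinite(logp)
    if not np.any(finite):
        raise ValueError(
            "posterior mass is zero everywhere: likelihood and priors have "
            "disjoint support on the grid"
        )
    mass = np.zeros_like(grid)
    mass[finite] = np.exp(logp[finite] - logp[finite].max())
    total = mass.sum()
    if total == 0:
        raise ValueError("posterior mass underflowed to zero everywhere")
    return PosteriorGrid(grid=grid, mass=mass / total, measurement=float(measurement))


def predict_ph(
    ah: float,
    prior: PriorSpec,
    meas_sigma: float,
    estimator: Literal["posterior_mean", "map"] = "posterior_mean",
    n_mc: int = 200,
    seed: int = 0,
    grid_step: float = DEFAULT_GRID_STEP,
) -> float:
    """Expected reported heading for a true heading ``ah``.

    Averages the chosen posterior point estimate over ``n_mc`` simulated
    measurements M ~ Normal(ah, meas_sigma²).
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if estimator not in ("posterior_mean", "map"):
        raise ValueError('estimator must be "posterior_mean" or "map"')
    rng = np.random.default_rng(seed)
    measurements = rng.normal(ah, meas_sigma, size=n_mc)
    estimates = np.empty(n_mc)
    for i, m in enumerate(measurements):
        post = posterior(m, prior, meas_sigma, grid_step=grid_step)
        estimates[i] = post.mean if estimator == "posterior_mean" else post.map
    return float(estimates.mean())


def predicted_slope(
    prior: PriorSpec,
    meas_sigma: float,
    heading_set: "list[float] | tuple[float, ...] | np.ndarray",
    estimator: Literal["posterior_mean", "map"] = "posterior_mean",
    n_mc: int = 200,
    seed: int = 0,
    grid_step: float = DEFAULT_GRID_STEP,
) -> float:
    """OLS slope of predicted perceived heading against actual heading.

    The model analogue of the empirical center-bias slope: < 1 means the
    ego prior compresses predictions toward its center.
    """
    ahs = np.asarray(heading_set, dtype=float)
    if ahs.size < 2 or np.allclose(ahs, ahs[0]):
        raise ValueError("heading_set must contain >= 2 distinct values")
    preds = np.array(
        [
            predict_ph(
                ah,
                prior,
                meas_sigma,
                estimator=estimator,
                n_mc=n_mc,
                seed=seed + k,
                grid_step=grid_step,
            )
            for k, ah in enumerate(ahs)
        ]
    )
    slope, _ = np.polyfit(ahs, preds, 1)
    return float(slope)
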