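"""Scalar figures of merit for comparing predicted and experimental restraints.

Distance distributions are compared by the earth mover's distance (EMD,
1-D Wasserstein-1), which is a proper metric on probability distributions,
or by overlap deficiency (one minus the overlap integral).  PRE tables are
compared by a reduced chi-square.  A Gaussian overlay utility converts
non-parametric distance distributions into (mean, width) restraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DistanceDistribution",
    "GaussianRestraint",
    "emd",
    "overlap_deficiency",
    "chi2_pre",
    "fit_gaussian",
]


@dataclass
class DistanceDistribution:
    """Normalized probability density P(r) on a closed uniform grid in Å.

    The density integrates to one (trapezoid rule).  An optional confidence
    band (lower/upper densities) is carried for reporting; fits always use
    the point-estimate density.
    """

    grid: np.ndarray
    density: np.ndarray
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("grid must be a 1-D array with at least two points")
        if self.grid.shape != self.density.shape:
            raise ValueError("grid and density shapes differ")
        steps = np.diff(self.grid)
        if np.any(steps <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("grid must be uniform")
        if np.any(self.density < -1e-12):
            raise ValueError("density must be non-negative")
        self.density = np.clip(self.density, 0.0, None)
        area = np.trapezoid(self.density, self.grid)
        if area <= 0:
            raise ValueError("degenerate distribution: density integrates to zero")
        if not np.isclose(area, 1.0, atol=1e-9):
            self.density = self.density / area
            if self.ci_lower is not None:
                self.ci_lower = np.asarray(self.ci_lower, dtype=float) / area
            if self.ci_upper is not None:
                self.ci_upper = np.asarray(self.ci_upper, dtype=float) / area

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def masses(self) -> np.ndarray:
        """Per-bin probability mass (density * step, normalized to sum 1)."""
        m = self.density * self.step
        return m / m.sum()

    def mean(self) -> float:
        return float(np.sum(self.masses() * self.grid))

    def std(self) -> float:
        m = self.masses()
        mu = np.sum(m * self.grid)
        return float(np.sqrt(np.sum(m * (self.grid - mu) ** 2)))

    def regrid(self, grid: np.ndarray) -> "DistanceDistribution":
        """Linear interpolation onto a new uniform grid, renormalized."""
        grid = np.asarray(grid, dtype=float)
        dens = np.interp(grid, self.grid, self.density, left=0.0, right=0.0)
        inside = (self.grid >= grid[0]) & (self.grid <= grid[-1])
        kept = np.trapezoid(np.where(inside, self.density, 0.0), self.grid)
        if kept < 0.99:
            raise ValueError(
                "regrid would discard more than 1% of the probability mass; "
                "use a wider grid"
            )
        return DistanceDistribution(grid, dens)


@dataclass
class GaussianRestraint:
    """Gaussian overlay of a distance distribution: A·exp(-(r-⟨r⟩)²/2σ²)."""

    mean: float
    sigma: float
    amplitude: float
    rss: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _common_grid(p: DistanceDistribution, q: DistanceDistribution):
    if p.grid.shape == q.grid.shape and np.allclose(p.grid, q.grid, atol=1e-9):
        return p, q
    return p, q.regrid(p.grid)


def emd(p: DistanceDistribution, q: DistanceDistribution) -> float:
    """Earth mover's distance (1-D Wasserstein-1) in Å.

    Computed from the cumulative distributions on the shared grid:
    EMD = Σ_g |CDF_P(g) - CDF_Q(g)| · Δr.  Zero iff the distributions are
    identical on the grid; symmetric; obeys the triangle inequality.
    """
    p, q = _common_grid(p, q)
    diff = np.cumsum(p.masses() - q.masses())
    return float(np.sum(np.abs(diff)) * p.step)


def overlap_deficiency(p: DistanceDistribution, q: DistanceDistribution) -> float:
    """1 - Σ min(P, Q) · Δr, in [0, 1]; 0 for identical distributions."""
    p, q = _common_grid(p, q)
    o = float(np.sum(np.minimum(p.masses(), q.masses())))
    return float(np.clip(1.0 - o, 0.0, 1.0))


def chi2_pre(observed, predicted, cap: float = 170.0) -> float:
    """Mean chi-square between observed and predicted PRE rates.

    ``observed`` is a PRETable (residue-matched with ``predicted``, an array
    of back-calculated Γ₂ values in s⁻¹, or a PRETable).  Residues flagged
    ``unreliable`` are excluded.  A residue whose paramagnetic peak vanished
    is only known to relax faster than the detection cap: it contributes zero
    when the prediction reaches the cap, otherwise ((cap - pred)/σ)².
    """
    status = np.asarray(observed.status)
    obs = np.asarray(observed.gamma2, dtype=float)
    err = np.asarray(observed.gamma2_err, dtype=float)
    if hasattr(predicted, "gamma2"):
        if not np.array_equal(
            np.asarray(observed.residues), np.asarray(predicted.residues)
        ):
            raise ValueError("observed and predicted PRE tables list different residues")
        pred = np.asarray(predicted.gamma2, dtype=float)
    else:
        pred = np.asarray(predicted, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("prediction length does not match observation length")
    usable = status != "unreliable"
    if not np.any(usable):
        raise ValueError("no usable residues for chi-square")
    if np.any(err[usable] <= 0):
        raise ValueError("observed errors must be positive")
    resid = np.where(
        status == "vanished",
        np.maximum(cap - pred, 0.0),
        obs - pred,
    )
    return float(np.mean((resid[usable] / err[usable]) ** 2))


def _gauss(r, a, mu, sigma):
    return a * np.exp(-((r - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(p: DistanceDistribution, max_restarts: int = 5) -> GaussianRestraint:
    """Least-squares Gaussian overlay of a non-parametric distribution.

    Initialized from the distribution's mean and standard deviation; bounded
    restarts perturb the initial guess deterministically if the fit fails to
    converge.
    """
    r, y = p.grid, p.density
    mu0, s0 = p.mean(), max(p.std(), p.step)
    a0 = float(y.max())
    last_err: Exception | None = None
    for k in range(max_restarts):
        scale = 1.0 + 0.5 * k
        p0 = (a0, mu0, s0 * scale)
        try:
            popt, _ = curve_fit(
                _gauss,
                r,
                y,
                p0=p0,
                bounds=([0.0, r[0] - 10.0, 1e-3], [np.inf, r[-1] + 10.0, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover - rare
            last_err = exc
            continue
        a, mu, sigma = popt
        rss = float(np.sum((y - _gauss(r, *popt)) ** 2))
        return GaussianRestraint(mean=float(mu), sigma=float(abs(sigma)), amplitude=float(a), rss=rss)
    raise RuntimeError(
        f"Gaussian fit failed after {max_restarts} restarts "
        f"(mean0={mu0:.2f}, sigma0={s0:.2f}): {last_err}"
    )
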