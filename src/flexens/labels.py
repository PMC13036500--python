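"""Pluggable spin-label models and forward prediction of restraints.

A spin label attached to a residue is represented by a weighted point cloud
of possible unpaired-electron positions.  The default ``gauss_cloud`` model
draws 64 points from an isotropic Gaussian (σ 2.5 Å) centred 7 Å from the
attachment residue's Cα along the local outward direction (Cα minus the
centroid of the residue's domain).  Alternative models plug in through the
same contract; a degenerate ``point`` model places a single point at the
offset position.

Forward predictions:

* pair distance distributions — all cross-pair point distances between two
  clouds, weighted by the product of point weights, smoothed by a Gaussian
  kernel onto a uniform grid, and mixed over conformers with the ensemble
  weights;
* PRE rates — per conformer and target residue the cloud is collapsed to an
  effective distance r_eff = (Σ_k p_k r_k^-6)^(-1/6), converted to Γ₂ and
  clipped to the detection cap; the ensemble value is the weighted mean of
  the clipped conformer rates (an exact linear combination).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from flexens.io_formats import ConformerEnsemble
from flexens.metrics import DistanceDistribution
from flexens.nmr import GAMMA2_CAP_DEFAULT, PRE_K_CM6_S2, distance_to_gamma2

__all__ = [
    "LabelSite",
    "SpinCloudCentroid",
    "LABEL_MODELS",
    "attach_label",
    "build_site",
    "cloud_centroid",
    "verify_placement",
    "predict_distance_distribution",
    "per_conformer_distributions",
    "predict_pre",
    "per_conformer_pre",
    "DEFAULT_GRID",
    "DEFAULT_KERNEL_SIGMA",
]

#: Default distance grid: DEER-relevant range with margin, step 0.5 Å.
DEFAULT_GRID = np.arange(10.0, 100.0 + 0.25, 0.5)
#: Default Gaussian smoothing kernel width in Å.
DEFAULT_KERNEL_SIGMA = 1.0


@dataclass
class LabelSite:
    """Spin-label site with one point cloud per conformer.

    ``points`` has shape (C, P, 3) and ``point_weights`` shape (C, P); each
    conformer's point weights sum to one.
    """

    site_id: str
    residue: int
    model: str
    points: np.ndarray
    point_weights: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.point_weights = np.asarray(self.point_weights, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise ValueError("points must have shape (C, P, 3)")
        if self.point_weights.shape != self.points.shape[:2]:
            raise ValueError("point_weights must have shape (C, P)")
        if self.points.shape[1] < 1:
            raise ValueError("cloud must be non-empty")
        sums = self.point_weights.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("point weights must sum to 1 per conformer")

    @property
    def n_conformers(self) -> int:
        return int(self.points.shape[0])


@dataclass
class SpinCloudCentroid:
    """Point-weighted cloud centre with mean distances to anchor Cα atoms."""

    site_id: str
    centroid: np.ndarray
    anchor_distances: np.ndarray


def _outward_direction(ca: np.ndarray, domain_centroid: np.ndarray) -> np.ndarray:
    v = ca - domain_centroid
    n = np.linalg.norm(v)
    if n < 1e-9:
        # degenerate: residue sits on the domain centroid
        return np.array([1.0, 0.0, 0.0])
    return v / n


def _gauss_cloud(anchor, direction, rng, n_points=64, sigma=2.5, offset=7.0):
    centre = anchor + offset * direction
    pts = centre + rng.normal(0.0, sigma, size=(n_points, 3))
    w = np.full(n_points, 1.0 / n_points)
    return pts, w

def _point(anchor, direction, rng, offset=7.0):
    return (anchor + offset * direction)[None, :], np.array([1.0])


LABEL_MODELS = {"gauss_cloud": _gauss_cloud, "point": _point}


def attach_label(
    conformer,
    residue: int,
    model: str = "gauss_cloud",
    seed: int = 0,
    domain_residues=None,
    **model_kwargs,
):
    """Attach a label cloud to one conformer; returns (points, weights).

    ``domain_residues`` names the residues of the rigid domain hosting the
    site; their Cα centroid defines the outward direction.  Defaults to all
    residues of the conformer.  Deterministic for a fixed seed.
    """
    if model not in LABEL_MODELS:
        raise ValueError(
            f"unknown label model {model!r}; registered: {sorted(LABEL_MODELS)}"
        )
    i_ca = conformer.atom_index(residue, "CA")
    if i_ca is None:
        raise ValueError(f"residue {residue} has no CA atom")
    ca = conformer.coords[i_ca]
    ca_mask = conformer.names == "CA"
    if domain_residues is not None:
        ca_mask = ca_mask & np.isin(conformer.residue_ids, np.asarray(domain_residues))
    centroid = conformer.coords[ca_mask].mean(axis=0)
    direction = _outward_direction(ca, centroid)
    rng = np.random.default_rng(seed)
    return LABEL_MODELS[model](ca, direction, rng, **model_kwargs)


def build_site(
    ensemble: ConformerEnsemble,
    site_id: str,
    residue: int,
    model: str = "gauss_cloud",
    seed: int = 0,
    domain_residues=None,
    **model_kwargs,
) -> LabelSite:
    """Attach a label at the same residue on every conformer of an ensemble.

    Per-conformer clouds are seeded from (seed, conformer identity), with
    identity taken from the provenance tag: the whole site is reproducible,
    clouds differ between conformers, and a sub-ensemble keeps exactly the
    clouds its conformers had in the parent pool.
    """
    points, weights = [], []
    for c in range(ensemble.n_conformers):
        ident = zlib.crc32(str(ensemble.provenance[c]).encode())
        pts, w = attach_label(
            ensemble.conformer(c), residue, model,
            seed=int(np.random.SeedSequence([seed, ident]).generate_state(1)[0] % (2**31)),
            domain_residues=domain_residues, **model_kwargs,
        )
        points.append(pts)
        weights.append(w)
    return LabelSite(site_id, residue, model, np.stack(points), np.stack(weights))


def cloud_centroid(
    points: np.ndarray,
    point_weights: np.ndarray,
    anchor_coords: np.ndarray,
    site_id: str = "",
) -> SpinCloudCentroid:
    """Weighted cloud centre and its distances to a set of anchor Cα atoms."""
    anchor_coords = np.atleast_2d(np.asarray(anchor_coords, dtype=float))
    if anchor_coords.shape[0] < 1:
        raise ValueError("at least one anchor is required")
    w = np.asarray(point_weights, dtype=float)
    centroid = (w[:, None] * np.asarray(points, dtype=float)).sum(axis=0)
    dists = np.linalg.norm(anchor_coords - centroid, axis=1)
    return SpinCloudCentroid(site_id, centroid, dists)


def verify_placement(
    centroid: np.ndarray,
    anchor_coords: np.ndarray,
    target_distances: np.ndarray,
    tol: float = 0.2,
) -> float:
    """Assert that a placed centre reproduces anchor distances within ±tol Å.

    Returns the maximum absolute deviation; raises if it exceeds ``tol``.
    """
    d = np.linalg.norm(np.atleast_2d(anchor_coords) - np.asarray(centroid), axis=1)
    dev = float(np.max(np.abs(d - np.asarray(target_distances))))
    if dev > tol:
        raise ValueError(
            f"centre placement deviates {dev:.3f} Å from anchor distances "
            f"(tolerance {tol} Å)"
        )
    return dev


def _pair_distances(site_a: LabelSite, site_b: LabelSite, c: int):
    d = cdist(site_a.points[c], site_b.points[c]).ravel()
    w = np.outer(site_a.point_weights[c], site_b.point_weights[c]).ravel()
    return d, w


def per_conformer_distributions(
    site_a: LabelSite,
    site_b: LabelSite,
    grid: np.ndarray = DEFAULT_GRID,
    kernel_sigma: float = DEFAULT_KERNEL_SIGMA,
    coverage_tol: float = 0.01,
) -> np.ndarray:
    """(C, G) per-conformer densities of the pair distance on ``grid``.

    Each conformer's density is renormalized to unit trapezoid integral;
    an error is raised when more than ``coverage_tol`` of the *total* cloud
    mass (averaged over conformers) falls outside the grid.
    """
    if site_a.n_conformers != site_b.n_conformers:
        raise ValueError("sites carry clouds for different conformer counts")
    grid = np.asarray(grid, dtype=float)
    c_n = site_a.n_conformers
    dens = np.empty((c_n, grid.size))
    captured = np.empty(c_n)
    norm = 1.0 / (kernel_sigma * np.sqrt(2.0 * np.pi))
    for c in range(c_n):
        d, w = _pair_distances(site_a, site_b, c)
        z = (grid[:, None] - d[None, :]) / kernel_sigma
        rho = norm * (np.exp(-0.5 * z**2) @ w)
        captured[c] = np.trapezoid(rho, grid)
        dens[c] = rho / max(captured[c], 1e-300)
    if np.mean(captured) < 1.0 - coverage_tol:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] covers only "
            f"{100 * np.mean(captured):.1f}% of the predicted distance mass; "
            "widen the grid"
        )
    return dens


def predict_distance_distribution(
    ensemble: ConformerEnsemble,
    site_a: LabelSite,
    site_b: LabelSite,
    grid: np.ndarray = DEFAULT_GRID,
    kernel_sigma: float = DEFAULT_KERNEL_SIGMA,
) -> DistanceDistribution:
    """Ensemble distance distribution Σ_c w_c P_c between two label sites."""
    dens = per_conformer_distributions(site_a, site_b, grid, kernel_sigma)
    mix = ensemble.weights @ dens
    return DistanceDistribution(np.asarray(grid, dtype=float), mix)


def _target_positions(conformer, targets) -> np.ndarray:
    pos = []
    for rid in targets:
        idx = conformer.atom_index(rid, "H")
        if idx is None:
            idx = conformer.atom_index(rid, "CA")
        if idx is None:
            raise ValueError(f"residue {rid}: neither H nor CA atom present")
        pos.append(conformer.coords[idx])
    return np.array(pos, dtype=float)


def per_conformer_pre(
    ensemble: ConformerEnsemble,
    site: LabelSite,
    targets,
    tau_c: float,
    omega_h: float,
    cap: float | None = GAMMA2_CAP_DEFAULT,
    k: float = PRE_K_CM6_S2,
) -> np.ndarray:
    """(C, T) per-conformer Γ₂ predictions for the target residues.

    Target protons are the amide H if present, otherwise the Cα is used as a
    proxy.  The label cloud enters through the r^-6-weighted effective
    distance r_eff = (Σ_k p_k r_k^-6)^(-1/6).  Back-computed values are
    clipped to the detection cap per conformer (pass ``cap=None`` for raw
    rates), which keeps the ensemble prediction an exact linear combination
    of the conformer predictions.
    """
    targets = list(targets)
    out = np.empty((ensemble.n_conformers, len(targets)))
    for c in range(ensemble.n_conformers):
        pos = _target_positions(ensemble.conformer(c), targets)
        d = cdist(site.points[c], pos)  # (P, T)
        if np.any(d == 0):
            raise ValueError("label point coincides with a target atom")
        inv6 = (site.point_weights[c][:, None] * d**-6).sum(axis=0)
        r_eff = inv6 ** (-1.0 / 6.0)
        out[c] = distance_to_gamma2(r_eff, tau_c, omega_h, k)
    if cap is not None:
        out = np.minimum(out, cap)
    return out


def predict_pre(
    ensemble: ConformerEnsemble,
    site: LabelSite,
    targets,
    tau_c: float,
    omega_h: float,
    cap: float = GAMMA2_CAP_DEFAULT,
    k: float = PRE_K_CM6_S2,
) -> np.ndarray:
    """Ensemble Γ₂ per target residue: weighted mean of the per-conformer
    (cap-clipped) rates; never exceeds the cap."""
    per_conf = per_conformer_pre(ensemble, site, targets, tau_c, omega_h, cap, k)
    return ensemble.weights @ per_conf
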