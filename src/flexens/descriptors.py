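"""Ensemble-level structural descriptors.

* Weighted radius of gyration R_g = sqrt(Σ w_c R_g,c²) over Cα atoms.
* Distance RMSD matrix D_kl: the RMS difference of internal Cα-Cα distances
  between two conformers — a superposition-free shape difference that has
  the properties of a Euclidean distance.
* Disorder parameter δ = R_g,ACS / R_g, where R_g,ACS is the weighted radius
  of gyration of the conformer point set embedded into abstract conformer
  space (ACS) by classical multidimensional scaling of D_kl.  δ is close to
  0.1 for rigid folded ensembles and reaches 0.6-0.8 for random-coil-like
  ensembles.
* Contact maps (3 Å atom-pair rule), binding-pose checks (7.5 Å rule), and
  average-linkage cluster analysis of merged pools to classify binding
  transitions (mixed / source-exclusive clusters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform

from flexens.io_formats import Conformer, ConformerEnsemble

__all__ = [
    "radius_of_gyration",
    "per_conformer_rg",
    "drmsd_matrix",
    "disorder_parameter",
    "contact_map",
    "binding_pose_check",
    "ensemble_pose_summary",
    "merged_cluster_analysis",
    "ClusterReport",
]


def per_conformer_rg(ensemble: ConformerEnsemble) -> np.ndarray:
    """Radius of gyration of each conformer over its Cα atoms, in Å."""
    ca = ensemble.ca_coords()
    centred = ca - ca.mean(axis=1, keepdims=True)
    return np.sqrt((centred**2).sum(axis=2).mean(axis=1))


def radius_of_gyration(ensemble: ConformerEnsemble) -> float:
    """Ensemble radius of gyration: weighted RMS over conformer values."""
    rg = per_conformer_rg(ensemble)
    return float(np.sqrt(np.sum(ensemble.weights * rg**2)))


def drmsd_matrix(ensemble: ConformerEnsemble, stride: int = 1) -> np.ndarray:
    """Pairwise distance-RMSD matrix D_kl over Cα internal distances.

    ``stride`` subsamples the Cα set for large systems (default: all atoms).
    Symmetric with a zero diagonal; invariant to rigid-body moves of any
    conformer.
    """
    if ensemble.n_conformers < 2:
        raise ValueError("dRMSD needs at least two conformers")
    ca = ensemble.ca_coords()[:, ::stride, :]
    dists = np.stack([pdist(x) for x in ca])  # (C, n_pairs)
    sq = (dists**2).sum(axis=1)
    gram = dists @ dists.T
    n_pairs = dists.shape[1]
    d2 = (sq[:, None] + sq[None, :] - 2.0 * gram) / n_pairs
    return np.sqrt(np.clip(d2, 0.0, None))


def disorder_parameter(
    ensemble: ConformerEnsemble, drmsd: np.ndarray | None = None
) -> tuple[float, float]:
    """(R_g,ACS, δ): spread of the ensemble in abstract conformer space.

    Classical MDS embeds the conformers from the double-centred squared
    D_kl matrix (negative eigenvalues truncated to zero); R_g,ACS is the
    weighted radius of gyration of the embedded points using the ensemble
    weights, and δ = R_g,ACS / R_g.  An ensemble of identical conformers
    gives δ = 0.
    """
    if drmsd is None:
        drmsd = drmsd_matrix(ensemble)
    c = drmsd.shape[0]
    d2 = drmsd**2
    j = np.eye(c) - np.full((c, c), 1.0 / c)
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    evals = np.clip(evals, 0.0, None)
    coords = evecs * np.sqrt(evals)[None, :]
    w = ensemble.weights
    centre = w @ coords
    rg_acs = float(np.sqrt(np.sum(w * ((coords - centre) ** 2).sum(axis=1))))
    rg = radius_of_gyration(ensemble)
    delta = rg_acs / rg if rg > 0 else 0.0
    return rg_acs, float(delta)


def contact_map(
    ensemble: ConformerEnsemble,
    group_a,
    group_b,
    cutoff: float = 3.0,
):
    """Weighted contact fractions between two residue groups.

    A residue pair (a, b) is in contact in a conformer iff the minimum
    atom-pair distance between the two residues is at or below ``cutoff``
    (3 Å by default).  The reported fraction is the summed weight of
    conformers showing the contact; per-residue totals (fraction of weight
    with any cross-group contact involving the residue) are also returned.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if not group_a or not group_b:
        raise ValueError("residue groups must be non-empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    idx_a = {r: np.flatnonzero(ensemble.residue_ids == r) for r in group_a}
    idx_b = {r: np.flatnonzero(ensemble.residue_ids == r) for r in group_b}
    for r, idx in {**idx_a, **idx_b}.items():
        if idx.size == 0:
            raise ValueError(f"residue {r} has no atoms")
    fractions: dict[tuple[int, int], float] = {}
    per_residue = {r: 0.0 for r in group_a + group_b}
    for c in range(ensemble.n_conformers):
        w = ensemble.weights[c]
        coords = ensemble.coords[c]
        touched = set()
        for ra, ia in idx_a.items():
            for rb, ib in idx_b.items():
                dmin = cdist(coords[ia], coords[ib]).min()
                if dmin <= cutoff:
                    fractions[(ra, rb)] = fractions.get((ra, rb), 0.0) + w
                    touched.update((ra, rb))
        for r in touched:
            per_residue[r] += w
    return fractions, per_residue


def format_contact_percent(fraction: float) -> str:
    """Report style: one decimal percent (0.0286 -> '2.9 %')."""
    return f"{100.0 * fraction:.1f} %"


def binding_pose_check(
    conformer: Conformer,
    motif_atoms,
    domain_atoms,
    threshold: float = 7.5,
) -> tuple[float, bool]:
    """Shortest cross-set atom distance and whether it is below threshold."""
    motif_atoms = np.asarray(motif_atoms, dtype=int)
    domain_atoms = np.asarray(domain_atoms, dtype=int)
    if motif_atoms.size == 0 or domain_atoms.size == 0:
        raise ValueError("atom sets must be non-empty")
    dmin = float(
        cdist(conformer.coords[motif_atoms], conformer.coords[domain_atoms]).min()
    )
    return dmin, dmin < threshold


def ensemble_pose_summary(
    ensemble: ConformerEnsemble,
    motif_a,
    domain_a,
    motif_b,
    domain_b,
    threshold: float = 7.5,
) -> tuple[int, float]:
    """Count and weight fraction of conformers passing both motif checks."""
    count, weight = 0, 0.0
    for c in range(ensemble.n_conformers):
        conf = ensemble.conformer(c)
        _, ok_a = binding_pose_check(conf, motif_a, domain_a, threshold)
        _, ok_b = binding_pose_check(conf, motif_b, domain_b, threshold)
        if ok_a and ok_b:
            count += 1
            weight += ensemble.weights[c]
    return count, float(weight)


@dataclass
class ClusterReport:
    """Merged-pool clustering outcome: per-cluster class and populations."""

    labels: np.ndarray          # cluster id per merged conformer
    sources: np.ndarray         # 0 for ensemble A, 1 for ensemble B
    classes: dict[int, str]     # cluster id -> mixed | A_only | B_only
    class_fractions: dict[str, dict[str, float]]  # per-source weight shares
    n_clusters: int


def merged_cluster_analysis(
    ensemble_a: ConformerEnsemble,
    ensemble_b: ConformerEnsemble,
    mean_cluster_size: int = 12,
) -> ClusterReport:
    """Cluster the merged pool of two ensembles and classify the clusters.

    Average-linkage hierarchical clustering of the merged D_kl matrix, cut
    into round(C / mean_cluster_size) clusters (default aims for about 12
    conformers per cluster).  Each cluster is classified by member
    provenance as mixed, A-only, or B-only.  Fractions are normalized
    within each source ensemble: ``class_fractions["A"]["mixed"]`` is the
    weight of A's conformers that sit in mixed clusters relative to all of
    A's weight, and ``["A"]["exclusive"]`` the weight in A-only clusters
    (the two sum to one; likewise for B).
    """
    merged = ensemble_a.merged_with(ensemble_b)
    c = merged.n_conformers
    n_clusters = max(int(round(c / mean_cluster_size)), 1)
    if n_clusters < 2:
        raise ValueError("merged pool too small for at least two clusters")
    d = drmsd_matrix(merged)
    labels = fcluster(
        linkage(squareform(d, checks=False), method="average"),
        n_clusters,
        criterion="maxclust",
    )
    sources = np.array(
        [0] * ensemble_a.n_conformers + [1] * ensemble_b.n_conformers
    )
    # each source's weights sum to 1 on their own; keep them un-merged so
    # fractions are normalized within each source ensemble
    w = np.concatenate([ensemble_a.weights, ensemble_b.weights])
    classes: dict[int, str] = {}
    frac = {
        "A": {"mixed": 0.0, "exclusive": 0.0},
        "B": {"mixed": 0.0, "exclusive": 0.0},
    }
    for cid in sorted(set(labels.tolist())):
        members = labels == cid
        in_a = members & (sources == 0)
        in_b = members & (sources == 1)
        has_a, has_b = bool(np.any(in_a)), bool(np.any(in_b))
        cls = "mixed" if (has_a and has_b) else ("A_only" if has_a else "B_only")
        classes[cid] = cls
        key = "mixed" if cls == "mixed" else "exclusive"
        frac["A"][key] += float(np.sum(w[in_a]))
        frac["B"][key] += float(np.sum(w[in_b]))
    return ClusterReport(labels, sources, classes, frac, n_clusters)
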