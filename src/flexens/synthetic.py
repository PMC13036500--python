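"""Seeded synthetic two-domain systems with known ground truth.

The generator emulates the study conditions of a tandem-domain protein:
two rigid domains of ~70 residues each, modelled as Cα point clouds drawn
once per system from a 10 Å-radius ball, joined by a ~30-residue flexible
linker resampled per conformer as a fixed-bond-length (3.8 Å) random chain
with a soft self-avoidance check.  Three label sites per domain plus one
linker site mirror a typical spin-labelling scheme.  Forward-simulated
restraints cover broad uni- or bimodal distance distributions in the
15-80 Å range and PRE rates in 0-170 s⁻¹ with vanished-peak flags; noise is
zero-mean Gaussian on the distribution densities (clipped at zero and
renormalized) and on the PRE rates.

Side chains are deliberately absent: the downstream descriptors (Cα radius
of gyration, dRMSD, label clouds) never require side-chain detail, and
amide positions are approximated by the Cα positions for PRE targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from flexens.io_formats import (
    ConformerEnsemble,
    write_distance_distribution,
    write_ensemble,
    write_pre_table,
)
from flexens.labels import LabelSite, build_site, cloud_centroid, predict_distance_distribution, predict_pre
from flexens.metrics import DistanceDistribution
from flexens.multistate import RigidTopology
from flexens.nmr import PRETable
from flexens.reweigh import RestraintSet

__all__ = [
    "ToySystemSpec",
    "NoiseSpec",
    "GroundTruth",
    "build_pool",
    "build_rigid_jitter_pool",
    "make_truth_ensemble",
    "default_sites",
    "default_deer_pairs",
    "default_pre_targets",
    "simulate_restraints",
    "rigid_topology",
    "write_fixture",
]

#: Conditions of the emulated experiment: τc of the tandem construct and the
#: spectrometer ¹H frequency used for the PRE acquisition.
DEFAULT_TAU_C = 11.0e-9
DEFAULT_NU_H_HZ = 700.0e6
DEFAULT_CAP = 170.0

#: Grid for synthetic distributions: wide enough to cover the full reach of
#: a 30-residue linker with margin for the label clouds.
DEFAULT_SYN_GRID = np.arange(0.0, 120.0 + 0.25, 0.5)
DEFAULT_KERNEL_SIGMA = 1.0


@dataclass
class ToySystemSpec:
    """Geometry and labelling scheme of a synthetic two-domain system."""

    domain_size: int = 70
    linker_length: int = 30
    bond_length: float = 3.8
    domain_radius: float = 10.0
    seed: int = 0
    label_sites: dict[str, int] = field(default_factory=dict)
    motif_residues: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.linker_length < 1:
            raise ValueError("linker_length must be >= 1")
        if not self.label_sites:
            d, l = self.domain_size, self.linker_length
            self.label_sites = {
                "d1a": d // 6, "d1b": d // 2, "d1c": d - d // 6,
                "lnk": d + l // 2,
                "d2a": d + l + d // 6, "d2b": d + l + d // 2,
                "d2c": d + l + d - d // 6,
            }
        if not self.motif_residues:
            self.motif_residues = (self.domain_size // 2, self.domain_size // 2 + 1)
        n = self.n_residues
        for site, rid in self.label_sites.items():
            if not 1 <= rid <= n:
                raise ValueError(f"label site {site!r} at residue {rid} outside 1..{n}")

    @property
    def n_residues(self) -> int:
        return 2 * self.domain_size + self.linker_length

    @property
    def domain1_residues(self) -> np.ndarray:
        return np.arange(1, self.domain_size + 1)

    @property
    def linker_residues(self) -> np.ndarray:
        return np.arange(self.domain_size + 1, self.domain_size + self.linker_length + 1)

    @property
    def domain2_residues(self) -> np.ndarray:
        return np.arange(
            self.domain_size + self.linker_length + 1, self.n_residues + 1
        )

    def domain_of(self, residue: int) -> str:
        if residue in self.domain1_residues:
            return "d1"
        if residue in self.domain2_residues:
            return "d2"
        return "linker"

    def domain_residues_of_site(self, site: str) -> np.ndarray | None:
        dom = self.domain_of(self.label_sites[site])
        if dom == "d1":
            return self.domain1_residues
        if dom == "d2":
            return self.domain2_residues
        return None


@dataclass
class NoiseSpec:
    """Noise model for simulated restraints.

    Distribution densities receive zero-mean Gaussian noise with standard
    deviation ``density_sigma_frac`` of the peak density (clipped at zero,
    renormalized).  PRE rates receive Gaussian noise with standard
    deviation max(pre_sigma_base, pre_sigma_frac · Γ₂); that same value is
    reported as the table's error column (floored at 1 s⁻¹ for a fully
    noise-free specification so chi-square stays defined).
    """

    density_sigma_frac: float = 0.05
    pre_sigma_base: float = 2.0
    pre_sigma_frac: float = 0.05

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0)

    def pre_sigma(self, gamma2: np.ndarray) -> np.ndarray:
        return np.maximum(self.pre_sigma_base, self.pre_sigma_frac * np.asarray(gamma2))


@dataclass
class GroundTruth:
    """Truth ensemble with matched noiseless and noisy restraint sets."""

    truth: ConformerEnsemble
    noiseless: RestraintSet
    noisy: RestraintSet
    noise: NoiseSpec
    sites: dict[str, LabelSite]


def _domain_template(spec: ToySystemSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rigid Cα clouds for the two domains, sampled once per system spec."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(2):
        pts = np.empty((spec.domain_size, 3))
        got = 0
        while got < spec.domain_size:
            cand = rng.uniform(-spec.domain_radius, spec.domain_radius, size=(64, 3))
            cand = cand[np.linalg.norm(cand, axis=1) <= spec.domain_radius]
            take = min(cand.shape[0], spec.domain_size - got)
            pts[got : got + take] = cand[:take]
            got += take
        pts = pts - pts.mean(axis=0)
        out.append(pts)
    dom1, dom2 = out
    # attach the linker at surface residues: the linker leaves domain 1 from
    # its most exposed point and enters domain 2 at the same kind of point
    far1 = int(np.argmax(np.linalg.norm(dom1, axis=1)))
    dom1[[far1, -1]] = dom1[[-1, far1]]
    far2 = int(np.argmax(np.linalg.norm(dom2, axis=1)))
    dom2[[far2, 0]] = dom2[[0, far2]]
    return dom1, dom2


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def _sample_linker(
    start: np.ndarray,
    n_beads: int,
    bond: float,
    rng: np.random.Generator,
    obstacles: np.ndarray,
    min_sep: float = 3.0,
    max_attempts: int = 100,
) -> np.ndarray:
    """Fixed-bond-length random chain with a soft self-avoidance check.

    The chain grows bead by bead; a step that would place a bead closer
    than ``min_sep`` to any non-bonded bead (or to an obstacle Cα) is
    redrawn.  If a step exhausts its redraws the whole chain is resampled,
    up to ``max_attempts`` chains.
    """
    for _ in range(max_attempts):
        beads = np.empty((n_beads, 3))
        pos = start
        failed = False
        for i in range(n_beads):
            for _try in range(40):
                cand = pos + bond * _random_unit(rng)
                prev = beads[: max(i - 1, 0)]  # non-bonded earlier beads
                if prev.size and np.min(np.linalg.norm(prev - cand, axis=1)) < min_sep:
                    continue
                if obstacles.size and np.min(
                    np.linalg.norm(obstacles - cand, axis=1)
                ) < min_sep:
                    continue
                break
            else:
                failed = True
                break
            beads[i] = cand
            pos = cand
        if not failed:
            return beads
    raise RuntimeError(
        "could not sample a self-avoiding linker in "
        f"{max_attempts} attempts; consider a longer linker"
    )


def _assemble_conformer(
    spec: ToySystemSpec,
    dom1: np.ndarray,
    dom2: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    anchor1 = dom1[-1]
    for _ in range(100):
        linker = _sample_linker(
            anchor1, spec.linker_length, spec.bond_length, rng, dom1
        )
        # place domain 2 with a clash check against domain 1 (the two folded
        # domains are mutually excluded volumes; the linker is not)
        for _ in range(50):
            rot = _random_rotation(rng)
            d2 = dom2 @ rot.T
            anchor_target = linker[-1] + spec.bond_length * _random_unit(rng)
            d2 = d2 + (anchor_target - d2[0])
            from scipy.spatial.distance import cdist

            if cdist(d2, dom1).min() >= 3.0:
                return np.concatenate([dom1, linker, d2])
    raise RuntimeError("could not place domain 2 without clashes")


def _pool_from_coords(spec: ToySystemSpec, coords: np.ndarray, tag: str) -> ConformerEnsemble:
    n = spec.n_residues
    return ConformerEnsemble(
        names=np.full(n, "CA", dtype=object),
        residue_ids=np.arange(1, n + 1),
        chain_ids=np.full(n, "A", dtype=object),
        elements=np.full(n, "C", dtype=object),
        coords=coords,
        provenance=[f"{tag}:{i + 1}" for i in range(coords.shape[0])],
    )


def build_pool(spec: ToySystemSpec, n: int, seed: int) -> ConformerEnsemble:
    """Sample n conformers: rigid domains, random self-avoiding linker.

    Domain-internal coordinates are identical across conformers up to a
    rigid-body transform of domain 2; the linker is resampled per
    conformer.  Deterministic for a fixed (spec, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dom1, dom2 = _domain_template(spec)
    rng = np.random.default_rng([seed, spec.seed])
    coords = np.stack([_assemble_conformer(spec, dom1, dom2, rng) for _ in range(n)])
    return _pool_from_coords(spec, coords, f"pool_seed{seed}")


def build_rigid_jitter_pool(
    spec: ToySystemSpec,
    n: int,
    seed: int,
    jitter_sigma: float = 0.3,
    n_arrangements: int = 1,
) -> ConformerEnsemble:
    """Pool of small perturbations around one or more fixed arrangements.

    With ``n_arrangements=1`` this emulates a rigid, well-ordered system
    (tiny coordinate jitter around a single conformation); with 2 it
    produces two separated islands, which yields bimodal pair distance
    distributions.
    """
    dom1, dom2 = _domain_template(spec)
    rng = np.random.default_rng([seed, spec.seed, 7])
    bases = [
        _assemble_conformer(spec, dom1, dom2, rng) for _ in range(n_arrangements)
    ]
    coords = np.empty((n, spec.n_residues, 3))
    for i in range(n):
        base = bases[i % n_arrangements]
        coords[i] = base + rng.normal(0.0, jitter_sigma, size=base.shape)
    return _pool_from_coords(spec, coords, f"jitter_seed{seed}")


def make_truth_ensemble(
    pool: ConformerEnsemble, k: int, concentration: float, seed: int
) -> tuple[ConformerEnsemble, np.ndarray]:
    """Draw k conformers without replacement with Dirichlet weights.

    Returns the truth ensemble and the indices of its conformers in the
    pool.  ``concentration`` is the symmetric Dirichlet parameter (large
    values approach uniform weights).
    """
    if k > pool.n_conformers:
        raise ValueError(f"cannot draw {k} conformers from a pool of {pool.n_conformers}")
    rng = np.random.default_rng(seed)
    indices = np.sort(rng.choice(pool.n_conformers, size=k, replace=False))
    weights = rng.dirichlet(np.full(k, concentration))
    return pool.subset(indices, weights), indices


def default_sites(
    spec: ToySystemSpec, ensemble: ConformerEnsemble, seed: int = 0
) -> dict[str, LabelSite]:
    """Attach the spec's label scheme to every conformer of an ensemble."""
    sites = {}
    for idx, (site_id, residue) in enumerate(sorted(spec.label_sites.items())):
        sites[site_id] = build_site(
            ensemble, site_id, residue,
            model="gauss_cloud",
            seed=int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31)),
            domain_residues=spec.domain_residues_of_site(site_id),
        )
    return sites


def default_deer_pairs(spec: ToySystemSpec) -> list[tuple[str, str]]:
    """Eight pairs: six inter-domain plus two involving the linker site."""
    return [
        ("d1a", "d2a"), ("d1a", "d2b"), ("d1b", "d2b"), ("d1b", "d2c"),
        ("d1c", "d2a"), ("d1c", "d2c"), ("d1a", "lnk"), ("lnk", "d2c"),
    ]


def default_pre_targets(spec: ToySystemSpec, site: str, stride: int = 3) -> np.ndarray:
    """PRE target residues for a site: the other domain plus the linker.

    Intra-domain PREs are uninformative for the rigid-domain system and are
    omitted; a stride keeps the tables compact.
    """
    dom = spec.domain_of(spec.label_sites[site])
    if dom == "d1":
        others = np.concatenate([spec.linker_residues, spec.domain2_residues])
    elif dom == "d2":
        others = np.concatenate([spec.domain1_residues, spec.linker_residues])
    else:
        others = np.concatenate([spec.domain1_residues, spec.domain2_residues])
    return others[::stride]


def simulate_restraints(
    truth: ConformerEnsemble,
    spec: ToySystemSpec,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    deer_pairs=None,
    pre_sites=("d1b", "d2b"),
    grid: np.ndarray = DEFAULT_SYN_GRID,
    kernel_sigma: float = DEFAULT_KERNEL_SIGMA,
    tau_c: float = DEFAULT_TAU_C,
    nu_h_hz: float = DEFAULT_NU_H_HZ,
    cap: float = DEFAULT_CAP,
    sites_seed: int = 0,
) -> GroundTruth:
    """Forward-simulate DEER and PRE observables from a truth ensemble.

    The noiseless restraints are exactly the forward-model output on the
    truth ensemble; the noisy copies add Gaussian noise (densities clipped
    at zero and renormalized; rates above the cap flagged as vanished and
    set to the cap).  Confidence bands of noisy distributions are ±2 noise
    standard deviations.
    """
    noise = noise or NoiseSpec()
    deer_pairs = deer_pairs or default_deer_pairs(spec)
    omega_h = 2.0 * np.pi * nu_h_hz
    rng = np.random.default_rng(seed)
    sites = default_sites(spec, truth, seed=sites_seed)

    clean_deer, noisy_deer = {}, {}
    for pair in deer_pairs:
        a, b = pair
        dist = predict_distance_distribution(
            truth, sites[a], sites[b], grid, kernel_sigma
        )
        clean_deer[pair] = dist
        sigma = noise.density_sigma_frac * dist.density.max()
        noisy = dist.density + rng.normal(0.0, sigma, size=dist.density.shape) if sigma > 0 else dist.density.copy()
        noisy = np.clip(noisy, 0.0, None)
        band = 2.0 * sigma
        noisy_deer[pair] = DistanceDistribution(
            grid, noisy,
            ci_lower=np.clip(noisy - band, 0.0, None),
            ci_upper=noisy + band,
        )

    clean_pre, noisy_pre = {}, {}
    for site_id in pre_sites:
        targets = default_pre_targets(spec, site_id)
        gamma2 = predict_pre(truth, sites[site_id], targets, tau_c, omega_h, cap)
        sigma = noise.pre_sigma(gamma2)
        err = np.maximum(sigma, 1.0)
        status_clean = np.where(gamma2 >= cap, "vanished", "observed").astype(object)
        clean_pre[site_id] = PRETable(targets, gamma2, err, status_clean)
        noisy_gamma = gamma2 + (rng.normal(0.0, 1.0, size=gamma2.shape) * sigma)
        noisy_gamma = np.clip(noisy_gamma, 0.0, None)
        status = np.where(noisy_gamma >= cap, "vanished", "observed").astype(object)
        noisy_gamma = np.minimum(noisy_gamma, cap)
        noisy_pre[site_id] = PRETable(targets, noisy_gamma, err, status)

    return GroundTruth(
        truth=truth,
        noiseless=RestraintSet(clean_deer, clean_pre),
        noisy=RestraintSet(noisy_deer, noisy_pre),
        noise=noise,
        sites=sites,
    )


def rigid_topology(
    spec: ToySystemSpec, sites_seed: int = 0
) -> RigidTopology:
    """Two-domain rigid topology with label centres for multi-state runs.

    Label centres are the cloud centroids on the domain templates; linker
    sites have no fixed frame and are omitted.
    """
    dom1, dom2 = _domain_template(spec)
    reference = _pool_from_coords(
        spec,
        np.concatenate(
            [dom1, np.zeros((spec.linker_length, 3)), dom2 + np.array([60.0, 0, 0])]
        )[None],
        "topology",
    )
    sites = default_sites(spec, reference, seed=sites_seed)
    labels1, labels2 = {}, {}
    for site_id, site in sites.items():
        dom = spec.domain_of(spec.label_sites[site_id])
        centre = cloud_centroid(
            site.points[0], site.point_weights[0], np.zeros((1, 3)), site_id
        ).centroid
        if dom == "d1":
            labels1[site_id] = centre
        elif dom == "d2":
            labels2[site_id] = centre - np.array([60.0, 0, 0])
    return RigidTopology(
        domain1_ca=dom1,
        domain2_ca=dom2,
        domain1_residues=spec.domain1_residues,
        domain2_residues=spec.domain2_residues,
        linker_length=spec.linker_length,
        bond_length=spec.bond_length,
        labels1=labels1,
        labels2=labels2,
    )


def write_fixture(
    out_dir,
    spec: ToySystemSpec,
    pool: ConformerEnsemble,
    truth: ConformerEnsemble,
    ground_truth: GroundTruth,
    tau_c: float = DEFAULT_TAU_C,
    nu_h_hz: float = DEFAULT_NU_H_HZ,
    cap: float = DEFAULT_CAP,
    grid: np.ndarray = DEFAULT_SYN_GRID,
    kernel_sigma: float = DEFAULT_KERNEL_SIGMA,
    seed: int = 0,
) -> Path:
    """Write a complete fixture directory (pool, truth weights, manifest,
    noiseless and noisy restraint tables); returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ensemble(out / "pool.pdb", pool)
    write_ensemble(out / "truth.pdb", truth, weights_path=out / "truth_weights.tsv")
    deer_entries, pre_entries = [], []
    for kind, rset in (("noiseless", ground_truth.noiseless), ("noisy", ground_truth.noisy)):
        sub = out / kind
        sub.mkdir(exist_ok=True)
        for (a, b), dist in rset.deer.items():
            fname = f"{kind}/deer_{a}_{b}.tsv"
            write_distance_distribution(out / fname, dist)
            if kind == "noisy":
                deer_entries.append({"sites": [a, b], "file": fname})
        for site_id, table in rset.pre.items():
            fname = f"{kind}/pre_{site_id}.tsv"
            write_pre_table(out / fname, table)
            if kind == "noisy":
                pre_entries.append({"site": site_id, "file": fname})
    manifest = {
        "sites": {k: {"residue": int(v)} for k, v in spec.label_sites.items()},
        "scalars": {
            "tau_c_ns": tau_c * 1e9,
            "h_frequency_mhz": nu_h_hz / 1e6,
            "gamma2_cap": cap,
        },
        "options": {
            "grid_min": float(grid[0]),
            "grid_max": float(grid[-1]),
            "grid_step": float(grid[1] - grid[0]),
            "kernel_sigma": kernel_sigma,
            "seed": seed,
        },
        "deer": deer_entries,
        "pre": pre_entries,
    }
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path
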