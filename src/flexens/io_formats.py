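"""Readers and writers for ensembles, restraint tables, and the manifest.

Conformer pools travel as standard multi-model PDB files (one MODEL per
conformer); conformer weights live in a plain two-column sidecar text file
(1-based conformer index, weight) so the PDB stays standard-compliant.
Distance distributions and PRE tables are TSV with a mandatory header row;
comment lines start with '#'.  The restraint manifest is a YAML file tying
label-site pairs to distribution files and label sites to PRE tables, with
acquisition scalars (τc, ¹H frequency) and grid options.

All coordinates and distances are in Å, times in s, rates in s⁻¹;
frequencies are accepted in MHz in the manifest and converted once at load.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from flexens.metrics import DistanceDistribution
from flexens.nmr import PRETable

logger = logging.getLogger(__name__)

__all__ = [
    "Conformer",
    "ConformerEnsemble",
    "RestraintManifest",
    "read_ensemble",
    "write_ensemble",
    "read_weights",
    "write_weights",
    "read_distance_distribution",
    "write_distance_distribution",
    "read_pre_table",
    "write_pre_table",
    "reconstruct_amide_protons",
    "load_manifest",
]

_PRE_STATUSES = {"observed", "vanished", "unreliable"}


@dataclass
class Conformer:
    """A single atomic model: shared topology arrays plus one coordinate set."""

    names: np.ndarray
    residue_ids: np.ndarray
    chain_ids: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    residue_names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.residue_names is None:
            self.residue_names = np.full(self.names.size, "GLY", dtype=object)
        else:
            self.residue_names = np.asarray(self.residue_names, dtype=object)
        if self.coords.shape != (self.names.size, 3):
            raise ValueError("coords must have shape (n_atoms, 3)")

    @property
    def n_atoms(self) -> int:
        return int(self.names.size)

    def atom_index(self, residue: int, name: str) -> int | None:
        hit = np.flatnonzero((self.residue_ids == residue) & (self.names == name))
        return int(hit[0]) if hit.size else None


@dataclass
class ConformerEnsemble:
    """Ordered conformers sharing one topology, with simplex weights w_c.

    Invariants: all conformers share an identical atom count and ordering;
    weights are non-negative and sum to one; at least one conformer.
    """

    names: np.ndarray
    residue_ids: np.ndarray
    chain_ids: np.ndarray
    elements: np.ndarray
    coords: np.ndarray  # (C, A, 3)
    weights: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)
    residue_names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise ValueError("coords must have shape (n_conformers >= 1, n_atoms, 3)")
        if self.coords.shape[1] != self.names.size or self.coords.shape[2] != 3:
            raise ValueError("coordinate array does not match topology")
        if self.residue_names is None:
            self.residue_names = np.full(self.names.size, "GLY", dtype=object)
        else:
            self.residue_names = np.asarray(self.residue_names, dtype=object)
        c = self.coords.shape[0]
        if self.weights is None:
            self.weights = np.full(c, 1.0 / c)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.size != c:
                raise ValueError(
                    f"{self.weights.size} weights for {c} conformers"
                )
            if np.any(self.weights < -1e-12):
                raise ValueError("weights must be non-negative")
            self.weights = np.clip(self.weights, 0.0, None)
            total = self.weights.sum()
            if total <= 0:
                raise ValueError("weights sum to zero")
            self.weights = self.weights / total
        if not self.provenance:
            self.provenance = [f"conformer_{i + 1}" for i in range(c)]
        elif len(self.provenance) != c:
            raise ValueError("provenance length does not match conformer count")

    @property
    def n_conformers(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    def conformer(self, i: int) -> Conformer:
        return Conformer(
            self.names, self.residue_ids, self.chain_ids, self.elements,
            self.coords[i], self.residue_names,
        )

    def ca_mask(self) -> np.ndarray:
        return self.names == "CA"

    def ca_coords(self) -> np.ndarray:
        """(C, n_CA, 3) Cα coordinates; raises if no Cα atoms are present."""
        mask = self.ca_mask()
        if not np.any(mask):
            raise ValueError("ensemble contains no CA atoms")
        return self.coords[:, mask, :]

    def with_weights(self, weights: np.ndarray) -> "ConformerEnsemble":
        return ConformerEnsemble(
            self.names, self.residue_ids, self.chain_ids, self.elements,
            self.coords, np.asarray(weights, dtype=float),
            list(self.provenance), self.residue_names,
        )

    def subset(
        self, indices, weights: np.ndarray | None = None
    ) -> "ConformerEnsemble":
        """Sub-ensemble of the given conformer indices (weights renormalized)."""
        indices = np.asarray(indices, dtype=int)
        w = self.weights[indices] if weights is None else np.asarray(weights, float)
        return ConformerEnsemble(
            self.names, self.residue_ids, self.chain_ids, self.elements,
            self.coords[indices], w,
            [self.provenance[i] for i in indices], self.residue_names,
        )

    def merged_with(self, other: "ConformerEnsemble") -> "ConformerEnsemble":
        """Concatenate two ensembles sharing a topology; weights are stacked
        and renormalized (each source contributes its own total weight)."""
        if self.coords.shape[1:] != other.coords.shape[1:]:
            raise ValueError("ensembles have different topologies")
        return ConformerEnsemble(
            self.names, self.residue_ids, self.chain_ids, self.elements,
            np.concatenate([self.coords, other.coords]),
            np.concatenate([self.weights, other.weights]),
            list(self.provenance) + list(other.provenance),
            self.residue_names,
        )


def _check_topology(ref: Conformer, other: Conformer, model_idx: int) -> None:
    if ref.n_atoms != other.n_atoms:
        raise ValueError(
            f"model {model_idx + 1} has {other.n_atoms} atoms, expected {ref.n_atoms}"
        )
    same = (
        (ref.names == other.names)
        & (ref.residue_ids == other.residue_ids)
        & (ref.chain_ids == other.chain_ids)
    )
    if not np.all(same):
        i = int(np.flatnonzero(~same)[0])
        raise ValueError(
            f"topology mismatch in model {model_idx + 1} at atom {i + 1}: "
            f"expected {ref.chain_ids[i]}/{ref.residue_ids[i]}/{ref.names[i]}, "
            f"found {other.chain_ids[i]}/{other.residue_ids[i]}/{other.names[i]}"
        )


def _model_to_conformer(model) -> Conformer:
    names, resids, chains, elements, resnames, xyz = [], [], [], [], [], []
    for chain in model:
        for residue in chain:
            for atom in residue:
                names.append(atom.name)
                resids.append(residue.seqid.num)
                chains.append(chain.name)
                elements.append(atom.element.name)
                resnames.append(residue.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return Conformer(
        np.array(names, dtype=object),
        np.array(resids, dtype=int),
        np.array(chains, dtype=object),
        np.array(elements, dtype=object),
        np.array(xyz, dtype=float),
        np.array(resnames, dtype=object),
    )


def read_ensemble(path, weights_path=None) -> ConformerEnsemble:
    """Read a multi-model PDB into a ConformerEnsemble.

    Verifies that every model shares the same atom count and ordering.
    Weights come from the optional sidecar table and are renormalized;
    without a sidecar they default to uniform 1/C.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    conformers = [_model_to_conformer(m) for m in st]
    ref = conformers[0]
    for i, c in enumerate(conformers[1:], start=1):
        _check_topology(ref, c, i)
    coords = np.stack([c.coords for c in conformers])
    weights = None
    if weights_path is not None:
        weights = read_weights(weights_path, expected=len(conformers))
    tag = Path(path).stem
    return ConformerEnsemble(
        ref.names, ref.residue_ids, ref.chain_ids, ref.elements, coords,
        weights, [f"{tag}:{i + 1}" for i in range(len(conformers))],
        ref.residue_names,
    )


def write_ensemble(path, ensemble: ConformerEnsemble, weights_path=None) -> None:
    """Write a multi-model PDB (and optionally the weight sidecar)."""
    st = gemmi.Structure()
    st.name = Path(path).stem
    for c in range(ensemble.n_conformers):
        model = gemmi.Model(c + 1)
        chain = None
        residue = None
        last = (None, None)
        for a in range(ensemble.n_atoms):
            cid = str(ensemble.chain_ids[a])
            rid = int(ensemble.residue_ids[a])
            if chain is None or cid != chain.name:
                chain = gemmi.Chain(cid)
                model.add_chain(chain)
                chain = model[-1]
                last = (None, None)
            if last != (cid, rid):
                residue = gemmi.Residue()
                residue.name = str(ensemble.residue_names[a])
                residue.seqid = gemmi.SeqId(rid, " ")
                chain.add_residue(residue)
                residue = chain[-1]
                last = (cid, rid)
            atom = gemmi.Atom()
            atom.name = str(ensemble.names[a])
            atom.element = gemmi.Element(str(ensemble.elements[a]))
            x, y, z = ensemble.coords[c, a]
            atom.pos = gemmi.Position(x, y, z)
            residue.add_atom(atom)
        st.add_model(model)
    st.write_pdb(str(path))
    if weights_path is not None:
        write_weights(weights_path, ensemble.weights)


def read_weights(path, expected: int | None = None) -> np.ndarray:
    """Read the two-column sidecar weight table (1-based index, weight)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        idx, w = line.split()
        rows.append((int(idx), float(w)))
    rows.sort()
    weights = np.array([w for _, w in rows], dtype=float)
    if expected is not None and weights.size != expected:
        raise ValueError(
            f"{path}: {weights.size} weights for {expected} conformers"
        )
    return weights


def write_weights(path, weights: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("# conformer_index weight\n")
        for i, w in enumerate(np.asarray(weights, dtype=float), start=1):
            fh.write(f"{i} {w:.12g}\n")


def read_distance_distribution(path) -> DistanceDistribution:
    """Read a TSV distance distribution (r_angstrom, p[, ci_lower, ci_upper]).

    The grid must be strictly increasing with a uniform step; the density is
    renormalized to unit trapezoid integral.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("r_angstrom", "p"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    r = df["r_angstrom"].to_numpy(dtype=float)
    p = df["p"].to_numpy(dtype=float)
    if np.any(p < 0):
        raise ValueError(f"{path}: negative densities")
    if not np.all(p == 0) and np.trapezoid(p, r) <= 0:
        raise ValueError(f"{path}: degenerate distribution")
    if np.all(p == 0):
        raise ValueError(f"{path}: degenerate distribution (all-zero density)")
    steps = np.diff(r)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError(f"{path}: grid must be strictly increasing and uniform")
    ci_lo = df["ci_lower"].to_numpy(dtype=float) if "ci_lower" in df.columns else None
    ci_hi = df["ci_upper"].to_numpy(dtype=float) if "ci_upper" in df.columns else None
    return DistanceDistribution(r, p, ci_lo, ci_hi)


def write_distance_distribution(path, dist: DistanceDistribution) -> None:
    data = {"r_angstrom": dist.grid, "p": dist.density}
    if dist.ci_lower is not None:
        data["ci_lower"] = dist.ci_lower
    if dist.ci_upper is not None:
        data["ci_upper"] = dist.ci_upper
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_pre_table(path) -> PRETable:
    """Read a TSV PRE table (residue, gamma2, gamma2_err, status)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("residue", "gamma2", "gamma2_err", "status"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad = set(df["status"]) - _PRE_STATUSES
    if bad:
        raise ValueError(f"{path}: unknown PRE status values {sorted(bad)}")
    return PRETable(
        df["residue"].to_numpy(dtype=int),
        df["gamma2"].to_numpy(dtype=float),
        df["gamma2_err"].to_numpy(dtype=float),
        df["status"].to_numpy(dtype=object),
    )


def write_pre_table(path, table: PRETable) -> None:
    pd.DataFrame(
        {
            "residue": table.residues,
            "gamma2": table.gamma2,
            "gamma2_err": table.gamma2_err,
            "status": table.status,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


_NH_BOND = 1.01  # Å


def reconstruct_amide_protons(conformer: Conformer) -> Conformer:
    """Add backbone amide protons from N, CA, and the previous residue's C.

    The proton is placed in the peptide plane along the negative bisector of
    the unit vectors N→CA and N→C(prev) at an N-H bond length of 1.01 Å.
    Residues that already carry an H, prolines, chain-first residues, and
    residues with (near-)collinear N/CA/C(prev) are skipped; the last case
    with a warning.  Atom ordering of existing atoms is preserved; protons
    are appended per residue directly after the backbone N.
    """
    if np.any(conformer.names == "H"):
        return conformer
    insertions: list[tuple[int, np.ndarray, int, str, str]] = []
    resids = np.unique(conformer.residue_ids)
    for rid in resids:
        sel = conformer.residue_ids == rid
        resname = str(conformer.residue_names[sel][0])
        if resname == "PRO":
            continue
        i_n = conformer.atom_index(rid, "N")
        i_ca = conformer.atom_index(rid, "CA")
        i_cprev = conformer.atom_index(rid - 1, "C")
        if i_n is None or i_ca is None or i_cprev is None:
            continue
        n = conformer.coords[i_n]
        v1 = conformer.coords[i_ca] - n
        v2 = conformer.coords[i_cprev] - n
        v1 = v1 / np.linalg.norm(v1)
        v2 = v2 / np.linalg.norm(v2)
        bisector = v1 + v2
        norm = np.linalg.norm(bisector)
        if norm < 1e-6:
            warnings.warn(
                f"residue {rid}: collinear N/CA/C(prev), amide proton skipped",
                stacklevel=2,
            )
            continue
        h = n - _NH_BOND * bisector / norm
        chain = str(conformer.chain_ids[i_n])
        insertions.append((i_n, h, rid, chain, resname))
    if not insertions:
        return conformer
    names = list(conformer.names)
    resids_l = list(conformer.residue_ids)
    chains = list(conformer.chain_ids)
    elements = list(conformer.elements)
    resnames = list(conformer.residue_names)
    coords = list(conformer.coords)
    for i_n, h, rid, chain, resname in sorted(insertions, reverse=True):
        names.insert(i_n + 1, "H")
        resids_l.insert(i_n + 1, rid)
        chains.insert(i_n + 1, chain)
        elements.insert(i_n + 1, "H")
        resnames.insert(i_n + 1, resname)
        coords.insert(i_n + 1, h)
    return Conformer(
        np.array(names, dtype=object),
        np.array(resids_l, dtype=int),
        np.array(chains, dtype=object),
        np.array(elements, dtype=object),
        np.array(coords, dtype=float),
        np.array(resnames, dtype=object),
    )


@dataclass
class RestraintManifest:
    """Validated description of a restraint set on disk.

    ``deer`` maps a site pair (tuple of site ids) to a parsed distance
    distribution; ``pre`` maps a label-site id to a parsed PRE table.
    Scalars are stored in SI units (τc in s, ωH in rad/s).
    """

    path: Path
    sites: dict[str, int]
    deer: dict[tuple[str, str], DistanceDistribution]
    pre: dict[str, PRETable]
    tau_c: float | None
    tau_c_err: float
    nu_h_hz: float | None
    gamma2_cap: float
    grid: np.ndarray
    kernel_sigma: float
    seed: int
    sha256: str

    @property
    def omega_h(self) -> float:
        if self.nu_h_hz is None:
            raise ValueError("manifest defines no 1H frequency")
        return 2.0 * np.pi * self.nu_h_hz

    @property
    def n_restraints(self) -> int:
        return len(self.deer) + len(self.pre)


def load_manifest(path) -> RestraintManifest:
    """Load and fully validate a YAML restraint manifest.

    Every referenced file must exist and parse; site ids referenced by deer
    and PRE entries must exist in the site registry; τc and the ¹H frequency
    are mandatory as soon as PRE entries are present.  Paths are resolved
    relative to the manifest file.
    """
    path = Path(path)
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    cfg = yaml.safe_load(raw)
    base = path.parent
    sites = {str(k): int(v["residue"]) if isinstance(v, dict) else int(v)
             for k, v in (cfg.get("sites") or {}).items()}
    scalars = cfg.get("scalars") or {}
    options = cfg.get("options") or {}

    deer: dict[tuple[str, str], DistanceDistribution] = {}
    for entry in cfg.get("deer") or []:
        a, b = entry["sites"]
        for s in (a, b):
            if s not in sites:
                raise ValueError(f"{path}: deer entry references unknown site {s!r}")
        fpath = base / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"{path}: missing distribution file {fpath}")
        deer[(str(a), str(b))] = read_distance_distribution(fpath)

    pre: dict[str, PRETable] = {}
    for entry in cfg.get("pre") or []:
        s = str(entry["site"])
        if s not in sites:
            raise ValueError(f"{path}: pre entry references unknown site {s!r}")
        fpath = base / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"{path}: missing PRE table {fpath}")
        pre[s] = read_pre_table(fpath)

    tau_c = scalars.get("tau_c_ns")
    tau_c = float(tau_c) * 1e-9 if tau_c is not None else None
    tau_c_err = float(scalars.get("tau_c_err_ns", 0.0)) * 1e-9
    nu_h = scalars.get("h_frequency_mhz")
    nu_h_hz = float(nu_h) * 1e6 if nu_h is not None else None
    if pre and (tau_c is None or nu_h_hz is None):
        raise ValueError(
            f"{path}: PRE entries require scalars tau_c_ns and h_frequency_mhz"
        )
    gmin = float(options.get("grid_min", 10.0))
    gmax = float(options.get("grid_max", 100.0))
    gstep = float(options.get("grid_step", 0.5))
    grid = np.arange(gmin, gmax + 0.5 * gstep, gstep)
    manifest = RestraintManifest(
        path=path,
        sites=sites,
        deer=deer,
        pre=pre,
        tau_c=tau_c,
        tau_c_err=tau_c_err,
        nu_h_hz=nu_h_hz,
        gamma2_cap=float(scalars.get("gamma2_cap", 170.0)),
        grid=grid,
        kernel_sigma=float(options.get("kernel_sigma", 1.0)),
        seed=int(options.get("seed", 0)),
        sha256=digest,
    )
    logger.info(
        "loaded manifest %s (sha256 %s): %d deer + %d pre entries, seed %d",
        path, digest[:12], len(deer), len(pre), manifest.seed,
    )
    return manifest
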