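"""r⁻⁶ multi-state modelling of dynamically averaged PRE restraints.

When a flexible protein interconverts between conformations during a PRE
measurement, the observed rate reflects an average dominated by the
shortest distances.  Instead of fitting one conformer, a multi-state model
optimizes N rigid copies of the system jointly; each restraint is satisfied
by the effective averaged distance

    D*_ab = ( Σ_i (d_ab^i)^-6 )^(-1/6)

over the N states, so a single state with a sufficiently short distance can
satisfy a strong-PRE restraint even when the other states do not.  All
states are assumed to have equal population.

The system is a two-domain topology: domain 1 is fixed in the laboratory
frame, domain 2 undergoes one rigid-body transform per state, and the
flexible linker only enters as a closure constraint (the anchor-to-anchor
gap cannot exceed the linker's contour length).  Spin-label positions are
represented by their cloud centres, fixed in the frame of the host domain.
A simulated-annealing search over all state transforms minimizes the
quadratic restraint-violation score, followed by a derivative-free local
polish.  States whose anchor gap approaches the contour length are flagged
as elongated; elongated states indicate that more states were requested
than the restraints support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from flexens.io_formats import ConformerEnsemble
from flexens.nmr import PREDistanceRestraint

__all__ = [
    "RigidTopology",
    "AnnealSchedule",
    "MultiStateModel",
    "effective_distance",
    "violation_score",
    "anneal_states",
    "scan_num_states",
    "split_states",
]


def effective_distance(distances) -> float:
    """(Σ d_i⁻⁶)^(-1/6): the r⁻⁶ state-averaged effective distance in Å.

    Permutation-invariant; bounded above by the shortest distance, with
    equality only for a single state.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("at least one distance is required")
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    return float(np.sum(d**-6.0) ** (-1.0 / 6.0))


@dataclass
class RigidTopology:
    """Two rigid Cα domains joined by a flexible linker of known length.

    Domain 1 coordinates are in the (fixed) laboratory frame; domain 2
    coordinates are in its own local frame and are placed per state by a
    rigid-body transform.  Label-site centres are given in the frame of the
    domain hosting the site.
    """

    domain1_ca: np.ndarray
    domain2_ca: np.ndarray
    domain1_residues: np.ndarray
    domain2_residues: np.ndarray
    linker_length: int
    bond_length: float = 3.8
    anchor1_index: int = -1   # into domain1_ca (linker start side)
    anchor2_index: int = 0    # into domain2_ca (linker end side)
    labels1: dict[str, np.ndarray] = field(default_factory=dict)
    labels2: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.domain1_ca = np.asarray(self.domain1_ca, dtype=float)
        self.domain2_ca = np.asarray(self.domain2_ca, dtype=float)
        self.domain1_residues = np.asarray(self.domain1_residues, dtype=int)
        self.domain2_residues = np.asarray(self.domain2_residues, dtype=int)
        if self.linker_length < 1:
            raise ValueError("linker must contain at least one residue")

    @property
    def closure_bound(self) -> float:
        """Maximum anchor-to-anchor gap: (n_linker + 1) virtual bonds."""
        return (self.linker_length + 1) * self.bond_length

    def resolve_restraint(self, r: PREDistanceRestraint):
        """Map a restraint to (fixed_point|None, moving_local|None) endpoints.

        The label endpoint is the site's cloud centre; the target endpoint
        is the residue's Cα.  Returns (fixed, moving) where ``fixed`` is in
        the laboratory frame (domain 1) and ``moving`` in domain 2's local
        frame; one of the two may be None for same-frame restraints.
        """
        if r.site in self.labels1:
            label, label_frame = self.labels1[r.site], 1
        elif r.site in self.labels2:
            label, label_frame = self.labels2[r.site], 2
        else:
            raise KeyError(f"unknown label site {r.site!r}")
        if r.residue in self.domain1_residues:
            i = int(np.flatnonzero(self.domain1_residues == r.residue)[0])
            target, target_frame = self.domain1_ca[i], 1
        elif r.residue in self.domain2_residues:
            i = int(np.flatnonzero(self.domain2_residues == r.residue)[0])
            target, target_frame = self.domain2_ca[i], 2
        else:
            raise KeyError(
                f"restraint target residue {r.residue} is not in a rigid domain"
            )
        if label_frame == target_frame:
            return None, None, float(np.linalg.norm(label - target))
        fixed = label if label_frame == 1 else target
        moving = target if label_frame == 1 else label
        return fixed, moving, None


@dataclass
class AnnealSchedule:
    """Geometric-cooling schedule for the multi-state annealer.

    ``jump_probability`` is the chance per step of re-placing one state
    entirely (a basin-hopping move that escapes local minima of the
    strongly multi-modal violation landscape); ``n_starts`` independent
    annealing cycles are run with derived seeds and the best result kept.
    """

    steps: int = 10_000
    t_start: float = 1.0
    t_end: float = 0.01
    max_rotation_deg: float = 15.0
    max_translation: float = 2.0
    jump_probability: float = 0.03
    n_starts: int = 3
    polish: bool = True


@dataclass
class MultiStateModel:
    """N jointly optimized states with their effective distances and score."""

    topology: RigidTopology
    n_states: int
    params: np.ndarray              # (N, 6): rotation vector + translation
    effective_distances: np.ndarray
    score: float
    elongated: np.ndarray           # per-state flags
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def state_coords(self, i: int) -> np.ndarray:
        """Cα coordinates of state i: fixed domain 1 + transformed domain 2."""
        rot = Rotation.from_rotvec(self.params[i, :3])
        d2 = rot.apply(self.topology.domain2_ca) + self.params[i, 3:]
        return np.concatenate([self.topology.domain1_ca, d2])


class _Engine:
    """Vectorized score evaluation for a fixed restraint set."""

    def __init__(self, topology: RigidTopology, restraints):
        self.topology = topology
        self.fixed, self.moving = [], []
        self.upl, self.lol = [], []
        self.const_d = []
        self.const_upl, self.const_lol = [], []
        for r in restraints:
            fixed, moving, const = topology.resolve_restraint(r)
            upl = r.upl
            lol = r.lol if r.kind == "two_sided" else -np.inf
            if const is not None:
                self.const_d.append(const)
                self.const_upl.append(upl)
                self.const_lol.append(lol)
            else:
                self.fixed.append(fixed)
                self.moving.append(moving)
                self.upl.append(upl)
                self.lol.append(lol)
        self.fixed = np.array(self.fixed).reshape(-1, 3)
        self.moving = np.array(self.moving).reshape(-1, 3)
        self.upl = np.array(self.upl)
        self.lol = np.array(self.lol)
        self.anchor1 = topology.domain1_ca[topology.anchor1_index]
        self.anchor2_local = topology.domain2_ca[topology.anchor2_index]

    def distances(self, params: np.ndarray) -> np.ndarray:
        """(R, N) distances of the cross-frame restraints for all states."""
        n = params.shape[0]
        out = np.empty((self.fixed.shape[0], n))
        for i in range(n):
            rot = Rotation.from_rotvec(params[i, :3])
            moved = rot.apply(self.moving) + params[i, 3:]
            out[:, i] = np.linalg.norm(moved - self.fixed, axis=1)
        return out

    def effective(self, dists: np.ndarray) -> np.ndarray:
        return np.sum(dists**-6.0, axis=1) ** (-1.0 / 6.0)

    def score_from_dists(self, dists: np.ndarray) -> float:
        score = 0.0
        if dists.size:
            d_eff = self.effective(dists)
            v = np.maximum(d_eff - self.upl, 0.0) + np.maximum(self.lol - d_eff, 0.0)
            score += float(np.sum(v**2))
        for d, upl, lol in zip(self.const_d, self.const_upl, self.const_lol):
            v = max(d - upl, 0.0) + max(lol - d, 0.0)
            score += v * v
        return score

    def gaps(self, params: np.ndarray) -> np.ndarray:
        n = params.shape[0]
        out = np.empty(n)
        for i in range(n):
            rot = Rotation.from_rotvec(params[i, :3])
            a2 = rot.apply(self.anchor2_local) + params[i, 3:]
            out[i] = np.linalg.norm(a2 - self.anchor1)
        return out

    def score(self, params: np.ndarray) -> float:
        return self.score_from_dists(self.distances(params))

    def penalized(self, flat: np.ndarray, n: int) -> float:
        params = flat.reshape(n, 6)
        bound = self.topology.closure_bound
        over = np.maximum(self.gaps(params) - bound, 0.0)
        return self.score(params) + 100.0 * float(np.sum(over**2))


def violation_score(model: MultiStateModel, restraints) -> tuple[float, np.ndarray]:
    """Σ v² over restraints, with v = max(0, D*−upl) + max(0, lol−D*).

    Returns the total score and the per-restraint violations, recomputed
    from the model's coordinates.
    """
    engine = _Engine(model.topology, restraints)
    dists = engine.distances(model.params)
    viol = []
    i_cross = 0
    i_const = 0
    for r in restraints:
        _, _, const = model.topology.resolve_restraint(r)
        if const is not None:
            d_eff = effective_distance([const] * model.n_states)
            i_const += 1
        else:
            d_eff = effective_distance(dists[i_cross])
            i_cross += 1
        lol = r.lol if r.kind == "two_sided" else -np.inf
        viol.append(max(d_eff - r.upl, 0.0) + max(lol - d_eff, 0.0))
    viol = np.array(viol)
    return float(np.sum(viol**2)), viol


def _anneal_once(
    engine: _Engine,
    n_states: int,
    schedule: AnnealSchedule,
    rng: np.random.Generator,
):
    """One annealing cycle; returns (best params, best score, trace)."""
    bound = engine.topology.closure_bound
    params = np.stack([_random_state(engine, rng) for _ in range(n_states)])
    dists = engine.distances(params)
    current = engine.score_from_dists(dists)
    best_params, best_score = params.copy(), current
    trace = [current]
    cooling = (schedule.t_end / schedule.t_start) ** (1.0 / max(schedule.steps - 1, 1))
    temp = schedule.t_start
    max_rot = np.deg2rad(schedule.max_rotation_deg)
    for _ in range(schedule.steps):
        i = int(rng.integers(n_states))
        proposal = params[i].copy()
        u = rng.random()
        if u < schedule.jump_probability:
            proposal = _random_state(engine, rng)
        elif u < 0.5 + 0.5 * schedule.jump_probability:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(-max_rot, max_rot)
            delta = Rotation.from_rotvec(angle * axis)
            rot_old = Rotation.from_rotvec(proposal[:3])
            rot_new = delta * rot_old
            # rotate about the state's linker-anchor position to keep closure
            pivot = rot_old.apply(engine.anchor2_local) + proposal[3:]
            proposal[:3] = rot_new.as_rotvec()
            proposal[3:] = pivot - rot_new.apply(engine.anchor2_local)
        else:
            proposal[3:] = proposal[3:] + rng.uniform(
                -schedule.max_translation, schedule.max_translation, size=3
            )
        trial = params.copy()
        trial[i] = proposal
        gap = engine.gaps(trial[i : i + 1])[0]
        if gap > bound:
            trace.append(best_score)
            temp *= cooling
            continue
        new_dists = dists.copy()
        new_dists[:, i] = engine.distances(trial[i : i + 1])[:, 0]
        new_score = engine.score_from_dists(new_dists)
        if new_score <= current or rng.random() < np.exp(
            -(new_score - current) / max(temp, 1e-12)
        ):
            params, dists, current = trial, new_dists, new_score
            if current < best_score:
                best_params, best_score = params.copy(), current
        trace.append(best_score)
        temp *= cooling
    return best_params, best_score, trace


def _random_state(engine: _Engine, rng: np.random.Generator) -> np.ndarray:
    """One feasible state: domain 2 placed with its anchor inside the
    closure sphere around domain 1's anchor."""
    quat = rng.normal(size=4)
    rot = Rotation.from_quat(quat / np.linalg.norm(quat))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = rng.uniform(0.1, 0.7) * engine.topology.closure_bound
    anchor_target = engine.anchor1 + radius * direction
    t = anchor_target - rot.apply(engine.anchor2_local)
    return np.concatenate([rot.as_rotvec(), t])


def anneal_states(
    topology: RigidTopology,
    n_states: int,
    restraints,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
) -> MultiStateModel:
    """Joint simulated annealing of N rigid-body states against restraints.

    Proposals rotate (≤ max_rotation about the linker anchor, which keeps
    closure intact) or translate (≤ max_translation) one state's domain 2;
    proposals breaking linker closure are rejected.  Geometric cooling from
    t_start to t_end; the best-so-far model is tracked and returned, after
    an optional derivative-free polish with a quadratic closure penalty.
    Deterministic for fixed inputs and seed.
    """
    if n_states < 1:
        raise ValueError("need at least one state")
    if not restraints:
        raise ValueError("restraints must be non-empty")
    schedule = schedule or AnnealSchedule()
    engine = _Engine(topology, restraints)
    bound = topology.closure_bound
    best_params, best_score, trace = None, np.inf, []
    for start in range(schedule.n_starts):
        rng = np.random.default_rng([seed, start])
        params, score, tr = _anneal_once(engine, n_states, schedule, rng)
        if score < best_score:
            best_params, best_score, trace = params, score, tr
    if schedule.polish:
        res = minimize(
            engine.penalized, best_params.ravel(), args=(n_states,),
            method="Powell",
            options={"maxiter": 100, "maxfev": 40_000, "xtol": 1e-8, "ftol": 1e-12},
        )
        cand = res.x.reshape(n_states, 6)
        if (
            engine.score(cand) < best_score
            and np.all(engine.gaps(cand) <= bound + 1e-9)
        ):
            best_params = cand
            best_score = engine.score(cand)
            trace.append(best_score)
    final_dists = engine.distances(best_params)
    d_eff = engine.effective(final_dists) if final_dists.size else np.empty(0)
    gaps = engine.gaps(best_params)
    return MultiStateModel(
        topology=topology,
        n_states=n_states,
        params=best_params,
        effective_distances=d_eff,
        score=best_score,
        elongated=gaps > 0.8 * bound,
        trace=np.array(trace),
    )


def scan_num_states(
    topology: RigidTopology,
    restraints,
    n_range=range(1, 11),
    repeats: int = 3,
    seed: int = 0,
    schedule: AnnealSchedule | None = None,
    violation_tol: float = 0.1,
) -> tuple[pd.DataFrame, int]:
    """Scan the number of states and select the smallest adequate N.

    For each N the annealer runs ``repeats`` times with derived seeds; the
    best score, violated-restraint count, and elongated-state count are
    tabulated.  The selected N is the smallest whose best score lies within
    5% of the overall minimum (plus a small absolute slack for near-zero
    scores) and whose best run has no elongated states.
    """
    rows = []
    best_models = {}
    for n in n_range:
        best = None
        for rep in range(repeats):
            run_seed = (seed * 10_000 + n * 100 + rep) % (2**31)
            model = anneal_states(topology, n, restraints, schedule, run_seed)
            if best is None or model.score < best.score:
                best = model
        _, viol = violation_score(best, restraints)
        best_models[n] = best
        rows.append(
            {
                "n_states": n,
                "best_score": best.score,
                "violations": int(np.sum(viol > violation_tol)),
                "elongated": int(np.sum(best.elongated)),
            }
        )
    df = pd.DataFrame(rows)
    overall = df["best_score"].min()
    ok = (df["best_score"] <= 1.05 * overall + 1e-6) & (df["elongated"] == 0)
    if not ok.any():
        ok = df["best_score"] <= 1.05 * overall + 1e-6
    selected = int(df.loc[ok, "n_states"].min())
    return df, selected


def restraints_from_states(
    topology: RigidTopology,
    params: np.ndarray,
    targets_per_domain: int = 5,
) -> list[PREDistanceRestraint]:
    """Tight restraints implied by a known multi-state arrangement.

    For every cross-frame (label, target-residue) combination the r⁻⁶
    effective distance over the given states becomes a zero-width two-sided
    restraint (upl = lol = D*).  Used to plant recoverable problems for the
    annealer; the planted arrangement satisfies them with zero score.
    """
    params = np.asarray(params, dtype=float)
    restraints: list[PREDistanceRestraint] = []
    pick1 = np.linspace(0, topology.domain1_residues.size - 1, targets_per_domain).astype(int)
    pick2 = np.linspace(0, topology.domain2_residues.size - 1, targets_per_domain).astype(int)
    candidates = [
        (site, int(topology.domain2_residues[i]))
        for site in topology.labels1 for i in pick2
    ] + [
        (site, int(topology.domain1_residues[i]))
        for site in topology.labels2 for i in pick1
    ]
    for site, residue in candidates:
        probe = PREDistanceRestraint(site, residue, 1.0, 1.0, None, "upper_only")
        engine = _Engine(topology, [probe])
        d_eff = float(engine.effective(engine.distances(params))[0])
        restraints.append(
            PREDistanceRestraint(site, residue, d_eff, d_eff, d_eff, "two_sided")
        )
    return restraints


def split_states(runs, keep: int) -> ConformerEnsemble:
    """Split multi-state runs into independent equal-weight conformers.

    Keeps the ``keep`` best-scoring runs; each run's N states become N
    conformers (linker removed — only the two rigid domains remain), giving
    an ensemble of keep × N conformers with uniform weights 1/(keep·N).
    """
    runs = list(runs)
    if keep > len(runs):
        raise ValueError(f"cannot keep {keep} of {len(runs)} runs")
    if len({m.n_states for m in runs}) != 1:
        raise ValueError("all runs must share the same number of states")
    kept = sorted(runs, key=lambda m: m.score)[:keep]
    topo = kept[0].topology
    n1, n2 = topo.domain1_ca.shape[0], topo.domain2_ca.shape[0]
    residue_ids = np.concatenate([topo.domain1_residues, topo.domain2_residues])
    coords, provenance = [], []
    for run_i, model in enumerate(kept):
        for s in range(model.n_states):
            coords.append(model.state_coords(s))
            provenance.append(f"run{run_i + 1}:state{s + 1}")
    names = np.full(n1 + n2, "CA", dtype=object)
    return ConformerEnsemble(
        names,
        residue_ids,
        np.full(n1 + n2, "A", dtype=object),
        np.full(n1 + n2, "C", dtype=object),
        np.stack(coords),
        None,
        provenance,
    )
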