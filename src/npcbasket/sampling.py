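"""Replica-exchange Gibbs Monte Carlo over rigid bodies and flexible beads.

Each MC step is a Gibbs sweep: one Metropolis proposal per movable rigid
body (random rotation about its centroid plus random translation) and one
per flexible bead (random translation), each accepted with probability
``min(1, exp(-dE / T))``.  Parallel replicas at a geometric temperature
ladder exchange configurations at fixed intervals with the standard
replica-exchange acceptance ``min(1, exp((b_i - b_j)(E_i - E_j)))``.

Move magnitudes are annealed with replica temperature (multiplied by
sqrt(T)) so hot replicas explore and the cold replica refines.  The fixed
scaffold never moves.  Everything is deterministic in the run seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import AssemblyState, random_rotation_matrix
from .restraints import ScoringFunction

__all__ = [
    "MoveSet",
    "ReplicaConfig",
    "ModelEnsemble",
    "metropolis_accept",
    "randomize_initial",
    "mc_step",
    "replica_exchange",
    "run_sampling",
]


@dataclass(frozen=True)
class MoveSet:
    """Maximum proposal magnitudes (uniform in [-max, max] per component)."""

    rb_max_rotation: float = 8.0      # deg, about the body centroid
    rb_max_translation: float = 4.0   # A
    bead_max_translation: float = 4.0  # A

    def __post_init__(self):
        if min(self.rb_max_rotation, self.rb_max_translation, self.bead_max_translation) < 0:
            raise ValueError("move magnitudes must be >= 0")

    def scaled(self, factor: float) -> "MoveSet":
        return MoveSet(
            self.rb_max_rotation * factor,
            self.rb_max_translation * factor,
            self.bead_max_translation * factor,
        )


@dataclass(frozen=True)
class ReplicaConfig:
    """Replica-exchange run parameters."""

    n_replicas: int = 4
    temperature_ladder: tuple[float, ...] | None = None  # geometric 1..2.5 if None
    t_min: float = 1.0
    t_max: float = 2.5
    swap_interval: int = 10
    n_steps: int = 5000
    n_independent_runs: int = 2
    save_interval: int = 25
    seed: int = 0
    moves: MoveSet = field(default_factory=MoveSet)

    def ladder(self) -> np.ndarray:
        if self.temperature_ladder is not None:
            lad = np.asarray(self.temperature_ladder, dtype=float)
            if len(lad) != self.n_replicas:
                raise ValueError("ladder length must equal n_replicas")
            if np.any(np.diff(lad) <= 0) or np.any(lad <= 0):
                raise ValueError("ladder must be strictly ascending and positive")
            return lad
        if self.n_replicas == 1:
            return np.array([self.t_min])
        return np.geomspace(self.t_min, self.t_max, self.n_replicas)


def metropolis_accept(delta_e, temperature: float, rng: np.random.Generator):
    """Metropolis rule: accept with probability min(1, exp(-dE/T)).

    Accepts scalars or arrays of energy differences.
    """
    delta_e = np.asarray(delta_e, dtype=float)
    with np.errstate(over="ignore"):
        p = np.exp(np.minimum(0.0, -delta_e / temperature))
    u = rng.uniform(size=delta_e.shape) if delta_e.shape else rng.uniform()
    return u < p


def randomize_initial(
    state: AssemblyState,
    region: tuple[np.ndarray, np.ndarray],
    seed: int | np.random.Generator = 0,
) -> AssemblyState:
    """Place movable bodies and flexible beads uniformly in a box region.

    ``region`` is (lower, upper) corner of an axis-aligned box that must
    enclose the scaffold neighborhood.  Rigid bodies get a uniform random
    orientation and a uniform centroid position; flexible beads are placed
    independently.  Fixed bodies are untouched.  Deterministic in ``seed``.
    """
    lo = np.asarray(region[0], dtype=float)
    hi = np.asarray(region[1], dtype=float)
    if np.any(hi - lo <= 0):
        raise ValueError("region must have positive extent on every axis")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = state.copy()
    out.coords = state.coords.copy()
    for rb in state.movable_bodies():
        idx = rb.bead_idx
        centroid = state.coords[idx].mean(axis=0)
        rot = random_rotation_matrix(rng)
        new_centroid = rng.uniform(lo, hi)
        out.coords[idx] = (state.coords[idx] - centroid) @ rot.T + new_centroid
    flex = state.flexible_idx()
    if len(flex):
        out.coords[flex] = rng.uniform(lo, hi, size=(len(flex), 3))
    return out


def _propose_body(coords, idx, moves: MoveSet, rng) -> np.ndarray:
    old = coords[idx].copy()
    centroid = old.mean(axis=0)
    rot = random_rotation_matrix(rng, np.deg2rad(moves.rb_max_rotation))
    shift = rng.uniform(-moves.rb_max_translation, moves.rb_max_translation, size=3)
    coords[idx] = (old - centroid) @ rot.T + centroid + shift
    return old


def mc_step(
    scorer: ScoringFunction,
    state: AssemblyState,
    moveset: MoveSet,
    temperature: float,
    rng: np.random.Generator,
    energy: float | None = None,
):
    """One Gibbs sweep over all movable degrees of freedom (in place).

    Returns ``(energy_after, accepted_flags)``; ``state.coords`` is updated
    in place.  Fixed bodies are never proposed.
    """
    coords = state.coords
    e = scorer.energy(coords) if energy is None else energy
    accepted = []
    for rb in state.movable_bodies():
        old = _propose_body(coords, rb.bead_idx, moveset, rng)
        e_new = scorer.energy(coords)
        if metropolis_accept(e_new - e, temperature, rng):
            e = e_new
            accepted.append(True)
        else:
            coords[rb.bead_idx] = old
            accepted.append(False)
    for bead in state.flexible_idx():
        old = coords[bead].copy()
        coords[bead] = old + rng.uniform(
            -moveset.bead_max_translation, moveset.bead_max_translation, size=3
        )
        e_new = scorer.energy(coords)
        if metropolis_accept(e_new - e, temperature, rng):
            e = e_new
            accepted.append(True)
        else:
            coords[bead] = old
            accepted.append(False)
    return e, np.asarray(accepted, dtype=bool)


def replica_exchange(replicas: list[tuple], rng: np.random.Generator) -> list[tuple]:
    """Attempt adjacent-pair swaps on ``[(coords, temperature, energy), ...]``.

    Swaps exchange configurations (and their energies) between temperature
    slots; the multiset of configurations is preserved.  Alternating parity
    is chosen at random each call.
    """
    if len(replicas) < 2:
        raise ValueError("replica exchange needs at least 2 replicas")
    out = list(replicas)
    # random parity interleaves the two pairings; with a single adjacent
    # pair there is nothing to interleave
    start = int(rng.integers(0, 2)) if len(out) > 2 else 0
    for i in range(start, len(out) - 1, 2):
        (xi, ti, ei), (xj, tj, ej) = out[i], out[i + 1]
        beta_i, beta_j = 1.0 / ti, 1.0 / tj
        log_p = (beta_i - beta_j) * (ei - ej)
        if np.log(rng.uniform()) < min(0.0, log_p) or log_p >= 0:
            out[i], out[i + 1] = (xj, ti, ej), (xi, tj, ei)
    return out


@dataclass
class ModelEnsemble:
    """Sampled states (lowest-temperature replica) with provenance."""

    topology: AssemblyState            # template; per-frame coords below
    frames: np.ndarray                 # (n_frames, n_beads, 3)
    scores: np.ndarray                 # (n_frames,)
    breakdowns: pd.DataFrame           # weighted per-term scores per frame
    provenance: pd.DataFrame           # columns: run, replica, step

    def __len__(self) -> int:
        return len(self.frames)

    def state(self, i: int) -> AssemblyState:
        st = self.topology.copy()
        st.coords = self.frames[i].copy()
        return st

    def subset(self, idx) -> "ModelEnsemble":
        idx = np.asarray(idx)
        return ModelEnsemble(
            self.topology,
            self.frames[idx],
            self.scores[idx],
            self.breakdowns.iloc[idx].reset_index(drop=True),
            self.provenance.iloc[idx].reset_index(drop=True),
        )

    def best_index(self) -> int:
        return int(np.argmin(self.scores))


def run_sampling(
    state: AssemblyState,
    scorer: ScoringFunction,
    config: ReplicaConfig,
    region: tuple | None = None,
) -> ModelEnsemble:
    """Full replica-exchange run(s) from randomized initial configurations.

    Executes ``n_independent_runs`` runs with seeds spawned from
    ``config.seed`` and returns all saved lowest-temperature frames with
    scores, per-term breakdowns, and (run, replica, step) provenance.
    """
    if region is None:
        span = np.abs(state.coords).max() * 1.2 + 100.0
        region = (np.array([-span, -span, -span]), np.array([span, span, span]))
    ladder = config.ladder()
    fixed_before = state.coords[state.fixed_bead_idx()].copy()

    frames, scores, rows, prov = [], [], [], []
    run_seeds = np.random.SeedSequence(config.seed).spawn(config.n_independent_runs)
    for run, seq in enumerate(run_seeds):
        rng = np.random.default_rng(seq)
        reps = []
        for t in ladder:
            st = randomize_initial(state, region, rng)
            reps.append([st, t, scorer.energy(st.coords)])
        movesets = [config.moves.scaled(np.sqrt(t)) for t in ladder]
        for step in range(1, config.n_steps + 1):
            for r, (st, t, e) in enumerate(reps):
                e_new, _ = mc_step(scorer, st, movesets[r], t, rng, energy=e)
                reps[r][2] = e_new
            if config.n_replicas > 1 and step % config.swap_interval == 0:
                packed = [(st.coords, t, e) for st, t, e in reps]
                packed = replica_exchange(packed, rng)
                for r, (coords, t, e) in enumerate(packed):
                    reps[r][0].coords = coords
                    reps[r][1] = t
                    reps[r][2] = e
            if step % config.save_interval == 0:
                st, _, e = reps[0]
                frames.append(st.coords.copy())
                scores.append(e)
                _, terms, info = scorer.breakdown(st.coords)
                rows.append({**terms, **info})
                prov.append({"run": run, "replica": 0, "step": step})

    fixed_after = state.coords[state.fixed_bead_idx()]
    if not np.array_equal(fixed_before, fixed_after):
        raise AssertionError("fixed scaffold moved during sampling")
    return ModelEnsemble(
        topology=state,
        frames=np.asarray(frames),
        scores=np.asarray(scores),
        breakdowns=pd.DataFrame(rows),
        provenance=pd.DataFrame(prov),
    )
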