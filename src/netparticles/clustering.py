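"""Adaptive centroid-seed extraction of clusters from an equilibrium state.

A K-means-like loop in which K adapts: seeds start at the positions of two
randomly chosen particles, every particle joins its nearest seed, each seed
carries the mean squared distance E_k of its members, seeds with at most one
member are removed (they are isolated in particle space), seeds whose error
exceeds theta_s spawn a new seed at the offending cluster's farthest member,
and surviving seeds move to their members' centroid.  The loop stops when
the mean seed error changes by less than theta_c between rounds and no seed
was added or removed in the round.

The number of rounds needed grows roughly linearly with the number of
clusters found, since each round can add at most one seed per overloaded
cluster and well-separated clusters stabilize immediately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from netparticles.dynamics import ParticleState


@dataclass
class SeedSet:
    """Seed positions s_k, particle assignments, per-seed errors E_k."""

    positions: np.ndarray  # S x D
    assignments: np.ndarray  # N, values in 0..S-1
    errors: np.ndarray  # S
    iteration: int = 0

    @property
    def n_seeds(self) -> int:
        return self.positions.shape[0]

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == k)


def assign_particles(state: ParticleState, seed_positions: np.ndarray) -> np.ndarray:
    """Map each particle to its nearest seed (ties -> lowest seed index)."""
    if seed_positions.shape[0] < 1:
        raise ValueError("need at least one seed")
    d = cdist(state.positions, seed_positions)
    return np.argmin(d, axis=1)  # argmin takes the first minimum on ties


def seed_error(state: ParticleState, assignments: np.ndarray, seed_pos: np.ndarray, k: int) -> float:
    """E_k: mean squared distance of seed k's members to s_k (0 if empty)."""
    members = np.flatnonzero(assignments == k)
    if members.size == 0:
        return 0.0
    diffs = state.positions[members] - seed_pos[k]
    return float(np.einsum("ij,ij->", diffs, diffs) / members.size)


def _all_errors(state: ParticleState, assignments: np.ndarray, seed_pos: np.ndarray) -> np.ndarray:
    return np.array(
        [seed_error(state, assignments, seed_pos, k) for k in range(seed_pos.shape[0])]
    )


def update_seed_positions(state: ParticleState, assignments: np.ndarray, seed_pos: np.ndarray) -> np.ndarray:
    """Move each seed to the centroid of its members; empty seeds stay put."""
    new_pos = seed_pos.copy()
    for k in range(seed_pos.shape[0]):
        members = np.flatnonzero(assignments == k)
        if members.size:
            new_pos[k] = state.positions[members].mean(axis=0)
    return new_pos


def adapt_seeds(
    state: ParticleState, seeds: SeedSet, theta_s: float = 0.5
) -> tuple[SeedSet, bool]:
    """Remove seeds with <= 1 member; merge coincident seeds; split seeds
    with E_k > theta_s.

    theta_s bounds the heterogeneity allowed in one cluster: a cluster whose
    error exceeds theta_s spawns a new seed at its farthest member
    (deterministically separating heterogeneous clusters), and two seeds
    closer together than the cluster radius theta_s implies
    (||s_k - s_l||^2 <= theta_s) are collapsed onto one — both would fit
    inside a single admissible cluster, and without this rule two seeds can
    stably over-partition one tight particle cloud while neither the
    singleton-removal nor the split rule ever fires.  After any change the
    particles are reassigned.  Returns the updated set and whether the seed
    topology changed.
    """
    keep = [k for k in range(seeds.n_seeds) if seeds.members(k).size > 1]
    changed = len(keep) != seeds.n_seeds

    # merge greedily while the closest pair of seeds is within the admissible
    # cluster radius
    groups: list[np.ndarray] = [seeds.members(k) for k in keep]
    positions: list[np.ndarray] = [seeds.positions[k].copy() for k in keep]
    merged = True
    while merged and len(groups) > 1:
        merged = False
        best, best_d2 = None, theta_s
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                d2 = float(np.sum((positions[a] - positions[b]) ** 2))
                if d2 <= best_d2:
                    best, best_d2 = (a, b), d2
        if best is not None:
            a, b = best
            groups[a] = np.concatenate([groups[a], groups[b]])
            positions[a] = state.positions[groups[a]].mean(axis=0)
            del groups[b], positions[b]
            changed = True
            merged = True

    new_positions = positions
    for members, pos in zip(list(groups), list(positions)):
        diffs = state.positions[members] - pos
        sq = np.einsum("ij,ij->i", diffs, diffs)
        if sq.mean() > theta_s:
            far = members[np.argmax(sq)]
            new_positions.append(state.positions[far].copy())
            changed = True

    if not new_positions:
        # degenerate: everything was singleton-pruned; restart from the
        # global centroid so the invariant S >= 1 holds
        new_positions = [state.positions.mean(axis=0)]
        changed = True

    pos = np.vstack(new_positions)
    assignments = assign_particles(state, pos)
    errors = _all_errors(state, assignments, pos)
    return SeedSet(pos, assignments, errors, seeds.iteration), changed


def cluster_particles(
    state: ParticleState,
    theta_s: float = 0.5,
    theta_c: float = 1e-2,
    rng_seed: int | np.random.Generator = 0,
    max_rounds: int = 200,
    init_seed_positions: np.ndarray | None = None,
    n_init: int | None = None,
) -> tuple[np.ndarray, bool, SeedSet]:
    """Run the adaptive centroid-seed loop to convergence.

    Returns ``(labels, converged, seeds)`` where ``labels[i]`` is the final
    seed index of particle i.  Convergence requires both the mean seed error
    to change by less than theta_c between rounds and a round with no seed
    insertion or removal.  ``init_seed_positions`` warm-starts the loop from
    a previous SeedSet's positions instead of random particles.

    ``n_init`` seeds start at distinct randomly chosen particle positions
    (default sqrt(N)).  Seeding generously and pruning is more reliable than
    growing from a minimal seed set: the merge and removal rules delete any
    surplus seed, whereas the split rule can only separate a cluster whose
    error exceeds theta_s — two adjacent particle clouds whose union error
    stays below theta_s would never be split, no matter how many rounds run.
    """
    rng = np.random.default_rng(rng_seed)
    n = state.n
    if init_seed_positions is not None and init_seed_positions.shape[0] >= 1:
        pos = np.asarray(init_seed_positions, dtype=float).copy()
    else:
        if n_init is None:
            n_init = max(2, int(round(np.sqrt(n))))
        n_init = min(n_init, n)
        start = rng.choice(n, size=n_init, replace=False)
        pos = state.positions[start].copy()
    assignments = assign_particles(state, pos)
    errors = _all_errors(state, assignments, pos)
    seeds = SeedSet(pos, assignments, errors)

    prev_mean_error = float(errors.mean())
    converged = False
    for round_no in range(1, max_rounds + 1):
        seeds, changed = adapt_seeds(state, seeds, theta_s)
        new_pos = update_seed_positions(state, seeds.assignments, seeds.positions)
        assignments = assign_particles(state, new_pos)
        errors = _all_errors(state, assignments, new_pos)
        seeds = SeedSet(new_pos, assignments, errors, iteration=round_no)

        mean_error = float(errors.mean())
        if not changed and abs(mean_error - prev_mean_error) < theta_c:
            converged = True
            break
        prev_mean_error = mean_error

    # compact labels to 0..K-1 keeping seed order
    _, labels = np.unique(seeds.assignments, return_inverse=True)
    return labels, converged, seeds
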