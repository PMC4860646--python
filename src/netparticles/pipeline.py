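"""End-to-end community detection: static, hierarchical sweep, temporal.

``detect`` runs the full chain: random particle initialization, integration
to the repulsion-monitored equilibrium, and centroid-seed extraction of the
clusters.  ``beta_sweep`` repeats detection over an ascending list of
repulsion strengths with alpha fixed, exposing hierarchical structure (small
beta merges everything into one cluster; larger beta resolves progressively
finer communities).  ``run_temporal`` walks a :class:`TemporalScenario`,
warm-starting both the particle positions and the seed set of each snapshot
from the previous equilibrium, which is what makes tracking cheap: only the
perturbed part of the configuration has to move.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from netparticles.clustering import SeedSet, cluster_particles
from netparticles.dynamics import (
    DynamicsParams,
    ParticleState,
    init_positions,
    run_to_equilibrium,
)
from netparticles.generators import TemporalScenario
from netparticles.graphs import Graph, Partition
from netparticles.metrics import nmi


@dataclass(frozen=True)
class ClusterParams:
    """Centroid-seed thresholds: split threshold theta_s, stop threshold theta_c."""

    theta_s: float = 0.5
    theta_c: float = 1e-2
    max_rounds: int = 200


@dataclass(frozen=True)
class DetectionResult:
    partition: Partition
    converged: bool
    iterations: int
    r_trace: tuple[float, ...]
    state: ParticleState
    seeds: SeedSet
    clustering_converged: bool = True

    @property
    def n_communities(self) -> int:
        return self.partition.n_communities


@dataclass(frozen=True)
class TemporalResult:
    """Per-snapshot detection results plus NMI against planted labels."""

    entries: list[tuple[int, DetectionResult, float | None]] = field(default_factory=list)

    def community_counts(self) -> list[int]:
        return [r.n_communities for _, r, _ in self.entries]

    def iteration_counts(self) -> list[int]:
        return [r.iterations for _, r, _ in self.entries]


def detect(
    g: Graph,
    params: DynamicsParams | None = None,
    cluster_params: ClusterParams | None = None,
    rng_seed: int | np.random.Generator = 0,
    initial_state: ParticleState | None = None,
    initial_seeds: SeedSet | None = None,
) -> DetectionResult:
    """Detect communities of a static graph.

    ``initial_state``/``initial_seeds`` warm-start the dynamics and the
    clustering (used for temporal tracking); by default both start fresh
    from the given seed.
    """
    if g.n_nodes == 0:
        raise ValueError("graph is empty")
    params = params or DynamicsParams()
    cluster_params = cluster_params or ClusterParams()
    rng = np.random.default_rng(rng_seed)

    if initial_state is None:
        state = init_positions(g.n_nodes, dim=params.dim, rng_seed=rng)
    else:
        state = initial_state
    start_iter = state.iteration
    state, r_trace, converged = run_to_equilibrium(g, state, params)

    labels, clus_ok, seeds = cluster_particles(
        state,
        theta_s=cluster_params.theta_s,
        theta_c=cluster_params.theta_c,
        rng_seed=rng,
        max_rounds=cluster_params.max_rounds,
        init_seed_positions=None if initial_seeds is None else initial_seeds.positions,
    )
    partition = Partition.from_array(labels, g.node_labels)
    return DetectionResult(
        partition=partition,
        converged=converged,
        iterations=state.iteration - start_iter,
        r_trace=tuple(r_trace),
        state=state,
        seeds=seeds,
        clustering_converged=clus_ok,
    )


def beta_sweep(
    g: Graph,
    betas: list[float],
    params: DynamicsParams | None = None,
    cluster_params: ClusterParams | None = None,
    rng_seed: int = 0,
) -> list[DetectionResult | Exception]:
    """Run one detection per beta with alpha fixed.

    Each beta starts from fresh random positions.  Failures are recorded in
    place of a result and the sweep continues.
    """
    if not betas:
        raise ValueError("betas must be non-empty")
    if sorted(betas) != list(betas):
        raise ValueError("betas must be ascending")
    params = params or DynamicsParams()
    results: list[DetectionResult | Exception] = []
    for idx, beta in enumerate(betas):
        try:
            results.append(
                detect(
                    g,
                    replace(params, beta=beta),
                    cluster_params,
                    rng_seed=np.random.default_rng([rng_seed, idx]),
                )
            )
        except Exception as exc:  # per-beta failure must not kill the sweep
            results.append(exc)
    return results


def run_temporal(
    scenario: TemporalScenario,
    params: DynamicsParams | None = None,
    cluster_params: ClusterParams | None = None,
    rng_seed: int = 0,
) -> TemporalResult:
    """Track communities across a scenario's snapshots with warm starts.

    Snapshot 0 is solved cold.  Every later snapshot reuses the previous
    equilibrium positions (new nodes drawn close to the origin, removed
    nodes dropped) and the previous seed set, then re-equilibrates under
    the updated adjacency.
    """
    params = params or DynamicsParams()
    result = TemporalResult()
    prev_state: ParticleState | None = None
    prev_seeds: SeedSet | None = None
    prev_labels: tuple = ()
    rng = np.random.default_rng(rng_seed)

    for tau, graph, truth in scenario.snapshots:
        if prev_state is None:
            det = detect(graph, params, cluster_params, rng_seed=rng)
        else:
            state = _carry_positions(prev_state, prev_labels, graph, params, rng)
            det = detect(
                graph,
                params,
                cluster_params,
                rng_seed=rng,
                initial_state=state,
                initial_seeds=prev_seeds,
            )
        score = nmi(truth, det.partition) if truth is not None else None
        result.entries.append((tau, det, score))
        prev_state, prev_seeds, prev_labels = det.state, det.seeds, graph.node_labels
    return result


def _carry_positions(
    prev_state: ParticleState,
    prev_labels: tuple,
    graph: Graph,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> ParticleState:
    """Map previous equilibrium positions onto the new node set.

    Nodes present in both snapshots keep their particle; new nodes are
    placed uniformly close to the origin.
    """
    index_prev = {lab: i for i, lab in enumerate(prev_labels)}
    pos = np.empty((graph.n_nodes, prev_state.dim))
    for i, lab in enumerate(graph.node_labels):
        j = index_prev.get(lab)
        if j is None:
            pos[i] = rng.uniform(-0.5, 0.5, size=prev_state.dim)
        else:
            pos[i] = prev_state.positions[j]
    return ParticleState(positions=pos, iteration=0)
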