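"""Planted-partition benchmark factories.

Four families mirror the standard community-detection test beds:

* Girvan-Newman (GN): N nodes in equal groups; the mixing parameter mu is
  the expected fraction of a node's links that leave its group.  Wiring is
  the classic planted-partition construction: independent Bernoulli trials
  per pair, with p_in and p_out solved from the requested mean degree and mu.
* Two-level hierarchical: micro-communities nested inside macro-communities;
  mu1 governs the fraction of links that leave the micro-community but stay
  in the macro, mu2 the fraction that leaves the macro.
* LFR-style: power-law degrees (exponent -2, truncated) and power-law
  community sizes (exponent -1), wired by configuration-model stub matching
  with rejection of self- and multi-edges.  This preserves the stated LFR
  parameters without reproducing the original rewiring code.
* Temporal scenario: a GN-style network evolving at the slow time scale tau
  through node migrations, with a scripted merge of two communities that
  drops the ground truth from 4 to 3 labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from netparticles.graphs import Graph, Partition, save_partition


class GenerationError(RuntimeError):
    """Raised when a sampler cannot satisfy its constraints."""


@dataclass(frozen=True)
class GNParams:
    """Girvan-Newman planted-partition parameters."""

    n_nodes: int = 128
    n_communities: int = 4
    mean_degree: float = 16.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.n_nodes % self.n_communities != 0:
            raise ValueError("n_nodes must be divisible by n_communities")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        g = self.n_nodes // self.n_communities
        if self.mu * self.mean_degree > self.n_nodes - g:
            raise ValueError("infeasible: mu * mean_degree exceeds external capacity")
        if (1 - self.mu) * self.mean_degree > g - 1:
            raise ValueError("infeasible: internal degree exceeds group size")


@dataclass(frozen=True)
class LFRParams:
    """LFR-style benchmark parameters (S: sizes 10-50, B: sizes 20-100)."""

    n_nodes: int = 1000
    mean_degree: float = 20.0
    max_degree: int = 50
    degree_exponent: float = -2.0
    community_exponent: float = -1.0
    community_size_range: tuple[int, int] = (10, 50)
    mu: float = 0.1

    def __post_init__(self) -> None:
        if self.community_size_range[0] < 2:
            raise ValueError("minimum community size must be >= 2")
        if self.degree_exponent >= 0 or self.community_exponent >= 0:
            raise ValueError("exponents must be negative")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")

    @classmethod
    def small(cls, n_nodes: int = 1000, mu: float = 0.1) -> "LFRParams":
        return cls(n_nodes=n_nodes, community_size_range=(10, 50), mu=mu)

    @classmethod
    def big(cls, n_nodes: int = 1000, mu: float = 0.1) -> "LFRParams":
        return cls(n_nodes=n_nodes, community_size_range=(20, 100), mu=mu)


EventOp = Literal["add_node", "remove_node", "add_edge", "remove_edge", "relabel"]


@dataclass
class TemporalScenario:
    """Snapshot sequence plus the event log that produces it.

    ``snapshots[k]`` is ``(tau, Graph, Partition)``; replaying ``events``
    with tau <= tau_k onto snapshot 0's edge set reproduces snapshot k.
    """

    snapshots: list[tuple[int, Graph, Partition]] = field(default_factory=list)
    events: list[tuple[int, EventOp, tuple]] = field(default_factory=list)

    def replay(self, upto_tau: int) -> set[tuple[int, int]]:
        """Apply logged edge events through tau onto the initial edge set."""
        _, g0, _ = self.snapshots[0]
        edges = set(g0.edges)
        for tau, op, payload in self.events:
            if tau > upto_tau:
                break
            if op == "add_edge":
                i, j = payload
                edges.add((min(i, j), max(i, j)))
            elif op == "remove_edge":
                i, j = payload
                edges.discard((min(i, j), max(i, j)))
        return edges


def _bernoulli_block_graph(
    membership: np.ndarray, prob_fn, rng: np.random.Generator
) -> Graph:
    """Wire all pairs independently; prob_fn(ci, cj) gives the link probability."""
    n = membership.size
    iu, ju = np.triu_indices(n, k=1)
    probs = prob_fn(membership[iu], membership[ju])
    mask = rng.random(iu.size) < probs
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    return Graph.from_edges(edges, nodes=range(n))


def generate_gn(params: GNParams, rng_seed: int | np.random.Generator = 0) -> tuple[Graph, Partition]:
    """Sample a GN planted-partition graph and its ground truth."""
    rng = np.random.default_rng(rng_seed)
    n, c = params.n_nodes, params.n_communities
    g = n // c
    membership = np.repeat(np.arange(c), g)

    # p_in (g-1) = (1-mu) kbar ; p_out (N-g) = mu kbar
    p_in = (1 - params.mu) * params.mean_degree / (g - 1)
    p_out = params.mu * params.mean_degree / (n - g) if n > g else 0.0
    graph = _bernoulli_block_graph(
        membership, lambda a, b: np.where(a == b, p_in, p_out), rng
    )
    return graph, Partition.from_array(membership, range(n))


def generate_hierarchical(
    n_nodes: int = 288,
    micro_size: int = 32,
    macro_size: int = 96,
    mu1: float = 0.25,
    mu2: float = 0.08,
    mean_degree: float = 24.0,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[Graph, Partition, Partition]:
    """Two-level planted partition: micro-communities nested in macro ones.

    Each node's expected links split as (1-mu1-mu2) inside its
    micro-community, mu1 inside the macro but outside the micro, and mu2
    across macro boundaries.  Returns the graph and both ground truths.
    """
    if macro_size % micro_size != 0 or n_nodes % macro_size != 0:
        raise ValueError("micro_size must divide macro_size must divide n_nodes")
    if mu1 + mu2 >= 1.0:
        raise ValueError("infeasible: mu1 + mu2 must be < 1")
    rng = np.random.default_rng(rng_seed)

    micro = np.arange(n_nodes) // micro_size
    macro = np.arange(n_nodes) // macro_size

    p_micro = (1 - mu1 - mu2) * mean_degree / (micro_size - 1)
    p_meso = mu1 * mean_degree / (macro_size - micro_size)
    p_macro = mu2 * mean_degree / (n_nodes - macro_size)
    for name, p in (("intra-micro", p_micro), ("intra-macro", p_meso), ("inter-macro", p_macro)):
        if p > 1:
            raise ValueError(f"infeasible {name} link probability {p:.3f} > 1")

    iu, ju = np.triu_indices(n_nodes, k=1)
    probs = np.where(
        micro[iu] == micro[ju],
        p_micro,
        np.where(macro[iu] == macro[ju], p_meso, p_macro),
    )
    mask = rng.random(iu.size) < probs
    graph = Graph.from_edges(
        zip(iu[mask].tolist(), ju[mask].tolist()), nodes=range(n_nodes)
    )
    return (
        graph,
        Partition.from_array(micro, range(n_nodes)),
        Partition.from_array(macro, range(n_nodes)),
    )


def _sample_powerlaw_int(
    rng: np.random.Generator, exponent: float, lo: int, hi: int, size: int
) -> np.ndarray:
    """Draw integers in [lo, hi] with P(x) ~ x^exponent (exponent < 0)."""
    support = np.arange(lo, hi + 1, dtype=float)
    weights = support ** exponent
    weights /= weights.sum()
    return rng.choice(np.arange(lo, hi + 1), size=size, p=weights)


def _sample_community_sizes(
    rng: np.random.Generator, n_nodes: int, lo: int, hi: int, exponent: float,
    max_tries: int = 200,
) -> list[int]:
    for _ in range(max_tries):
        sizes: list[int] = []
        while sum(sizes) < n_nodes:
            sizes.append(int(_sample_powerlaw_int(rng, exponent, lo, hi, 1)[0]))
        excess = sum(sizes) - n_nodes
        if excess == 0:
            return sizes
        if sizes[-1] - excess >= lo:
            sizes[-1] -= excess
            return sizes
    raise GenerationError("could not partition nodes into communities in range")


def generate_lfr_like(
    params: LFRParams, rng_seed: int | np.random.Generator = 0
) -> tuple[Graph, Partition]:
    """Sample an LFR-style graph by planted-partition stub matching.

    Degrees follow a truncated power law with the configured exponent and
    maximum; the lower cutoff is solved so the realized mean matches
    ``mean_degree``.  Each node splits its stubs ~(1-mu)/mu between its own
    community and the rest of the graph; stubs are paired uniformly with
    self/multi-edge rejection, and unpairable leftovers are dropped.
    """
    rng = np.random.default_rng(rng_seed)
    lo_size, hi_size = params.community_size_range
    sizes = _sample_community_sizes(
        rng, params.n_nodes, lo_size, hi_size, params.community_exponent
    )

    k_min = _solve_degree_cutoff(params.mean_degree, params.max_degree, params.degree_exponent)
    degrees = _sample_powerlaw_int(
        rng, params.degree_exponent, k_min, params.max_degree, params.n_nodes
    )

    internal = np.round((1 - params.mu) * degrees).astype(int)
    external = degrees - internal
    membership = _assign_communities(rng, internal, np.array(sizes))
    # stubs a too-small community cannot host are dropped, not spilled into
    # inter-community links, so the realized mixing stays at mu
    comm_sizes = np.bincount(membership)
    internal = np.minimum(internal, comm_sizes[membership] - 1)

    edges: set[tuple[int, int]] = set()
    for c in range(len(sizes)):
        nodes_c = np.flatnonzero(membership == c)
        _match_stubs(rng, nodes_c, internal[nodes_c], edges)
    _match_stubs(rng, np.arange(params.n_nodes), external, edges, forbid=membership)

    graph = Graph.from_edges(edges, nodes=range(params.n_nodes))
    return graph, Partition.from_array(membership, range(params.n_nodes))


def _assign_communities(
    rng: np.random.Generator, internal: np.ndarray, sizes: np.ndarray
) -> np.ndarray:
    """Place nodes into communities that can host their internal degree.

    Nodes are processed in decreasing internal-degree order; each picks a
    community with free capacity among those with size > internal degree,
    weighted by remaining capacity.  Nodes no community can host fall back
    to the one with the most free slots (their internal stubs are capped by
    the caller).
    """
    n = internal.size
    membership = np.empty(n, dtype=np.int64)
    capacity = sizes.astype(np.int64).copy()
    for node in np.argsort(-internal):
        fits = np.flatnonzero((capacity > 0) & (sizes - 1 >= internal[node]))
        if fits.size:
            weights = capacity[fits] / capacity[fits].sum()
            c = int(rng.choice(fits, p=weights))
        else:
            c = int(np.argmax(capacity))
        membership[node] = c
        capacity[c] -= 1
    return membership


def _solve_degree_cutoff(mean: float, k_max: int, exponent: float) -> int:
    """Smallest lower cutoff whose truncated power law has mean >= target."""
    best = 2
    for k_min in range(2, k_max):
        support = np.arange(k_min, k_max + 1, dtype=float)
        w = support ** exponent
        m = float((support * w).sum() / w.sum())
        best = k_min
        if m >= mean:
            break
    return best


def _match_stubs(
    rng: np.random.Generator,
    nodes: np.ndarray,
    counts: np.ndarray,
    edges: set[tuple[int, int]],
    forbid: np.ndarray | None = None,
    max_rounds: int = 50,
) -> None:
    """Pair stubs uniformly at random, rejecting self/multi-edges.

    ``forbid`` (community membership) vetoes within-community pairs, used
    for the external-stub pass.  Stubs that remain unmatched after
    ``max_rounds`` shuffles are dropped.
    """
    stubs = np.repeat(nodes, counts)
    for _ in range(max_rounds):
        if stubs.size < 2:
            return
        rng.shuffle(stubs)
        leftovers = []
        for a, b in zip(stubs[0::2], stubs[1::2]):
            i, j = int(a), int(b)
            key = (min(i, j), max(i, j))
            ok = i != j and key not in edges
            if ok and forbid is not None and forbid[i] == forbid[j]:
                ok = False
            if ok:
                edges.add(key)
            else:
                leftovers.extend((i, j))
        if stubs.size % 2:
            leftovers.append(int(stubs[-1]))
        if len(leftovers) == stubs.size:  # no progress
            return
        stubs = np.array(leftovers, dtype=np.int64)


def generate_temporal_scenario(
    base: GNParams | None = None,
    merge_at: int = 5,
    n_snapshots: int = 10,
    migrations_per_step: int = 1,
    rng_seed: int | np.random.Generator = 0,
) -> TemporalScenario:
    """Evolving 4-community scenario with a scripted merge.

    Starts from a GN graph of 4 equal communities.  At each slow time step
    tau, ``migrations_per_step`` nodes migrate between randomly chosen
    communities (their edges are rewired to the new membership's mu-split).
    At ``tau = merge_at`` two planted communities merge: links between them
    are re-sampled at the intra-community density, and the ground truth
    drops to 3 labels, one community holding the union.
    """
    if base is None:
        base = GNParams(n_nodes=128, n_communities=4, mean_degree=16.0, mu=0.1)
    if base.n_communities != 4:
        raise ValueError("the scenario requires 4 planted communities")
    if not 0 <= merge_at < n_snapshots:
        raise ValueError("merge_at must fall within the scenario horizon")
    rng = np.random.default_rng(rng_seed)

    graph, part = generate_gn(base, rng)
    n = base.n_nodes
    membership = part.as_array(range(n))
    edges = set(graph.edges)
    g = n // base.n_communities
    p_in = (1 - base.mu) * base.mean_degree / (g - 1)
    p_out = base.mu * base.mean_degree / (n - g) if n > g else 0.0

    scenario = TemporalScenario()
    scenario.snapshots.append((0, graph, Partition.from_array(membership, range(n))))
    merged = False

    for tau in range(1, n_snapshots):
        step_events: list[tuple[int, EventOp, tuple]] = []
        for _ in range(migrations_per_step):
            node = int(rng.integers(n))
            labels_now = np.unique(membership)
            target = int(rng.choice(labels_now[labels_now != membership[node]]))
            step_events += _migrate_node(
                rng, node, target, membership, edges, p_in, p_out, tau
            )
        if tau == merge_at and not merged:
            step_events += _merge_communities(rng, 0, 1, membership, edges, p_in, tau)
            merged = True

        scenario.events.extend(step_events)
        snap_graph = Graph.from_edges(edges, nodes=range(n))
        scenario.snapshots.append(
            (tau, snap_graph, Partition.from_array(membership, range(n)))
        )
    return scenario


def _migrate_node(
    rng: np.random.Generator,
    node: int,
    target: int,
    membership: np.ndarray,
    edges: set[tuple[int, int]],
    p_in: float,
    p_out: float,
    tau: int,
) -> list[tuple[int, EventOp, tuple]]:
    """Move a node to another community, rewiring its edges to the mu-split."""
    events: list[tuple[int, EventOp, tuple]] = []
    for e in [e for e in edges if node in e]:
        edges.discard(e)
        events.append((tau, "remove_edge", e))
    membership[node] = target
    events.append((tau, "relabel", (node, target)))
    others = np.flatnonzero(np.arange(membership.size) != node)
    probs = np.where(membership[others] == target, p_in, p_out)
    chosen = others[rng.random(others.size) < probs]
    for j in chosen.tolist():
        key = (min(node, j), max(node, j))
        edges.add(key)
        events.append((tau, "add_edge", key))
    return events


def _merge_communities(
    rng: np.random.Generator,
    c_a: int,
    c_b: int,
    membership: np.ndarray,
    edges: set[tuple[int, int]],
    p_in: float,
    tau: int,
) -> list[tuple[int, EventOp, tuple]]:
    """Fuse two communities: cross links re-sampled at intra density."""
    events: list[tuple[int, EventOp, tuple]] = []
    nodes_a = np.flatnonzero(membership == c_a)
    nodes_b = np.flatnonzero(membership == c_b)
    for i in nodes_a.tolist():
        for j in nodes_b.tolist():
            key = (min(i, j), max(i, j))
            present = key in edges
            want = rng.random() < p_in
            if want and not present:
                edges.add(key)
                events.append((tau, "add_edge", key))
            elif present and not want:
                edges.discard(key)
                events.append((tau, "remove_edge", key))
    for j in nodes_b.tolist():
        membership[j] = c_a
        events.append((tau, "relabel", (j, c_a)))
    return events


def dump_benchmark(
    graph: Graph,
    partition: Partition,
    out_dir: str | Path,
    provenance: dict,
    prefix: str = "benchmark",
) -> None:
    """Write edge list, partition file and JSON provenance to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / f"{prefix}.edges", "w") as fh:
        labs = graph.node_labels
        for i, j in sorted(graph.edges):
            fh.write(f"{labs[i]} {labs[j]}\n")
    save_partition(partition, out / f"{prefix}.labels")
    with open(out / f"{prefix}.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)


def dump_temporal(scenario: TemporalScenario, out_dir: str | Path) -> None:
    """Write the event log plus per-snapshot edge/ground-truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "events.log", "w") as fh:
        for tau, op, payload in scenario.events:
            args = " ".join(str(x) for x in payload)
            fh.write(f"{tau}\t{op}\t{args}\n")
    for tau, graph, part in scenario.snapshots:
        dump_benchmark(
            graph, part, out, {"tau": tau}, prefix=f"snapshot_{tau:03d}"
        )
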