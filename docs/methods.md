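# Methods

## The particle system

Each node of a simple undirected graph is a particle in R^D (D = 3 by
default). Writing A for the adjacency matrix, R = 1 − A − I for the matrix
of absent links, and k_i for the degree of node i, particle i moves under

    dx_i/dt = α F_att,i + β F_rep,i
    F_att,i = Σ_j (A_ij / k_i) (x_j − x_i)
    F_rep,i = Σ_j (R_ij / k_i) (x_i − x_j) e^{−d_ij/γ},   d_ij = ‖x_i − x_j‖.

Attraction pulls a particle toward the centroid of its network neighbours;
repulsion pushes it away from every non-neighbour with per-pair magnitude
d·e^{−d/γ}, which vanishes both at d → 0 (coincident particles do not
blow up) and d → ∞ (the system stays confined; the per-pair magnitude is
bounded by γ/e). Both interactions carry the unbiased random-walk weights
A_ij/k_i and R_ij/k_i. The repulsive force derives from the pair potential
φ(d) = γ(γ + d)e^{−d/γ}, so the dynamics is a gradient system and the
explicit Euler scheme with Δt = 1 converges to equilibria in practice.

Nodes in the same community share most of their links, so their mutual
attraction dominates and they collapse into a tight cloud; clouds belonging
to different communities repel until the exponential decay balances the
residual attraction through inter-community links. The equilibrium
cloud-to-cloud separation therefore shrinks as the mixing between
communities grows and as β falls — which is also what makes β a resolution
parameter (see the sweep below).

Updates are synchronous (one force evaluation per step, all particles moved
together). Isolated nodes feel no attraction and unit-weight repulsion
(1/k_i replaced by 1): they drift away and end up as singleton communities.
Coincident pairs contribute zero repulsion; no jitter is needed.

### Parameters

| parameter | meaning | default |
|---|---|---|
| α | attraction strength | 1.0 |
| β | repulsion strength / resolution | 0.36 (GN-scale); working band (0.1, 0.4) |
| γ | repulsion decay length | 1.0 |
| Δt | Euler step | 1.0 |
| θ_r | equilibrium threshold on ΔR(t) | 10⁻² |
| D | embedding dimension | 3 |
| max_iter | iteration cap | 1000 |

For the LFR-style benchmarks the better-performing β values are 0.15
(N=1000, small communities), 0.12 (N=1000 big, N=5000 small) and 0.09
(N=5000 big).

### Equilibrium monitor

The run is stopped by watching R̄(t), the mean over particles of the
repulsive-force magnitude, and its instantaneous variation
ΔR(t) = |R̄(t) − R̄(t−1)|. The trajectory of R̄ is characteristically
non-monotone: it peaks when the intra-community collapse ends and decays as
the clusters separate. A single reading below θ_r therefore occurs already
at the peak's inflection and again during the slow separation phase, long
before the geometry stabilizes; stopping there truncates the separation and
costs accuracy at moderate mixing. The monitor consequently requires
ΔR(t) < θ_r to persist for 10 consecutive steps (the `patience`
parameter). θ_r itself stays at 10⁻². Typical equilibration on a 128-node
benchmark is 20–40 iterations.

## Cluster extraction (adaptive centroid seeds)

The equilibrium configuration is converted to a partition by a K-means-like
loop whose K adapts:

1. S₀ seeds start at the positions of randomly chosen distinct particles
   (S₀ = ⌈√N⌉ by default).
2. Every particle joins its nearest seed (ties to the lowest seed index).
3. Each seed k carries the error E_k, the mean squared distance of its
   members to it; empty seeds have E_k = 0.
4. Adaptation: seeds with ≤ 1 member are removed (they are isolated in
   particle space); two seeds closer than the admissible cluster radius
   (‖s_k − s_l‖² ≤ θ_s) are merged; a seed with E_k > θ_s spawns a new seed
   at its farthest member. After any change, particles are reassigned.
5. Surviving seeds move to their members' centroid.
6. The loop stops when the mean seed error changes by less than θ_c between
   rounds and no seed was added, merged or removed in the round.

θ_s = 0.5 bounds the heterogeneity tolerated inside one cluster and drives
the rule in both directions: splitting separates clusters too spread to be
one community, merging removes seeds that over-partition a single tight
cloud. The merge rule is needed because two seeds inside one cloud are a
stable fixed point of steps 2–5 that neither the singleton-removal nor the
split rule ever touches. θ_c = 10⁻² stops the loop.

Seeding generously and pruning (S₀ = √N) is deliberately preferred over
growing from a minimal seed set: the split rule can only separate a cluster
whose error already exceeds θ_s, so two adjacent particle clouds whose
union error sits below θ_s would never be split no matter how many rounds
run — exactly the geometry produced by low β at moderate mixing (cloud
separation ≈ 1, union error ≈ 0.3). Surplus seeds, by contrast, are always
cleaned up by the removal and merge rules. The number of adaptation rounds
grows roughly linearly with the number of clusters found when growing from
a minimal seed set.

## Partition comparison

Agreement with a reference partition is scored by the confusion-matrix
normalized mutual information

    NMI = −2 Σ_ij N_ij ln(N_ij N / (N_i N_j))
          / [Σ_i N_i ln(N_i/N) + Σ_j N_j ln(N_j/N)]

(natural logs, 0·ln 0 = 0; rows = expected communities, columns = found).
NMI = 1 iff the partitions coincide up to relabeling; the degenerate case
of two single-community partitions is defined as 1. The implementation is
cross-checked in the tests against scikit-learn's arithmetic-mean NMI,
which is the same quantity.

## Benchmarks generated

* **Girvan–Newman**: N = 128 nodes in 4 groups of 32, mean degree 16. The
  mixing parameter μ is the expected fraction of a node's links leaving its
  group. Wiring is the classic planted partition: per-pair Bernoulli with
  p_in(g−1) = (1−μ)k̄ and p_out(N−g) = μk̄.
* **Two-level hierarchical**: N = 288, 9 micro-communities of 32 nested in
  3 macro-communities of 96; link fractions (1−μ₁−μ₂)/μ₁/μ₂ = intra-micro /
  intra-macro / inter-macro with μ₁ = 0.25, μ₂ = 0.08. Mean degree defaults
  to 24, which keeps intra-micro density dominant at those fractions.
* **LFR-style**: power-law degrees (exponent −2, truncated at 50, lower
  cutoff solved so the mean is ≈ 20) and power-law community sizes
  (exponent −1; 10–50 "S", 20–100 "B"), wired by configuration-model stub
  matching with self/multi-edge rejection. Nodes are placed in communities
  large enough to host their internal degree; stubs a community cannot host
  are dropped rather than spilled across communities, so the realized
  mixing tracks μ. This preserves the stated LFR parameters without
  reproducing the original LFR rewiring code.
* **Temporal scenario**: starts as GN (4×32, μ = 0.1); at each slow time
  step τ one node migrates between communities (its edges rewired to the
  new membership's μ-split), and at a scripted τ two communities merge —
  their cross-links are re-sampled at intra-community density and the
  ground truth drops to 3 labels, one of ≈ 64 nodes. The event log replays
  exactly onto the initial snapshot.

What the generators deliberately do not emulate: degree–community-size
correlations, overlapping memberships, weighted or directed edges, and the
exact LFR rewiring schedule. Results on them show recovery of planted
block structure under the stated mixing levels; they do not by themselves
establish performance on real networks with fat-tailed mixing or
overlapping communities.

## Hierarchical detection

A β-sweep at fixed α = 1 (fresh random positions per β) exposes the levels:
β ≈ 0.01 collapses the 288-node benchmark to a single cluster; a plateau at
β ≈ 0.03–0.12 resolves exactly the 3 macro-communities; the 9
micro-communities resolve at β ≈ 0.5–0.7 with our kernels (counts can
fluctuate by one there as an occasional micro-community splits, so the
reported fine-grained count is the mode over a few runs in that window).
The community count is non-decreasing along the sweep.

## Time-varying networks

Topology evolution (slow time τ) and particle motion (fast time t) are
decoupled: all events of a snapshot are applied, then the particles
re-equilibrate before communities are read. Both the particle positions
and the seed set warm-start from the previous snapshot's equilibrium; new
nodes are placed uniformly in the initial box around the origin, removed
nodes drop their particles. Warm starts cut the iteration count roughly in
half on the merge snapshot of the evolving benchmark relative to a cold
start, and leave the detected partition unchanged on a static snapshot.

## Numerical choices and limitations

* Force evaluation is dense O(N²) per step (pairwise distance matrix);
  N up to a few thousand is practical single-threaded. Benchmarks used in
  the tests run at N = 128–1000.
* The detector is stochastic through the initial positions and seed
  placement; on well-mixed networks (μ ≳ 0.4) or at β outside the working
  band, run-to-run variation grows. Averaging NMI over ~20 seeds is the
  measurement protocol used in the tests.
* At low β and moderate mixing (e.g. β = 0.15, μ = 0.3) the equilibrium
  cloud separation approaches the θ_s merge scale and recovery degrades
  gracefully (communities pairwise-merge rather than shatter).
* Ties in nearest-seed assignment go to the lowest seed index; labels are
  compacted to 0..K−1 in seed order; all comparisons are
  relabeling-invariant.
* Isolated nodes become singleton communities by construction.
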