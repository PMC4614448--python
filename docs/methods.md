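# Methods

## From a multivariate signal to a multiplex network

Given an M-dimensional real-valued series `x[α](t)`, `t = 0..N-1`,
`α = 0..M-1`, each channel is mapped to its **horizontal visibility
graph** (HVG): one node per time point, and an undirected edge `(i, j)`
whenever every intermediate value is strictly below the smaller
endpoint,

    x(k) < min(x(i), x(j))    for all  i < k < j.

Consecutive points always connect, so every HVG is connected; the graph
is outerplanar on the time axis, and a subgraph of the natural
(convexity-criterion) visibility graph, which is also provided.  The M
HVGs are treated as the layers of a **multiplex visibility graph** over
the shared node set.  Construction is a single monotone-stack pass per
channel — each index is pushed and popped once, so expected cost is
O(N) per layer and O(N·M) for the multiplex (the worst case, a
monotone series, is O(N²) per layer but produces a path graph).

**Tie handling.**  An intermediate value exactly equal to the smaller
endpoint blocks visibility (the criterion is strict).  This is
irrelevant for chaotic or continuous-valued data (ties have measure
zero) but matters for quantized inputs such as prices; it is a fixed,
documented convention, not a tunable.

## Cross-channel coherence measures

Two scalars summarise how much microscopic structure the layers share.

**Average edge overlap.**  With `a_ij[α]` the layer adjacencies,

    ω = Σ_{i<j} Σ_α a_ij[α]  /  ( M · Σ_{i<j} 1{Σ_α a_ij[α] > 0} ),

the mean fraction of layers an edge of the union edge set appears in:
`ω ∈ [1/M, 1]`, equal to 1 iff all layers are identical and to `1/M`
iff every union edge lives in exactly one layer.  `M·ω` reads as the
expected number of layers per edge.  The implementation tallies each
stored edge once (hash of the `(i, j)` key), preserving the O(N·M)
cost for sparse HVG layers.

**Interlayer degree mutual information.**  For layers α, β the
node-wise joint degree counts `N_{k[α],k[β]}` (whose marginals are the
per-layer degree counts, exactly, as integer tables) give the plug-in
estimate

    I_αβ = Σ P(k[α], k[β]) · log[ P(k[α], k[β]) / (P(k[α]) P(k[β])) ],

computed as `H(k[α]) + H(k[β]) − H(k[α], k[β])` from raw counts with
`0·log 0 := 0`, clipped at 0 against rounding residue.  No bias
correction (Miller–Madow, shrinkage, …) is applied: the estimator is
the maximum-likelihood recipe, and all comparisons made with it
(rankings, monotonicity in coupling, spanning-tree structure) are
invariant under the common bias at fixed N.  The log base defaults to
natural (nats) and is configurable; every in-package comparison is
base-invariant.  `I = ⟨I_αβ⟩` averages over the `M(M−1)/2` unordered
pairs, each once.

## The graph of layers and its summaries

The `I_αβ` values are the edge weights of a complete weighted graph on
the M layers — the visibility analogue of a functional network.  Two
sparsifications are computed:

* **Backbone**: edges added in decreasing weight until the graph is one
  connected component.  Ties are resolved with threshold semantics —
  the output is exactly the set of edges with weight ≥ w_c, where w_c
  is the largest threshold at which the thresholded graph is connected —
  so the result does not depend on the order equal-weight edges are
  listed in.
* **Maximum spanning tree** (Kruskal, lexicographic tie-break): always
  a subset of the backbone, since the smallest MST edge weight equals
  w_c.

Subgraph descriptors are the edge count K, the mean unweighted
shortest-path length L, the mean local clustering coefficient C and
the total weight W; L and C are deliberately unweighted (the weighted
variants add nothing to the phase contrasts these summaries are used
for, and the unweighted versions are the conventional defaults).  For
an MST, the hub fraction max-degree/(M−1) flags star-like
concentration: 1 for a star, 2/(M−1) for a path.

## The coupled-map-lattice test system

The generator is the canonical diffusive lattice of fully chaotic
logistic maps `f(x) = 4x(1−x)` on a ring of M sites,

    x_{t+1}[α] = (1−ε) f(x_t[α]) + (ε/2) [ f(x_t[α−1]) + f(x_t[α+1]) ],

ε ∈ [0, 1], indices periodic (`ring`, the default) or with mirrored
ends (`chain`: the ghost of site 0 is site 1); the `global` topology
replaces the neighbour mean by the lattice mean (ε/M coupling to every
site), the mean-field variant that admits complete synchronisation.
State stays in [0, 1] (every update is a convex combination of values
of f), and equal sites remain equal (the synchronised manifold is
invariant).

Defaults, chosen once as the study conditions: initial states i.i.d.
uniform(0, 1); 1000-step discarded transient; N = 2^14 recorded steps;
M = 5 for the small-lattice analyses and M = 200 for the large one.
This lattice reproduces the known phase sequence as ε grows — fully
developed turbulence (FDT) at small ε and again above ≈ 0.2, pattern
selection (PS) in ≈ (0.16, 0.2), with intermittent regimes between —
which is precisely what the multiplex measures are asked to detect:
`I(ε)` rises monotonically through the FDT range, both I and ω jump in
PS, and strong global coupling drives ω → 1 with layers pairwise
identical.  Sweeps run a configurable number of independently seeded
realizations per ε (defaults sized for a desk machine: 5–10 rather
than 50–100) and report per-ε standard errors so tolerances can be
scaled to the replicate count.

What the generator does **not** emulate: observational noise,
nonstationary drift, heavy-tailed increments, unequal sampling —
passing on it shows the machinery recovers known dynamical structure,
not that any particular empirical series is well described by a CML.

## Windowed (temporal) analysis

For long, possibly nonstationary records the series is cut into
non-overlapping contiguous windows of fixed length (trailing remainder
dropped; windows with missing values are rejected rather than imputed,
since visibility is undefined across gaps).  Each window yields a
multiplex snapshot and one row of the profile table: ω, I, and the MST
hub fraction and total weight of the window's graph of layers.  A
centred running average (default half-width 2 windows, truncated at
the ends) smooths the profiles.  The regime-switching generator
concatenates lattice runs with piecewise-constant ε, carrying the
dynamical state across switches, and returns per-row segment labels as
ground truth; windowed I separates well-chosen FDT vs PS segments
essentially always at window length 1024 with M = 5.

The input contract for empirical data is agnostic about
transformations (raw levels vs returns vs log-prices); the caller
chooses, and the symbolization range for the baseline is likewise an
explicit parameter (per-channel [min, max] when no state space is
known, [0, 1] for lattice data).

## Symbolic-MI baseline

The comparison method symbolizes each channel onto p equal-width bins
(half-open, last bin closed; p = 2 default, p = 6 the conventional
alternative) and averages the plug-in MI of aligned symbol pairs over
channel pairs.  `I^SYMB ≤ log p` by construction, which is exactly its
weakness: the partition coarse-grains away fine structure that the
degree-sequence MI retains, and the choice of range/p is arbitrary.
For independent channels the plug-in bias is ≈ (p−1)²/(2N) nats.

## Numerical and implementation notes

* HVG construction and lattice iteration are JIT-compiled with numba
  when available; the pure-Python definitions are the reference
  behaviour and are exercised directly through the pluggable-map code
  path.
* Degree tables are sparse integer mappings (HVG degrees are unbounded
  in principle); joint histograms use dense bincounts over the
  observed degree range for speed.
* Identical seeds and parameters reproduce every simulation bit for
  bit; sweep realizations are seeded by spawning one child seed per
  (ε, replicate) from a single root.
* Degenerate inputs: series shorter than 2, non-finite values, empty
  union edge sets, disconnected subgraph summaries and out-of-range
  couplings all raise `ValueError`/`IndexError` naming the problem.
* Directed visibility variants, weighted/penetrable visibility,
  community detection on layers and formal phase-boundary detection
  are out of scope.

## Known limitations

* The plug-in MI is biased upward at small window lengths; profiles
  from short windows should be compared against each other, not across
  window lengths.
* In the PS coupling range the lattice is multistable: realizations
  settle into different periodic patterns, so ω there has realization-
  to-realization spread far above its FDT standard error; the quoted
  standard errors capture this only with enough replicates.
* The large-lattice coherence peak is sensitive to the record length N
  (longer records in PS accumulate overlap), so cross-study
  comparisons of M·ω must fix N.
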