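# Methods

This note records the models implemented in `sourceloc`, the conventions
chosen where the mathematics leaves freedom, and what the shipped
experiments do and do not demonstrate.

## Propagation models

**Diffusion.** Every undirected edge carries one delay drawn independently
from $N(u, \sigma^2)$, shared by both directions of the edge and redrawn for
every simulation run. A source $s$ starts spreading at its initial time
$t_s$; a node newly informed at time $t$ delivers to each neighbour at
$t + \theta_{\text{edge}}$. Under this local relay rule a node's informed
time is its earliest arrival over delay-weighted paths from any source, and
the simulator computes exactly that with a multi-source Dijkstra sweep
seeded with the $(t_s, s)$ pairs. Draws that come out non-positive are
resampled until positive — arrival times must advance along a path. The
truncation is negligible for $\sigma/u \le 0.25$ and mildly inflates the
effective mean delay at the largest noise level studied
($\sigma = 1.5$, $u = 2$); correlations between time and distance, which are
all the locator uses, are unaffected by a monotone shift.

A source's *recorded* informed time is by definition its own start time,
even when (with staggered starts) another source's wave passes through it
earlier; the wave itself still propagates at the earlier passage time.

**SI epidemics.** Synchronous integer steps. At each step the informed set
is frozen; an uninformed node with $c$ informed neighbours becomes informed
at the next step with probability $1 - (1-\lambda)^c$ (independent
transmission at rate $\lambda$ per contact). The informed rate is uniform
across nodes. Sources activate at their own integer initial times, and the
simulation runs until every node is informed (raising after a configurable
step cap otherwise). With $\lambda = 1$ the epidemic is a breadth-first
wavefront and informed times equal hop distances — a useful exact check.

Time-axis convention: a source's informed time equals its stated initial
time (experiments use 0 unless staggered); neighbours are informed at
integer times strictly after their infector.

## The locator

The score of candidate $v_k$ sums prefix Pearson correlations between the
candidate's ascending observer distances and the correspondingly ordered
observer times, over prefix lengths $h = 2 \dots r$. Conventions:

* $h = 1$ is excluded — the correlation of a single point is undefined.
* A prefix in which all distances or all times are equal contributes 0, a
  neutral sign-free value.
* Distance ties are broken by the observer's position in the input record,
  never by informed time: time-based tie-breaking would push every
  candidate's correlation upward and bias the scores.
* Candidates are *all* nodes, observers included; observers and sources are
  drawn without exclusions in the experiments, so overlap is possible.
* The "perfect threshold" (the prefix length matching a source's true
  infection radius) is never estimated; summing over all $h$ makes the
  score parameter-free.

Ranking is by descending $f$; exact ties are ordered by node identifier for
presentation, and the AUC gives tied source/non-source pairs half credit
(Mann–Whitney convention), so reported accuracy never depends on the
arbitrary within-tie order. The ROC curve is traced at distinct score
thresholds, which makes its trapezoidal area coincide with the rank-sum
AUC to machine precision.

## Locatability and observer selection

Distinguishability of nodes $u, v$ under an observer set is the *exact*
integer predicate $d^v = k\,d^u + c,\ k > 0$ (fitted from two anchor
coordinates and verified elementwise at tolerance $10^{-9}$); because hop
distances are small integers this is equivalent to their Pearson
correlation being exactly 1, and exactness avoids tuning a floating
threshold. The locatability index $x$ counts distinguishable unordered
pairs over **all** node pairs. The measurement index is
$q^p = 1 - \binom{n}{2}^{-1} \sum_{i<j} \rho(d_i, d_j)$; pairs involving a
zero-variance column contribute 1 when both columns are constant and 0
otherwise (the correlation is undefined there and this choice keeps
$q^p \in [0, 2]$).

The greedy selector starts from the empty set and repeatedly adds the node
maximising $x$ of the augmented observer-distance matrix, breaking ties by
larger $q^p$ and then by node identifier ($q^p$ of a single row is defined
as 0 for bootstrap purposes). Once $x$ saturates at $n(n-1)/2$ the
remaining additions maximise $q^p$ alone. The procedure emits an *ordered*
sequence so that any prefix of size $r$ is itself a greedy observer set —
this is what the observer-count sweeps consume. Larger $q^p$ is treated as
better throughout, consistent with its algebra: more diverse distance
signatures mean smaller pairwise correlations and a larger index.

## Synthetic data and experiment design

Model networks are connected Erdős–Rényi graphs ($p = \langle k\rangle/(n-1)$,
redrawn up to 100 times until connected — the propagation models assume
every node is eventually informed) and Barabási–Albert graphs grown from a
complete clique on $m+1$ nodes with $m$ edges per new node (edge count is
then deterministic; $\langle k\rangle \approx 2m$). Standard settings,
used as defaults throughout: $n = 100$, $\langle k\rangle = 4$, diffusion
$u = 2, \sigma = 0.25$, SI $\lambda = 0.5$, two simultaneous sources at
time 0, repetition counts of 200 for headline quantities (50 as the
desk-scale default in the benchmark catalogue). Strategy-comparison
experiments use $n = 50$ and fix one network instance per family, since the
greedy sequence is a property of the instance; headline and robustness
experiments redraw the network every repetition. Per-repetition randomness
derives from `SeedSequence(master_seed, spawn_key=(repetition,))`.

Degree-preserving rewiring performs double-edge-swap *attempts*, rejecting
self-loops and duplicate edges and rolling back swaps that disconnect the
graph, so the degree multiset and connectivity are preserved exactly.

What the synthetic generators do **not** emulate: community structure,
degree–degree correlations, clustering, weighted or temporal contact
patterns, and reporting noise in observer times. Passing tests on these
generators show the statistic behaves as designed under its own model
assumptions, not that it attains the same accuracy on real contact data.

## Numerical choices and degenerate inputs

* Prefix correlations are computed from cumulative sums with constancy
  detected by exact running min/max comparisons, immune to floating-point
  cancellation; values are clipped to $[-1, 1]$.
* `pearson_coefficient` returns an explicit undefined marker (`None`) for
  zero-variance inputs rather than propagating NaN.
* Graphs are simple and undirected; self-loops and duplicate edges are
  rejected at construction, and the edge-list reader collapses duplicates
  with a logged warning instead.
* Node identifiers are opaque strings; every iteration order that matters
  is lexicographic, making all outputs reproducible bit-for-bit for a
  given seed.

## Known limitations

* Observer accuracy at high delay noise: with $\sigma = 1.5$ ($u = 2$), two
  sources and 10% observers on ER networks, the mean AUC computed here is
  ≈ 0.77 rather than above 0.8 as at $\sigma \le 0.5$; earliest-arrival
  propagation grows genuinely more disordered as path-delay selection
  effects strengthen with $\sigma$. The robustness sweep in
  `scripts/acceptance.py` reports the per-$\sigma$ values so the decay is
  visible rather than averaged away.
* Greedy observer selection is a heuristic for an NP-hard set problem;
  test-scale exhaustive checks confirm optimality only on tiny graphs.
* The locatability analysis assumes equal edge delays; no claim is made
  about distinguishability under heterogeneous or noisy delays.
* The number of sources is not estimated — the output is a ranking, and
  choosing a cutoff is left to the user.
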