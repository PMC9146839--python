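# Methods

## The models

`grandnet` implements two hierarchical maximum-entropy ensembles of simple
undirected networks in which the number of nodes N is itself a random
variable ("grand canonical"): N is drawn from a size prior π(N) supported
on N ≥ N0, then per-node structure is drawn, then the graph. Because every
level of the hierarchy is label-symmetric, both ensembles are
exchangeable — the probability of a graph is invariant under any
permutation of node labels — while remaining sparse (the link count grows
linearly with N). Mixing over finite but unbounded sizes is what lets a
sparse exchangeable family exist at all: at any fixed N the conditional
link probability between two nodes is O(1/N) and vanishes as N → ∞
(consistent with the Aldous–Hoover constraint on infinite exchangeable
graphs), yet the size-mixture marginal link probability stays finite.

**Degree-distribution ensemble.** Given N, a degree sequence k is drawn
i.i.d. from a truncated degree distribution p(k) on [m̂, K] conditioned on
Σᵢ kᵢ = ⟨k⟩N, and the graph is uniform over simple graphs with that degree
sequence. The number of such graphs is counted by the sparse-regime
(Bender–Canfield) asymptotic

    ln N(k) = ln matchings(2L) − Σᵢ ln kᵢ!,

where matchings(2L) = (2L−1)!! is the number of perfect pairings of the 2L
stubs. Collecting the three levels, the ensemble is Gibbs with Hamiltonian

    H(G) = −ln π(N) − Σᵢ ln[p(kᵢ) kᵢ!] + ln matchings(⟨k⟩N)

on the constraint manifold (exact link count L(N) = round(⟨k⟩N/2), degrees
in [m̂, K]). The kᵢ! factor enters multiplicatively because it is the
reciprocal of the per-node stub-permutation count in 1/N(k); dropping it
to the denominator instead produces a visibly wrong stationary degree
distribution in the sampler (total variation ≈ 0.4 from the target in our
checks, versus < 0.05 with the correct sign).

**Latent-variable ensemble.** Given N, each node carries θᵢ ≥ 0 drawn
i.i.d. from a discrete prior p(θ) on a finite grid, and each unordered
pair links independently with

    p_N(θᵢ, θⱼ) = (θᵢθⱼ/N) / (1 + θᵢθⱼ/N) ≤ 1,

so no structural cutoff on θ is needed. The joint law factorizes exactly;
no asymptotics enter the model itself.

### Double-factorial convention

All matching counts use the perfect-matching number (x−1)!! for even x
(`convention="matching"`), under which the counting identities used by the
inference module are exact integers. The literal double factorial x!! is
available (`convention="literal"`) for sensitivity checks; at fixed link
count the term is an additive constant of H and cancels from every fixed-N
acceptance ratio, so sampling is unaffected by the choice.

### Truncation of size sums

π(N) has unbounded support; every numeric sum over N (normalization,
entropies, marginals, posteriors) is truncated at Nmax. For the
exponential family Nmax is chosen automatically so that the untruncated
tail mass beyond it is below `tail_eps` (default 1e-10); heavy-tailed
(power-law) priors require an explicit Nmax, which is recorded in the
prior object. Unnormalized weight ratios are independent of the
truncation, which is asserted as a property test.

## Sampling

**Fixed-N Metropolis.** One step removes a uniformly chosen link and
inserts a uniformly chosen non-link, accepted with probability
min(1, e^{−ΔH}); since H depends only on the degree multiset, ΔH involves
at most four nodes and is computed incrementally (a full recomputation
every 10⁵ steps guards against drift at 1e-8). Moves that would leave
[m̂, K] are rejected. The proposal is symmetric (link and non-link counts
are conserved), so the chain converges to e^{−H}/Z on the constraint
manifold; this is verified by an exhaustive chi-square test on an
enumerable state space.

**Resize moves.** Every `resize_period` steps the chain proposes N′ = N±1
with equal probability, accepted with min(1, π(N′)/π(N)) and only if
N′ > N0. An accepted move is followed by an in-place repair: an added node
is wired to at least m̂ partners by rewiring existing links, then links
are added/removed uniformly at random (respecting the bounds) until
|E| = L(N′); a removed node takes its incident links with it before the
same repair runs. All mutations are journalled and rolled back if the
repair budget (100·N attempts) is exhausted. The resize proposal has no
tractable density, so detailed balance across N is approximate by
construction; the repair also deposits a few uniformly-placed links that
the fixed-N dynamics then has to re-equilibrate. Consequently the chain
trades N-mixing speed against degree-distribution fidelity through
`resize_period`: frequent resizes distort the degree histogram, rare ones
slow the N walk (±1 proposals make it diffusive, with relaxation time of
order the squared prior width in accepted resizes). The replication runs
use `resize_period=500`, start at the prior mean, and check both the
degree histogram (TV < 0.05 against the target) and that the time-average
of N sits inside the central 99% prior mass.

**Latent generator.** Direct: draw N, draw θ i.i.d., flip each pair
independently. O(N²) pairs; capped at N = 10⁴.

## Entropies

Both ensembles admit a three-level entropy split — size term, parameter
sequence term, graph-given-parameters term — which is the chain rule
S = H[N] + E H[params|N] + E H[G|params, N] for the hierarchical law.
For the latent ensemble all three terms are exact (the third is a pairwise
Bernoulli entropy, estimated by Monte Carlo over θ draws or enumerated).
For the degree ensemble the default sequence term uses the sparse-limit
closed form Σ_N π(N)·N·H[p(k)] (exact only as the sum constraint
decouples) and the graph term averages the Bender–Canfield log-count over
sequences drawn from the constrained conditional by rejection. Both terms
have exact modes (`degree_term="exact"`, `method="enumerate"`, and an
injectable exact graph counter) used by the tests, where the decomposition
reproduces a directly enumerated −Σ P ln P to 1e-9.

## Inference from an induced subgraph

An observer sees the subgraph Ĝ induced by N̂ sampled nodes: every link
between two sampled nodes, nothing else. κᵢ denotes observed degrees,
L̂ = Σκᵢ/2.

**Degree route.** The unknowns are N, true sampled degrees kᵢ ≥ κᵢ and
unsampled degrees qⱼ. Writing M = Σ(kᵢ−κᵢ) (hidden links incident to
sampled nodes) and Q = Σqⱼ, stub conservation forces Q + M = 2L − 2L̂.
The completions of Ĝ are constrained stub matchings — extra sampled stubs
may pair only with unsampled stubs, since a new sampled–sampled link would
have been observed — counted by C(Q,M)·M!·matchings(Q−M). This count is
exact at stub level and is validated integer-for-integer against
exhaustive enumeration for all instances with Q+M ≤ 8. The posterior over
N conditions on M (an input, possibly scanned), marginalizing degrees
through exponential tilts: the sampled-node sum I^(k) at tilt ω⋆ solving
Σᵢ E_ω[kᵢ−κᵢ] = M, and the unsampled sum I^(q) at tilt ω̄⋆ solving
(N−N̂)·E_ω̄[q] = Q. Both moment maps are strictly decreasing, so the roots
are unique; they are found by bracketed bisection to residual 1e-10
(vectorized across the N grid for ω̄). Boundary targets (M or Q at the
edge of the attainable range) use the exact degenerate sums instead of a
tilt. Per-node degree posteriors are p(k)·k!/(k−κ)!·e^{−ωk} on
k ∈ [max(κ, m̂), K]; support includes k = κ (a sampled node may have no
unobserved links).

**Latent route.** The subgraph likelihood is exact and involves only the
sampled nodes' θ; unsampled nodes' posteriors are exactly the prior. In
the large-N regime the pair product is summarized by the mean-field
variable θ̄ = Σθⱼ/N, giving per-node posteriors
p(θ)·θ^κ·e^{−θθ̄/2} and a size posterior evaluated at the self-consistent
θ̄⋆(N), the unique nonnegative fixed point of
θ̄ = (1/N) Σᵢ E[θᵢ | κᵢ, tilt e^{−θθ̄}] (the doubled tilt is the joint
saddle condition). The fixed point is found by damped iteration
(damping 0.5, tolerance 1e-10) with a bisection fallback; a vectorized
variant solves the whole N grid simultaneously, exploiting that the node
sum does not depend on N.

**Size-posterior N exponent (design decision).** The mean-field size
posterior as printed carries N^{−(L̂−1)}: the Jacobian of converting the
discrete constraint δ(θ̄, Σθ/N) contributes a bare factor N on top of the
likelihood's N^{−L̂}. Asymptotically that factor is cancelled by the
Gaussian-fluctuation prefactor of the saddle-point integral, which the
closed form drops. Keeping it makes the posterior overweight large N by
one power: the exact likelihood satisfies P(Ĝ|θ,N) → Πθ^κ · N^{−L̂} as
N → ∞ (the pair product tends to 1), and on every enumerable test
instance the printed exponent pushes the posterior argmax to the upper
grid edge while brute-force enumeration decays. `grandnet` therefore uses
N^{−L̂} by default (`n_exponent="matched"`), which reproduces the exact
tail and shares the brute-force argmax on all test instances;
`n_exponent="printed"` retains the alternative for comparison.

**Approximation quality.** Both size posteriors are saddle-point
(asymptotic) objects. On toy instances (N̂ ≤ 5) they share the argmax with
exhaustive posteriors and correlate strongly with them, but pointwise
deviations of order 0.1 in probability are normal; the tests assert the
argmax and correlation and report the deviation rather than bounding it.
At realistic scale (N = 300, half the nodes sampled) the 90% credible
intervals cover the true size in ≥ 80% of synthetic replicates for both
routes.

## Reconstruction

Degree route: given (k, q), the hidden part is drawn as a uniform random
constrained stub matching — rejection of self-loops/multi-edges (up to
1000 attempts), then a degree-preserving swap repair; uniform matching is
the measure implied by the counting formula. Joint draws of (k, q)
consistent with (M, Q) are produced by sampling each node's posterior
independently and then repairing the totals with random unit
increments/decrements inside each support — the model does not prescribe
a joint proposal, so this is the package's choice. Latent route:
unsampled nodes draw θ from the prior and every unobserved pair is
flipped with the kernel probability; the observed block is copied
unchanged.

## Synthetic data

`make_fixture` draws a ground-truth network — a configuration-model draw
repaired to the exact link count and mixed by rewiring for the degree
ensemble, the direct generator for the latent ensemble — samples a uniform
node subset of a given fraction, and returns the induced subgraph with the
hidden truth. The recovery studies use true N = 300 with 50% sampling,
an exponential size prior with scale 200 and N0 = 100, a truncated
exponential degree distribution p(k) ∝ e^{−k/5} on [0, 16] (mean ≈ 3.93),
and a discretized exponential latent prior p(θ) ∝ e^{−θ/2} on
{0, 0.25, …, 12} (mean ≈ 2, typical degrees of a few links — a sparse
network of the kind the model targets). The replication figures use the
published parameter values (degree/latent scale 7, tilt ω = 2, mean-field
θ̄ = 0.6, N̂ = 200 with L̂ = N̂/2, size-prior scale 200 with N0 = 100).
What passing these tests shows is that the machinery is internally
consistent under its own generative assumptions; real networks with
degree correlations, community structure, or non-induced (noisy)
observation are outside the model class and are not emulated.

## Numerical choices

- All combinatorics in log domain via `gammaln`; posteriors normalized
  with `logsumexp`; ln(1−p) via `log1p` for small kernels.
- Impossible configurations are flags (−∞ log-weights, +∞ Hamiltonians),
  not exceptions, except where the whole problem is infeasible (empty
  posterior support), which raises with the first violated factor named.
- Q is tied to stub conservation, Q = 2L − 2L̂ − M with
  L = round(⟨k⟩N/2): this is the nearest integer of matching parity to
  ⟨k⟩N − 2L̂ − M. N values admitting no feasible Q get zero mass.
- Degree sequences drawn i.i.d. with odd sum have one uniformly chosen
  entry resampled until the sum is even.
- Hamiltonians sum per-degree-value counts rather than per-node terms so
  that exchangeability holds bitwise, not just up to rounding.
- All randomness flows through one explicitly passed
  `numpy.random.Generator`; CLI outputs record the seed, config hash and
  convention flags in a manifest.

## Problem sizes

Simulation sizes in the test-suite and the acceptance script (2.5M-step
chains, 10⁶-step stationarity checks, 20-replicate recovery studies at
N = 300, enumeration oracles up to N = 7 and 8 stubs) were chosen as the
smallest instances at which each property is sharply testable; all scale
linearly in the obvious parameters if larger studies are wanted.

## Known limitations

- The resize move inherits the model description's lack of a proposal
  density; exact detailed balance across N is not claimed, and the
  stationary size distribution is validated only against prior mass
  coverage.
- Bender–Canfield counting is asymptotic; at small N (tens of nodes) the
  stationary degree histogram deviates from the target by a few percent
  in total variation even for a perfect sampler, shrinking roughly as the
  structural-cutoff ratio K²/⟨k⟩N does.
- The degree route conditions on M rather than marginalizing it; a scan
  utility covers ranges of M.
- Only simple undirected graphs: no directed, bipartite, multiplex or
  weighted variants, no degree–degree correlations, no noisy observation
  models.
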