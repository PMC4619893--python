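# Methods

This note documents the statistical models implemented in templix, the
numerical and design choices behind them, what the synthetic-data
generators emulate, and the known limitations.

## Distance restraints

A template-derived restraint on the distance *d* between two query atoms is
modelled in log-distance space (distances cannot be negative, so Gaussians
on *d* itself would leak mass into the negative domain):

    p(log d | θ) = w(θ) N(log d | μ(θ), σ²(θ)) + (1 − w(θ)) N(log d | μ_bg(θ′), σ_bg²(θ′))

with θ = (log d_t, pp, sim) and θ′ = (pp, sim).  The signal component is
peaked near the log template distance; the background component models the
event that at least one of the two aligned residue pairs is wrong, in which
case the template distance carries no information.  `w` is interpretable as
the probability that both pairs are correctly aligned.

All logarithms are natural.  The log base of the modelled quantity is a
free convention — it rescales μ and σ jointly and cancels in every odds
ratio — and the natural log keeps derivative bookkeeping trivial in the
optimizers.  Standard deviations are floored at 1e−6 log-Å so that
degenerate fits cannot produce unbounded densities.

Restraints combine on the odds scale,

    p(d | d_1..d_K) / p(d) ≈ ∏_k [ p(d | d_k) / p(d) ]^{w_k},
    p(d | d_k) / p(d) = 1 − w + w N(log d | μ, σ²) / N(log d | μ_bg, σ_bg²),

evaluated as `logaddexp(log(1 − w), log w + logN₁ − logN₂)` so both tails
are exact in floating point.  The ratio of two Gaussians is again an
exponential-quadratic; `gaussian_ratio_form` returns its completed-square
closed form, with an explicit exponential-linear branch for σ = σ_bg
(the quadratic terms cancel) rather than treating that case as an error.
When every component has σ < σ_bg the negative combined log-odds is bounded
above by Σ_k −w_k log(1 − w_k): wrong restraints saturate instead of
growing quadratically, which is the robustness mechanism the package exists
to provide.  An additive single-Gaussian mixture baseline
(`modeller_additive_baseline`, with user-supplied mixing constants) is
included for comparison only; its combined density is wider than any
component, not narrower.

## Mixture density networks

One network per atom-pair class (Cα–Cα, N–O, SC–MC, SC–SC) maps θ to the
five mixture parameters.  The architecture encodes the model: five tanh
hidden nodes, of which the two lowest receive no connection from log d_t,
and μ_bg, σ_bg are wired only to those two — so the background provably
cannot depend on the template distance (the property tests confirm a
finite-difference derivative of exactly zero).  Output links guarantee
validity: logistic for w, identity for the means, softplus (+ floor) for
the standard deviations; the hidden activation is tanh.  These link/
activation choices are this package's; they are the standard construction
for small mixture density networks.

Training minimizes the mean negative log-likelihood with analytic
gradients (responsibility-weighted backpropagation through the masked
layers) under L-BFGS, tolerance 1e−7, restarted from random
initializations with the best final likelihood kept.  The default is 50
restarts; the tests and acceptance runs use 2–3 restarts on data sets up
to 50 000 examples, which already recover the generating mixture weight to
a mean absolute error well under 0.05.  Restart seeds derive from one
master seed via `numpy.random.default_rng`.

## Template weighting

Templates evolve from common ancestors, so their distance evidence is
correlated.  Under Brownian distance evolution,
p(d_l | d_k, τ) = N(d_l | d_k, γτ) with rate constant γ (Å² per unit
evolutionary distance), a query-rooted tree is transformed into an
equivalent star topology by repeatedly collapsing an internal node whose
children are all leaves and updating their weights with

    w'_k = (1/τ₀ + 1/τ_k) / (1/τ₀ + Σ_l w_l/τ_l) · w_k

where τ₀ is the edge above the collapsed node.  Collapsed leaves re-attach
with edge τ₀ + τ_k, so every query–template path length — and hence the
similarity on which the restraint network depends — is preserved.  The
update's two limits are the sanity anchors: weights sum to 1 when
τ₀ ≫ max τ_k (fully redundant templates) and are unchanged when
τ₀ ≪ min τ_k (independent templates).  Within the transformation every
collapsed group's weights sum to at least 1 (unit initial weights, and the
update maps a group sum ≥ 1 into [1, Σw]), which is the regime where the
sum bounds (max w_k ≤ Σw' ≤ Σw) hold; outside it they need not.

Collapse order is deepest-node-first by default; order independence is
asserted by test rather than assumed.  Edge lengths are floored at
τ_min = 1e−6, so m identical templates (zero-length split) share weight
≈ 1/m instead of dividing by zero.

The equivalence of tree and star is verified numerically rather than
symbolically: `numeric_tree_odds` evaluates the restraint curve on the
query distance by leaf-to-root message passing on a grid (weighted
Gaussian kernels at the leaves, trapezoidal convolution at internal
nodes) and normalizes.  The hidden-node background is taken flat
(improper), under which one elementary step is an exact Gaussian identity
— completing the square gives total variance γ(τ₀ + 1/S) and mean
(Σ w_k d_k/τ_k)/S, S = Σ w_k/τ_k, both invariant under the update — so
normalized curves of a tree and its star transform agree to integration
tolerance (in practice, machine precision).  The Brownian model and its
integration live on the distance axis; the resulting weights are
dimensionless exponents and transfer unchanged to the log-space
restraints.

The initial tree is UPGMA (average linkage) on
dist(t_k, t_l) = −log TMscore_pred(t_k, t_l), rerooted at the query.
UPGMA is implemented in-package so that tie-breaking is pinned (the
earliest-created cluster pair wins), making trees bit-reproducible; the
tests cross-check merge heights against SciPy's average-linkage
implementation.  Rerooting at a leaf reverses the parent chain, splices
the resulting unary nodes, and resets all template weights to 1.

## Template selection

A feed-forward network (4 standardized inputs → 3 tanh hidden nodes →
logistic output) predicts the TMscore of the model that would be built
from each hit, from: raw alignment score, secondary-structure score per
query residue, expected number of correctly aligned residues per query
residue, and template resolution (missing resolutions, e.g. NMR
structures, are imputed at 3.5 Å).  The top prediction is the first
template; ties break by higher homology probability, then lexicographic
id.

The simple baseline adds templates whose prediction is ≥ 90% of the first
template's, whose structural score to the first template exceeds 0.7, and
whose score to every *other* selected template exceeds 0.8 (the first
template has its own, looser threshold — otherwise the 0.7 rule could
never apply), up to 10 templates.

The greedy selection balances coverage against quality.  With local
quality s(i, t) = P_hom(t) · p(i◇i′ | q, t) and improvement
Δs(i, t) = s(i, t) − max over accepted templates (0 over an empty or
non-covering set, so new coverage earns the full s), each remaining
candidate scores

    S(t) = Σ_{(i,i′) ∈ A(q,t)} [ exp(α Δs(i,t)) − β ],

and the highest-scoring candidate is accepted while S > 0, recomputing all
scores each round, capped at 8 templates (the baseline's cap is 10); the
candidate pool is the top 100 hits.  Defaults α = 0.95, β = 1.  With
β ≥ 1 a candidate dominated everywhere (every Δs ≤ 0) has S ≤ 0, so exact
duplicates of accepted templates can never enter the set, and raising β
can only shrink the accepted set.

## Synthetic data

The generators produce every fixture with known ground truth; all are pure
functions of (config, seed).

* `simulate_tree_distances` — Brownian evolution down a tree: each edge
  adds N(0, γτ) noise, so leaf variances equal γ × path length and leaf
  covariances γ × shared path, which the tests check against the analytic
  covariance.  Negative distances (possible under Gaussian increments) are
  rejected and resampled, with the rate logged; at the default scales
  (root distance ≈ 9–40 Å, γ = 0.25 Å²/τ) resampling is rare.  γ = 0.25 is
  a fixture choice making toy trees give visibly distinct weights.
* `simulate_restraint_tuples` — alignment-error-contaminated training
  tuples: log d_t ~ N(2.2, 0.35²) (≈ 9 Å, the typical inter-residue
  scale), pp ~ Beta(2, 1), sim ~ U(0, 1.5) bits; the generating mixture
  weight is a logistic in (pp, sim) and the signal spread shrinks with
  alignment quality.  The generating w and component labels are recorded
  for recovery tests.
* `simulate_hit_pool` — hits with a latent quality driving all four global
  features, the aligned-window extent, the column posteriors and the true
  TMscore, each with configurable noise.
* `make_toy_structures` — an ideal α-helical Cα trace (2.3 Å radius,
  1.5 Å rise, 100°/residue) as the query truth; good templates are
  small-perturbation copies; bad templates emulate gross misalignment by
  scattering the aligned positions over an unrelated random-walk chain, so
  their distances carry no information about the query's.

What passing tests on these fixtures do *not* show: real alignments have
feature distributions, error correlations and gap structure the generators
do not model (no solvent accessibility or gap-distance effects, no real
TMscore geometry, no PDB-scale statistics).  The tests validate the
machinery and its claimed properties, not benchmark-scale accuracy.

## Toy coordinate builder

`build_toy` minimizes Σ (restraint energy) + harmonic chain term
(3.8 Å Cα spacing, weight 10) over Cα coordinates with L-BFGS, best of 10
restarts (tests use 3), with three interchangeable restraint functionals:
the odds restraints, classical single-Gaussian restraints, and the
additive mixture.  Restarts start from Gaussian perturbations of a
supplied framework — normally a template, the usual homology-modeling
initialization; with flat-tailed restraints a random start can sit
entirely in the flat region, which is a global-search problem this
demonstrator deliberately does not solve — or of an extended chain.
Model quality is measured superposition-free as the RMS difference of all
pairwise Cα distances.

On 20 seeded fixtures (12 residues, 2 good + 1 bad template), adding
bad-template restraints degrades the odds mode less than the
single-Gaussian mode in every fixture, and the unsatisfiable-restraint
penalty is bounded in odds mode but quadratic in single-Gaussian mode
(assertable on a two-atom system).  The additive-mixture baseline is
*also* robust in this paired metric: the log of an additive mixture has
bounded influence, so its degradation is comparable to the odds mode at
toy scale.  Its weakness is different — the combined restraint widens with
template disagreement instead of sharpening (verified directly on the
density) — and a bad-vs-none degradation comparison does not expose it.

## Limitations

* The restraint writer emitting MODELLER-style numeric records is lossy
  and best-effort; JSON is the canonical interchange.
* Only ATOM/HETATM PDB parsing (first model, one chain, altloc 'A'/blank);
  no mmCIF, no insertion-code arithmetic.
* Side chains are represented by Cβ for the SC–MC/SC–SC classes; glycine
  pairs are skipped.
* The per-pair posterior is approximated by min(pp_i, pp_j) — conservative
  and monotone in both column posteriors.
* No tree inference beyond UPGMA; no bootstrap support; the toy builder is
  a demonstrator, not a modeling engine (no dihedrals, side chains, or
  annealing schedules).
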