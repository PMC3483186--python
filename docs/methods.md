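# Methods

## Models

### Discrete-character likelihoods (Mk1, AsymmMk)

A character with k states evolves along the rooted tree as a
continuous-time Markov chain.  Under **Mk1** all off-diagonal generator
entries equal a single rate r (expected changes per unit branch length),
giving the closed forms P(same) = 1/k + (k−1)/k·e^(−krt) and
P(different) = (1 − e^(−krt))/k.  The **asymmetric binary model**
(AsymmMk) has forward rate q01 and backward rate q10 with the standard
two-state closed form.  Likelihoods use Felsenstein's pruning algorithm
with per-node rescaling; missing states ("?") contribute an all-ones
partial vector, and polytomies are handled natively by the recursion.

Root priors: uniform for Mk1 (which is also its stationary law);
selectable uniform or stationary ((q10, q01)/(q01+q10)) for AsymmMk,
default stationary.  Mk1 with a uniform prior is invariant to root
placement (verified by test); the asymmetric model is root-dependent,
which is inherent to the model, not an implementation artifact.  One
caution learned from the simulation harness: when a history starts from
a fixed, non-stationary root state, fitting under the stationary prior
lets an inverted-rate model mimic the data through its root
distribution; recovery experiments therefore fit with the uniform prior.

Fitting: Mk1 by bounded scalar search on log r in [log 1e−8, log 1e2]
(tolerance 1e−8); AsymmMk by Nelder–Mead on (log q01, log q10) from the
symmetric Mk1 optimum (which guarantees the nested-model inequality up
to optimizer tolerance) plus seeded random restarts.  Zero or missing
branch lengths are clamped to 1e−8 to keep transition matrices
nonsingular.

### Marginal ancestral states and the T = 2 rule

For every internal node v and state s we report the log-likelihood of
all tip data with v clamped to s, parameters held at their global MLEs
(no per-node re-optimization — this matches the "state estimate"
semantics of the decision rule; a re-maximizing variant was considered
and rejected as a different estimator, not a different implementation of
the same one).  The quantities come from one post-order pass (partials
D) and one pre-order pass (outside quantities G), with
lnL(v = s) = log G_v(s) + log D_v(s); summing over s returns the global
log-likelihood at every node, which the code asserts to 1e−6.  States
with best − lnL(s) < T survive; T defaults to 2 log-likelihood units
(the conventional cutoff for rejecting ancestral-state estimates), and
significant sets are monotone in T by construction.

### Two-area DEC

Ranges {A}, {T}, {AT} over aquatic/terrestrial habitats.  Anagenesis:
range expansion {A}→{AT} at ρ·d (the aquatic→terrestrial direction
carries the asymmetry multiplier ρ), {T}→{AT} at d, contraction
{AT}→{A}/{T} at e, and single-area loss to the absorbing empty range at
e (zero tip likelihood).  Cladogenesis: a single-area ancestor copies
itself; a widespread ancestor splits into the six equal-weight
vicariance/subset-sympatry scenarios.  Root prior: uniform over the
three live ranges.  (d, e) are fitted per grid ratio by Nelder–Mead on
log rates; the default grid is 20:1 … 1:1 … 1:20 (39 points), the
asymmetry call compares the profile maximum with the 1:1 null at 2 lnL,
and per-node range sets use the same 2-lnL rule via clamped
recomputation.  One extinction rate is shared by both areas and ρ sits
on the A→T direction only, matching a profile that reports one
dispersal and one extinction column per ratio.  Transition matrices come
from one eigendecomposition of the 4×4 generator batched over distinct
branch lengths (expm fallback if ill-conditioned); the likelihood is
verified against exhaustive enumeration over pre-split range assignments
on small trees.

**Weak identifiability of ρ.** When extinction fits near zero, the
likelihood is dominated by histories that hold the backbone in the
widespread range {AT} and resolve every habitat shift cladogenetically
(cost 1/6 per split, no direction-bearing anagenetic event).  Such
histories carry no information about ρ, and the ratio profile flattens.
On the packaged unit-branch-length tree this is exactly what happens:
all 39 grid ratios sit within 2 lnL of the maximum and the argmax lands
at 1:1, even though the node-level range estimates (e.g. a solidly
terrestrial sciomyzid root at a 12:1 ratio) are stable.  Recovering a
peaked profile evidently requires the heterogeneous molecular branch
lengths of the original phylogram, which a printed figure cannot
provide.  Simulation shows the same softness: at study-scale event
counts the sweep places the argmax on the correct (aquatic-biased) side
in roughly 80% of replicates, not the near-certainty one might hope for,
and the package documents direction recovery rather than numeric ratio
recovery as the testable property.

### Constrained minimum-transition counting

Significant-state sets become node constraints (singletons hard,
multi-state sets as-is, DEC's {AT} allowing either habitat under the
default policy; tips take their observed state, full set when missing).
A Sankoff pass gives the global minimum number of changes; per directed
state pair, a big-M–encoded second pass minimizes/maximizes that pair's
count over all globally minimal completions, so "at least N" claims are
reported as brackets, never bare points, plus one representative
completion from a deterministic backtrack.  A scope argument restricts
reported counts to branches inside a named clade (stem included) while
minimality stays global; clade origin counts (branches where the parent
lacks the target state and the child has it) use the same machinery.
With all internal nodes free the DP reproduces Fitch parsimony length
(cross-checked against an independent Fitch implementation), and the
whole apparatus is verified against brute-force completion enumeration.

### Site likelihoods and topology tests

Per-partition GTR+Γ(+I): exchangeabilities and base frequencies define a
reversible generator scaled to mean rate 1, diagonalized via the
π-symmetrization; rate variation uses 4 equal-probability discrete gamma
categories summarized by their means (the dominant convention; a flag
selects the category count), plus an optional invariant class; per
partition a free rate multiplier scales the shared branch lengths
(mirroring per-partition branch-length rate parameters in partitioned
Bayesian analyses).  Branch lengths are optimized by cyclic bounded 1-D
search (stop at ΔlnL < 1e−4 or 50 sweeps).  The Jukes–Cantor limit and
the two-taxon closed form are test-pinned.

Topology comparison is RELL-based: multinomial site resampling of the
per-site log-likelihood rows (no re-optimization), B = 10,000 by
default.  KH/WKH compare each topology with the best (centered
replicate differences; weighted variants standardize by the replicate
standard deviation of the pairwise difference); SH/WSH use the centered
maximum statistic over all candidates; AU fits the multiscale bootstrap
z-values to d·√r + c/√r by weighted least squares over scales
0.5 … 1.4 and reports 1 − Φ(d − c), clamping degenerate bootstrap
probabilities with a warning.  KH is computed but excluded from headline
reports as inappropriate for a-posteriori comparisons.  All resampling
flows from one seeded generator: fixed seed, bit-identical replicates.

## Synthetic data

Trees are Yule or birth–death (dendropy's sampler) rescaled to a stated
root height in expected substitutions per site.  Discrete histories are
simulated by exponential waiting times along branches with full
event-level records (SimTruth: node states, per-branch events, realized
directed counts); the DEC variant adds cladogenetic range inheritance
and resamples histories that hit the empty range.  Alignments draw a
gamma/invariant rate category per site and evolve columns by the exact
transition matrices.  Every generator is a pure function of (config,
seed).

The study-shaped preset is 65 tips, a binary habitat character with a
10:1 aquatic→terrestrial rate bias started from an aquatic root (the
transient regime in which realized counts are directional — at
stationarity the two fluxes balance), and 11/57 ≈ 19% missing tips,
mirroring the unknown-life-cycle species.  DEC calibrations use
d = 0.05, e = 0.1 on height-2 trees, which yields on the order of ten
aquatic→terrestrial events per tree — the empirical scale.  What these
simulations do not emulate: real molecular branch-length heterogeneity,
phylogenetic error in the tree, or correlated evolution between habitat
and feeding; passing calibrations therefore speak to the estimators
under the model, not to robustness against misspecification.

## The packaged study data

The species-level topology is transcribed from the prose description of
the published consensus phylogeny (the figure itself is not
machine-readable); arrangements the text leaves open are arbitrary and
flagged in `src/sciophylo/data/README.md`, and branch lengths —
unrecoverable from a printed figure — are unit.  On this tree the
habitat chain (AsymmMk → T = 2 sets → constrained counting) gives 10
aquatic→terrestrial transitions and exactly 1 terrestrial→aquatic
(min = max over all minimal completions), the feeding chain gives 19
transitions across the Tetanocerini, and within *Tetanocera*: 5
terrestrial origins and 7 feeding transitions (3 shoreline-predation, 2
terrestrial-snail-predation, 1 slug-parasitoidism with a nested
succineid origin).  The DEC ratio profile on this tree is flat (see
above); its node estimates, not its argmax, are the robust output.

## Numerical choices and degenerate inputs

Log-space (Mk ASR) or rescaled linear-space (likelihood optimization,
DEC) pruning avoids underflow; optimizer bounds are [1e−8, 1e2] on Mk
rates and [1e−7, 50] on DEC rates with boundary warnings; monomorphic
characters pin the Mk1 rate at the lower bound with a warning (error in
strict mode); empty alignments, ragged rows, non-covering partitions,
unknown states and taxon-set incongruence raise typed errors early.
Ties in the counting backtrack resolve toward the lowest state index;
AU argmax ties resolve toward the lower topology index (immaterial for
continuous log-likelihoods).

## Known limitations

Two areas only (no wider DEC state spaces, no founder-event speciation);
one free asymmetry for k = 2 only; no stochastic character mapping; no
tree search (candidate topologies are inputs); the AU implementation
follows the standard two-term z-curve fit without the newton-refined
variants of dedicated software; and the study-tree transcription carries
the uncertainty documented above.
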