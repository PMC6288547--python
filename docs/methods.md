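# Methods

## The branching indexes and architectural classes

A plant's architecture is summarised by two unit-free allocation ratios: the
photosynthetic branching index (branch-borne leaf area over total leaf area)
and the exploration branching index (cumulated branch length over total stem
length, branches plus trunk). Both are 0 for a monocaulous plant and
approach 1 as the trunk's role vanishes. When only representative branches
were measured, per-branch means are multiplied by the censused branch count;
this is the same extrapolation the whole-plant trait formulas (total leaf
area, leaf number) use, so the two conventions cannot disagree.

The integrative index is PC1 of the two z-scored indexes (correlation PCA).
Sign convention: both loadings positive; if the raw indexes are negatively
correlated (which makes that impossible) the photosynthetic loading is made
positive and a warning is raised. The PCA is fitted on species means; the
fitted axis then projects individual-level measurements, so species are
tested on replicated individual scores.

Class segregation ranks species by mean score, runs all pairwise two-sample
Mann–Whitney rank-sum tests (exact null for small groups, normal
approximation with tie correction otherwise — scipy's default policy),
builds a compact letter display (insert-and-absorb) at significance level
alpha = 0.1, and calls an adjacent pair sharing no letter a *break*. The
k−1 strongest significant breaks delimit the k classes; break strength is
(pairwise p ascending, mean-score gap descending). The method names in the
literature for this step vary (signed-rank is sometimes cited), but species
samples are independent, so the two-sample rank-sum test is the
statistically coherent choice; the rank basis makes the whole procedure
invariant under monotone transforms of the scores. If fewer than k−1
significant breaks exist, remaining boundaries fall on the largest
mean-score gaps and the result carries a warning.

Derived traits follow the standard formulas (slenderness ratio, specific
wood and stem density, Huber value, SLA, tissue proportions, total leaf
area, leaf number, fruit volume = length × width²). The internode-diameter
formula is read as the geometric mean √(min·max) — the only reading with
diameter units. A zero denominator yields a missing value for that trait
only, logged, never a global failure.

## Signal statistics with intraspecific variation

Species means carry sampling variance s²ᵢ/nᵢ, added to the diagonal of the
Brownian covariance everywhere. For Pagel's λ the likelihood is the profile
(GLS mean) multivariate normal with covariance σ²·C_λ + diag(s²ᵢ/nᵢ); σ²
and λ are jointly ML-estimated by bounded L-BFGS-B from several λ starts.
The p-value is an LRT against λ = 0; because λ = 0 is a boundary point the
reference distribution is the 50:50 mixture of χ²₀ and χ²₁. The λ search is
bounded to [0, 1] by default for interpretability; an `unbounded` flag
extends it to the matrix-feasible maximum (min diagonal / max off-diagonal)
for comparability with software that reports λ slightly above 1.

Blomberg's K is the observed ratio MSE₀/MSE (deviations from the GLS
phylogenetic mean; MSE uses C-whitened deviations) divided by its Brownian
expectation (tr C − n/(1ᵀC⁻¹1))/(n−1). With measurement error, C is
replaced by the error-adjusted ML covariance C + diag(s²ᵢ/nᵢ)/σ̂² with σ̂²
from the BM(λ=1) fit; this construction is validated by simulation (K
centred on 1 under Brownian motion, permutation p-values uniform under the
null) rather than against any published table. The p-value is the inclusive
(+1-corrected) proportion of seeded tip permutations whose whitened MSE is
at most the observed one.

## Bivariate phylogenetic regression

The regression is direct ML on the 2n-dimensional joint normal of stacked
species means with block covariance [[σx²C + Dx, rσxσyC], [rσxσyC,
σy²C + Dy]], Dx/Dy diagonal sampling variances, and two GLS-profiled means.
Free parameters are (log σx², log σy², r); the evolutionary slope is
β = r·σy/σx. Direct ML (no EM) is deliberate: with n in the hundreds a
dense Cholesky per evaluation is cheap, robust, and easy to test (on a star
tree with no sampling error the fit reproduces ordinary least squares
exactly). Optimization is multi-start bounded quasi-Newton (moment start
plus five seeded restarts; the returned optimum never falls below any
start). Significance is the LRT against r = 0 on χ²₁; r = 0 is interior to
(−1, 1), so no boundary correction applies. Slightly negative statistics
from optimizer noise are clipped to zero with a warning. The covariance
kernel is pure Brownian (λ = 1); no multiple-testing correction is applied
across traits by default (a Holm column is available).

## Mk models and ancestral states

The likelihood is Felsenstein pruning with per-edge transition matrices
exp(Qt) computed once per Q by eigendecomposition (batched over all edge
lengths), with per-branch scaling-and-squaring as a fallback for defective
or ill-conditioned generators. Partial likelihoods are renormalized at
every node on the log scale. The root prior is uniform over the k states by
default (the convention of the standard ML-ACE implementations); a
stationary-distribution prior is available. Polytomies are handled natively
by the pruning product over all children. Unknown tips enter as uniform
partial likelihoods.

ER, SYM and ARD are fitted in log-rate space with box bounds [1e−8, 1e3]
and chained seeding: the ER optimum seeds SYM, the SYM optimum seeds ARD.
Combined with never returning a point below the best evaluated start, this
makes lnL(ER) ≤ lnL(SYM) ≤ lnL(ARD) structural rather than hoped-for. AICc
uses n = number of tips — the natural sample unit for a single character,
stated explicitly because AICc's n is genuinely ambiguous for phylogenetic
data. Ties in AICc break toward fewer parameters.

Marginal ancestral probabilities come from the standard two-pass algorithm:
the downward (pruning) pass gives each node's subtree likelihood, the
upward pass the likelihood of the rest of the tree given the node's state;
their normalized product equals the rerooted marginal. Node identifiers in
all outputs are positions in the tree's postorder sequence.

## State-dependent diversification

The MuSSE likelihood integrates, tipward to rootward along every branch,
the extinction probabilities E_i(t) and subtree densities D_i(t):

    dE_i/dt = μ_i − (λ_i + μ_i + Σq_ij)E_i + λ_iE_i² + Σq_ijE_j
    dD_i/dt = −(λ_i + μ_i + Σq_ij)D_i + 2λ_iE_iD_i + Σq_ijD_j

with D combined as D_left·D_right·λ_i at every internal node, the root
included (this matches the (n−1) speciation factors of the closed-form
birth–death density, which the test suite verifies to 1e−5 in the
single-state limit). Root treatment defaults to FitzJohn state weighting
(w_i ∝ D_i) with survival conditioning off — the defaults of the standard
implementation this module is modelled on; both are switchable and recorded
in every output. Complete sampling is assumed (E_i(0) = 0); a
sampling-fraction hook exists but defaults to 1. Polytomies are rejected
with an explicit error.

The integrator is an embedded Dormand–Prince 5(4) stepper with per-branch
relative tolerance 1e−8 (1e−7 during fitting) and absolute tolerance 1e−10,
JIT-compiled with numba; an identical pure-Python path and an independent
scipy `solve_ivp` path exist for environments without numba and for
cross-checking. A branch exceeding 1500 accepted/rejected steps is declared
infeasible and the fitter scores that parameter point −inf; at the stated
tolerances this only triggers in extreme-rate regimes (hundreds of expected
events per branch) far outside the region where a 27-tip likelihood is
informative, and it keeps optimization from stalling inside the stiff corner
of the rate box. Per-node renormalization of D on the log scale protects
against underflow; the bookkeeping schedule provably does not change the
result and is tested.

The model family is the standard 15-pattern lattice for three states:
everything free (12 parameters) down to shared λ with μ ≡ 0 and one shared
q (2 parameters), including the three two-class speciation patterns with
and without extinction. Fitting proceeds in increasing parameter count;
each pattern's starts include the projected optimum of every nested pattern
already fitted, so the fully free model never scores below any constrained
model. Starting values are birth–death moment estimates (Yule-type λ from
tip count and crown age); optimization is L-BFGS-B in log-rate space with
bounds [1e−8, 1e3]. A failing model is recorded (infinite AICc) and the
family fit continues. AICc again uses n = tips.

## Ordination and PERMANOVA

Trait-space ordination is correlation PCA (z-scored columns, SVD,
deterministic signs: largest-magnitude loading positive per component).
PERMANOVA uses Euclidean distances on the same z-scored traits — the
minimal distance choice consistent with a correlation PCA of the same
table; the pseudo-F partitions the squared-distance sum among and within
groups, with a seeded free permutation of group labels (999 by default,
inclusive p). Species with any missing trait are dropped listwise and
constant traits are dropped, both logged — the same mechanism that handles
species excluded from individual traits in real datasets.

## The synthetic-data generators

The generators emulate the statistical structure of the study system, not
its biology: a 27-species crown clade of age 2.4 Myr; architectural classes
of sizes 7 (monocaulous), 6 (intermediate), 14 (branched); class-mean
photosynthetic/exploration indexes 0.03/0.16, 0.36/0.45, 0.82/0.76; five
individuals per species; continuous traits under Brownian motion with
tunable λ and within-species replicate noise (sd 0.1); state-dependent
diversification with λ = 1.2, μ = 0, q = 0.1 per Myr.

Trees are simulated forward (Gillespie) from two crown lineages and
conditioned on the survivor count by rejection, stopping at a uniform time
between the event that first reaches the target count and the next event;
both crown lineages must survive, so the crown age equals the simulation
span and rescaling to 2.4 Myr is exact. Index targets are beta-distributed
(bounded support, unlike a truncated normal): species targets around the
class mean with concentration 60, individual values around the species
target with concentration 40, and the two indexes coupled across species
through a Gaussian copula with latent correlation 0.3. These three values
were calibrated once, forward from the generator: they give a Spearman
correlation between the two indexes of ≈0.86 across species (matching the
structure the generator is meant to emulate) and individual-level
dispersion comparable to the species-level dispersion — which is what makes
within-class species share compact-letter-display letters, the premise of
the break-detection rule. Measurements (trunk length ~lognormal 150 cm,
total leaf area ~lognormal 3000 cm², two representative branches plus a
census) are constructed so the computed indexes reproduce the drawn targets
exactly; individuals whose drawn indexes fall below 1e−3 are emitted
unbranched.

What the generators do **not** emulate: real leaf/wood anatomy and
allometry, unequal sampling effort, phylogenetic error, non-Brownian trait
evolution, or incomplete taxon sampling. Passing tests therefore
demonstrate correctness and calibration of the estimators under their own
model assumptions on realistic problem sizes — not robustness to violations
of those assumptions in field data.

## Numerical choices and problem sizes

All optimizers are seeded multi-start bounded L-BFGS-B; every fit evaluates
all starts and can never return a point below the best of them. Rate
bounds are [1e−8, 1e3] in natural units; a fit at a bound is flagged as a
boundary estimate. Permutation tests use 999 permutations by default
(inclusive +1-corrected p-values); calibration tests in the suite use 199
permutations, which leaves KS uniformity checks insensitive to the p-value
discreteness. Simulation-based tests use problem sizes chosen as the
smallest at which the checked property is comfortably identifiable —
100-tip trees for λ recovery, 200 tips for Mk rate recovery, 27 tips
(the study size) for diversification model selection, 40 replicates for
the family-selection frequency — with the full-scale versions in the
acceptance suite and reduced versions in the unit suite.

## Known limitations

- The λ search is bounded at the matrix-feasible maximum; estimates exactly
  at 1 under strong signal are expected and are not evidence of more-than-
  Brownian covariance.
- The error-adjusted Blomberg K construction is a documented interpretation
  (simulation-validated); other software may adjust differently.
- The MuSSE machinery requires strictly bifurcating trees and assumes
  complete sampling by default.
- With 27 tips, state-dependent diversification models are weakly
  identifiable; the family AICc ranking is meaningful, individual rate
  estimates less so (the fitting warns below 10 tips).
- PERMANOVA is implemented for a single factor with free permutations; no
  strata or nested designs.
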