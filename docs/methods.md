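# Methods

This note records the modelling choices, numerical conventions and known
limitations of the package, in the spirit of a statistical-software methods
appendix. Nothing here asserts an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Substitution models

All five named models (JC, HKY, TrN, TVM, GTR) are parameterised as a
general time-reversible generator Q<sub>ij</sub> = s<sub>ij</sub>π<sub>j</sub>
with six symmetric exchangeabilities s (order AC, AG, AT, CG, CT, GT) and
stationary frequencies π, rescaled so −Σπ<sub>i</sub>Q<sub>ii</sub> = 1
(one expected substitution per unit of rate-time). Submodels are constraint
patterns: HKY has one transition/transversion ratio; TrN frees the two
transition rates; TVM frees the four transversion rates while keeping the
transitions equal; JC additionally forces uniform frequencies. During
inference one exchangeability is fixed at 1 as the reference and the free
ones carry log-normal(0,1) priors. Base frequencies default to the
empirical frequencies of the alignment (unambiguous sites only) and are not
sampled — with intraspecific data they are tightly determined, and this
matches the common practice of fixing them empirically.

Transition probabilities come from the π-symmetrised eigendecomposition,
computed once per parameter value and reused for every branch and rate
category; the test suite checks it against `scipy.linalg.expm` and against
the Chapman–Kolmogorov and detailed-balance identities.

## Site-rate models

Every RHAS treatment is reduced to category rates r<sub>c</sub> and weights
w<sub>c</sub> with Σw = 1 and Σw·r = 1. The unit-mean normalisation is what
keeps the clock rate comparable across treatments: μ always means expected
substitutions per site per year at the average site.

The discrete gamma uses k equal-probability bins of the unit-mean gamma.
The default bin representative is the conditional mean, computed in closed
form from regularised incomplete-gamma differences (so the discrete mean is
exactly 1); the bin median is available behind a flag because the choice
visibly changes likelihoods at small k, and both conventions are in
circulation. With invariable sites, the gamma rates are multiplied by
1/(1−p_inv), keeping the mixture mean at 1.

## Likelihood

Felsenstein pruning over alignment site patterns (columns compressed with
weights; compression is likelihood-neutral and tested as such). Gaps and
IUPAC ambiguity codes are partial observations — tip partials are indicator
vectors over the compatible states — so a rate-0 category contributes to
any pattern for which some single state is compatible with every tip. No
ascertainment correction is applied: the intended inputs are full
alignments including their constant columns.

The production evaluation path is a numba-compiled kernel with a
state-major memory layout; rescaling against underflow happens every eighth
internal node, and because only the root likelihood is needed the scale
factors accumulate in a single per-(category, pattern) matrix. A pure-numpy
implementation with per-node scaling is kept as the reference path (and the
fallback when numba is absent); the suite asserts the two agree with each
other and with exhaustive ancestral-state enumeration to 1e-10 relative on
small trees for every model × treatment combination.

Only the product μ × duration enters the likelihood. Heterochronous tip
ages break that confound; for isochronous data a normal root-age
calibration must be supplied, and the sampler refuses nothing — it simply
cannot learn μ without one of the two.

## Tree prior and MCMC

The tree prior is the serial-sample constant-size coalescent: lineages
activate at their sampling ages; with j active lineages the waiting time to
the next coalescence is exponential with rate j(j−1)/(2N), and each
coalescence contributes a 1/N factor. N is in years (an effective
population size × generation time compound) with a log-uniform prior.

Sampling is single-site Metropolis–Hastings over (μ, N, α, p_inv, free
exchangeabilities, node ages): multiplicative scale moves for positive
scalars, a logit-space random walk for p_inv, a uniform draw within
(oldest child, parent) for internal node ages, a scale move on the
root–oldest-child gap, and a joint "rate up / ages down" scale move that
multiplies μ by f and divides all internal ages by f (Hastings factor
(1−n_internal)·log f, rejected when a scaled age would drop below a tip).
The joint move matters: the posterior's slowest direction is the μ × time
ridge, and without it the effective sample size for μ is an order of
magnitude worse. Proposal step sizes adapt towards ~25% acceptance during
burn-in only, so the retained samples come from a fixed transition kernel.

Priors (all config-overridable): μ log-uniform on [1e−12, 1e−1], N
log-uniform, α exponential with mean 1 (truncated to [1e−3, 1e3] for
numerical sanity), p_inv uniform on (0,1), exchangeabilities
log-normal(0,1). Prior-only runs (likelihood switched off) are part of the
test suite: each scalar's sampled marginal must match its prior by KS test,
which catches Hastings-ratio errors wholesale.

Defaults are 2×10⁵ steps sampling every 100 with 10% burn-in; a
`full_scale` flag restores 2×10⁷ steps sampling every 10³ for full-scale
runs. Credible intervals are central 95% (2.5th–97.5th percentiles), not
HPD: central intervals are monotone-transform-equivariant and simpler to
reason about; for the skewed, unimodal marginals seen here the difference
is small. ESS is estimated from the FFT autocovariance with Geyer's initial
positive pair-sum truncation; `summarize` warns below 200. The marginal
likelihood is the harmonic-mean estimator on post-burn-in log-likelihoods
(stabilised log-sum-exp). Its upward bias and high variance are
well documented; it is used only to compare RHAS treatments on identical
data, where its cheapness is the point.

### Fixed topology

The topology is fixed throughout (user-supplied newick or a starting tree
built in-package) — node ages, not clades, are sampled. The estimands this
package targets (μ, root age, α, p_inv, marginal-likelihood trends in k)
are robust to modest topology error in low-diversity data, but clade
support is out of scope and deep topology errors would bias the rate. The
starting topology is UPGMA on Jukes–Cantor distances after an age
correction: d′_ij = d_ij + μ̂(a_i + a_j), which makes pairwise distances
approximately 2μT_mrca and so ultrametric, where μ̂ is a root-to-tip
regression guess. Plain UPGMA misplaces old tips badly enough to bias μ
several-fold on fast-evolving serial data; the corrected version recovers
generating parameters in simulation. Node ages are initialised from the
corrected heights divided by μ̂, pushed above the oldest descendant tip
where needed.

## Substitution counts

Fitch parsimony gives the per-site minimum number of changes, with
ambiguity codes entering as state sets. Stochastic mapping samples, per
site and realization: a rate category from its posterior given the pattern,
a joint ancestral state assignment by top-down sampling from the pruning
partials, and then a substitution history on each branch by uniformization
conditioned on the branch endpoints (jump count from the
Poisson-mixture posterior, intermediate states bridge-sampled, self-jumps
discarded). Counts are averaged over realizations (default 100) and rounded
half away from zero. The uniformization sampler is validated in
distribution against rejection-sampled Gillespie paths, and the summed
mapped counts against μ × tree length. The "constant site" summary is the
fraction of sites whose pre-rounding mean count falls below 0.5.

Both parsimony and mapping are reported because they answer slightly
different questions (minimum vs posterior-expected change); mapping is the
default for constant-site summaries, parsimony for count histograms.

## Count-distribution fits

Counts are pooled from the upper tail until every bin's expected count is
at least 5 under a moment-matched Poisson reference; both families share
that binning so the negative binomial (which nests Poisson as shape → ∞)
can never fit worse after its joint (m, shape) χ² minimisation
(Nelder–Mead in log space from a moment start, with a Poisson-limit start
and a log-spaced grid fallback). Degrees of freedom are bins − 1 − #params.
AIC uses the exact unpooled per-site log-likelihood at the χ²-minimising
parameters — χ² estimation with likelihood-based AIC is a deliberate hybrid,
flagged here because other conventions exist. The P-value ratio
P(negbin)/P(poisson) is reported but flagged ill-conditioned when both
P < 1e−12.

## Date-randomisation test

Tip ages are permuted over taxa (the multiset of observed dates is
reassigned, never resampled; identity permutations are redrawn) and the
full inference is rerun per replicate (default 20) with identical settings
and per-replicate seeds. The verdict is "no_signal" iff the original
posterior mean rate falls inside at least one replicate's 95% CI — the
permissive "any" rule; stricter "all-CIs" variants exist and are not
implemented.

## Synthetic data

The generator is the exact forward counterpart of the inference model:
serial coalescent trees (validated against the closed-form n=2 density and
the coalescent prior itself) and sequences evolved site-by-site with rates
from the configured treatment. Two deliberate extensions let the generator
pose harder questions than the inference model can represent:
continuous-gamma site rates (the "true k = ∞" target of the category
sweep) and a hotspot contamination (a fraction f of sites, default 0.05,
with rates multiplied by 20) emulating data whose upper count tail exceeds
any gamma fit.

Presets mirror four intraspecific study designs at reduced tip counts:
`mito_like` (2,000 of ~16.6 kb mitogenome sites, 65,000-year window, slow
clock, +Γ+I with α = 0.1, p_inv = 0.5), `dloop_like` (682 sites,
45,740-year window, α = 0.24), `flu_like` (1,200 sites, 82-year window,
fast clock, α = 0.31) and `hiv_like` (1,063 sites, 46-year window, fast
clock, α = 0.39, hotspots on). Site counts for `dloop_like` and `hiv_like`
are the original marker lengths; tip counts (16–24) and the other scalings
were chosen once so that each preset reproduces its regime's qualitative
signature (mitochondrial presets overwhelmingly constant, HIV-like the
least constant with a heavy count tail) while simulating in milliseconds.

What passing tests on these simulations do **not** show: robustness to
alignment error, recombination, selection, demographic change (only
constant-size coalescent trees are generated), rate variation among
lineages (the generator and the inference are both strict-clock), or
topology misspecification beyond what the fixed-topology design absorbs.

## Test and acceptance scale

The acceptance-style experiments run at sizes chosen for a single-core
test environment: credible-interval coverage uses 20 replicates of 20 tips
× 2,000 sites with 25,000-step chains (chain length set by mixing
diagnostics — ESS for μ in the tens — not by the study-scale
2×10⁷-step runs); the date-randomisation controls use 12 tips × 500 sites
with 4 replicates per test; the category sweep uses 14 tips × 800 sites
over k ∈ {3, 4, 6, 10, 32}. The same code paths scale to full-size runs
via `full_scale` and the config.

## Known limitations

* Fixed topology (above); no relaxed clocks; no partitioned models.
* Harmonic-mean marginal likelihoods only — adequate for within-data
  trends, not for publication-grade Bayes factors.
* The ESS estimator assumes roughly stationary post-burn-in chains; it is a
  diagnostic, not a guarantee.
* The χ²/AIC hybrid in the count fits follows the package's stated
  convention; alternative likelihood-only fits would give slightly
  different shape estimates.
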