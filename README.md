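# ratesweep

Bayesian tip-dated estimation of substitution rates and coalescence times
for intraspecific nucleotide data, built to study how the choice of
rate-heterogeneity-among-sites (RHAS) model — a discrete gamma with *k*
categories (+Γ), invariable sites (+I), or their mixture (+Γ+I) — affects
those estimates.

## Who this is for

Population-level sequence data (ancient DNA, serially sampled viruses,
intraspecific mitochondrial data) are typically low-diversity: most sites
are constant, and the RHAS model is chosen by information criteria rather
than biology. This package lets you ask, on your own data or on simulated
data with known truth: does increasing *k* change the marginal likelihood,
the rate, or the root age? Does assuming a proportion of invariable sites
matter? How is the +Γ+I model's *p*<sub>inv</sub> estimate entangled with
*k* and α?

## The model

Sites evolve independently under a reversible substitution model (JC, HKY,
TrN, TVM or GTR), Q normalised to one expected substitution per unit
rate-time. Site rates follow one of four treatments, always normalised so
the mean rate is 1 and the clock rate μ (substitutions/site/year) stays
identifiable:

* **equal** — one rate class;
* **+Γ(k)** — a unit-mean gamma with shape α cut into *k* equal-probability
  bins, each represented by its conditional mean (or median);
* **+I** — a rate-0 class of weight *p*<sub>inv</sub>;
* **+Γ+I** — both, with the gamma rates inflated by 1/(1−*p*<sub>inv</sub>).

A strict clock maps branch durations (years) to expected substitutions via
μ; tip sampling ages calibrate the clock (for isochronous data a normal
root-age prior is required instead). The tree prior is a constant-size
serial coalescent with population-size parameter *N*; the posterior over
(μ, *N*, α, *p*<sub>inv</sub>, exchangeabilities, node ages) is sampled by
Metropolis–Hastings on a fixed topology, and marginal likelihoods come from
the harmonic-mean estimator. Per-site substitution counts are obtained by
Fitch parsimony and by stochastic mutational mapping (endpoint-conditioned
uniformization); their histogram is fitted with Poisson and negative
binomial distributions by χ² minimisation — under gamma RHAS the negative
binomial's shape estimates α. A date-randomisation test (re-inference under
permuted tip dates) checks temporal signal.

## Worked example

Simulate an influenza-PB2-like data set (20 heterochronous tips over an
82-year window, 1,200 sites, HKY+Γ, true rate 2×10⁻³/site/year), infer
under HKY+Γ(8), map substitution counts, and fit the count distributions:

```python
from ratesweep import InferenceConfig, infer
from ratesweep.count_fit import Histogram, compare_fits, fit_negbin_chi2, fit_poisson_chi2
from ratesweep.mutation_counts import proportion_constant, stochastic_map_counts
from ratesweep.synthetic import preset, simulate_dataset

tree, aln = simulate_dataset(preset("flu_like"), seed=11)
cfg = InferenceConfig(model="HKY", rhas="gamma", k=8,
                      chain_length=20_000, sample_every=20, burn_in=0.3)
res = infer(aln, cfg, seed=1)
counts = stochastic_map_counts(aln, res.mean_tree, res.build_subst_model(),
                               res.build_site_model(), res.mu.mean,
                               realizations=100, seed=7)
h = Histogram.from_counts(counts.counts)
pfit, nfit = fit_poisson_chi2(h), fit_negbin_chi2(h)
```

Output:

```
simulated 20 tips x 1200 sites (265 unique patterns), true rate 0.002
log marginal likelihood (harmonic mean): -4874.2
clock rate: 1.83e-03 /site/year (95% CI 1.57e-03 - 2.11e-03)
root age:   95.2 years (95% CI 90.0 - 101.6; true 92.1)
gamma shape alpha: 0.27 (true 0.31)
constant sites (<0.5 mapped substitutions): 73.2%
Poisson GOF p = 1.19e-81; negative binomial shape = 0.27, dAIC = -492.0 (negbin preferred)
```

The credible intervals cover the generating rate and root age; the Poisson
fit is decisively rejected (there is strong RHAS), and the negative
binomial's shape agrees with the posterior α — the two independent routes
to the RHAS strength cross-validate.

For the headline experiment, sweep the number of gamma categories:

```bash
ratesweep sweep --alignment sim/alignment.fasta --k 3,4,6,8,10,16,24,32 \
    --pinv both --seed 1 --out sweep/
```

which writes one row per (k, ±I) cell with the log marginal likelihood and
posterior summaries for α, *p*<sub>inv</sub>, μ and the root age, plus a
panel plot. `ratesweep simulate / infer / mapcounts / fitcounts / daterand /
report` expose the other stages; every command takes `--seed`.

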