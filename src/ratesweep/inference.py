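"""High-level tip-dated inference: configuration, initialisation, one run.

``infer`` assembles the likelihood engine, a fixed starting topology (user
newick or UPGMA on Jukes-Cantor distances), rough initial values, and runs
the sampler.  The topology stays fixed throughout; with intraspecific data
the estimands of interest (clock rate, root age, RHAS parameters, marginal
likelihood trends) are robust to this, but it is a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .likelihood import LikelihoodEngine
from .mcmc import (
    Priors,
    Trace,
    PosteriorSummary,
    harmonic_mean_log_ml,
    run_mcmc,
    summarize,
)
from .seq_io import Alignment, ClockTree, read_tree
from .site_rate_models import compose_mixture
from .subst_models import SubstModel, exch_from_free, model_free_params

__all__ = ["InferenceConfig", "InferenceResult", "infer", "jc_distance_matrix", "initial_tree"]


@dataclass(frozen=True)
class InferenceConfig:
    model: str = "HKY"
    rhas: str = "gamma"
    k: int = 4
    alpha_init: float = 0.5
    pinv_init: float = 0.2
    representative: str = "mean"
    freqs: tuple | None = None  # None -> empirical (JC forces uniform)
    sample_exch: bool = True
    chain_length: int = 200_000
    sample_every: int = 100
    burn_in: float = 0.1
    tree_prior: str = "coalescent"
    root_calibration: tuple | None = None
    mu_init: float | None = None
    full_scale: bool = False

    def effective_chain(self) -> tuple[int, int]:
        if self.full_scale:
            return 20_000_000, 1000
        return self.chain_length, self.sample_every

    def with_rhas(self, rhas: str, k: int | None = None) -> "InferenceConfig":
        return replace(self, rhas=rhas, k=self.k if k is None else k)


def jc_distance_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise Jukes-Cantor distances over unambiguous site pairs."""
    codes = aln.codes
    unamb = np.isin(codes, (1, 2, 4, 8))
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = unamb[i] & unamb[j]
            m = both.sum()
            if m == 0:
                continue
            p = np.count_nonzero(codes[i, both] != codes[j, both]) / m
            p = min(p, 0.74)
            D[i, j] = D[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return D


def _mu_guess(aln: Alignment, D: np.ndarray, root_calibration) -> float:
    """Root-to-tip style slope of divergence on tip age; crude but adequate
    as a chain starting value."""
    ages = aln.ages
    mean_d = D[np.triu_indices(aln.n_taxa, 1)].mean() if aln.n_taxa > 1 else 0.0
    if ages.max() > 0:
        young = ages <= np.percentile(ages, 25)
        y = D[:, young].mean(axis=1)
        slope = np.polyfit(ages, y, 1)[0]
        if slope > 0:
            return float(np.clip(slope, 1e-11, 5e-2))
        return float(np.clip(mean_d / (2 * max(ages.max(), 1.0)), 1e-11, 5e-2))
    if root_calibration is not None:
        return float(np.clip(mean_d / (2 * max(root_calibration[0], 1.0)), 1e-11, 5e-2))
    return max(mean_d, 1e-4)


def initial_tree(aln: Alignment, mu_init: float) -> ClockTree:
    """Fixed starting topology: UPGMA on age-corrected JC distances.

    For serially sampled tips the path between tips i and j spans
    mu * (2*T_mrca - age_i - age_j), so an old tip looks artificially close
    and UPGMA's contemporaneity assumption misplaces it.  Adding
    mu_init * (age_i + age_j) makes every pairwise distance approximately
    2 * mu * T_mrca, i.e. ultrametric.  Node ages are the corrected heights
    converted by mu_init, pushed above the oldest descendant tip where
    necessary.
    """
    n = aln.n_taxa
    if n < 2:
        raise ValueError("need at least 2 taxa")
    D = jc_distance_matrix(aln)
    ages_pair = aln.ages[:, None] + aln.ages[None, :]
    Dc = D + mu_init * ages_pair
    np.fill_diagonal(Dc, 0.0)
    Z = linkage(squareform(Dc, checks=False), method="average")
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    ages = np.zeros(2 * n - 1)
    ages[:n] = aln.ages
    yscale = max(aln.ages.max(), Z[:, 2].max() / (2 * mu_init), 1.0)
    eps = 0.01 * yscale
    for i in range(n - 1):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        v = n + i
        parent[a] = parent[b] = v
        h_years = Z[i, 2] / (2.0 * mu_init)
        ages[v] = max(h_years, ages[a] + eps, ages[b] + eps)
    return ClockTree(list(aln.taxon_labels), parent, ages)


@dataclass
class InferenceResult:
    trace: Trace
    summaries: dict[str, PosteriorSummary]
    log_ml: float
    mean_tree: ClockTree
    config: InferenceConfig
    freqs: np.ndarray
    seed: int

    @property
    def mu(self) -> PosteriorSummary:
        return self.summaries["mu"]

    @property
    def root_age(self) -> PosteriorSummary:
        return self.summaries["root_age"]

    def posterior_mean_exch_free(self) -> np.ndarray:
        names = model_free_params(self.config.model)
        return np.array([self.summaries[f"exch_{nm}"].mean for nm in names])

    def build_subst_model(self) -> SubstModel:
        exch = exch_from_free(self.config.model, self.posterior_mean_exch_free())
        return SubstModel(self.config.model, exch, self.freqs)

    def build_site_model(self):
        cfg = self.config
        alpha = self.summaries["alpha"].mean if "alpha" in self.summaries else None
        p_inv = (
            self.summaries["p_inv"].mean
            if cfg.rhas in ("inv", "gamma_inv")
            else 0.0
        )
        return compose_mixture(cfg.rhas, alpha=alpha, p_inv=p_inv, k=cfg.k,
                               representative=cfg.representative)


def infer(
    aln: Alignment,
    config: InferenceConfig,
    seed: int = 1,
    tree: ClockTree | str | None = None,
) -> InferenceResult:
    """One full Bayesian run on an alignment; returns trace and summaries."""
    if config.model == "JC":
        freqs = np.full(4, 0.25)
    elif config.freqs is not None:
        freqs = np.asarray(config.freqs, dtype=float)
    else:
        freqs = aln.empirical_freqs()

    mu0 = config.mu_init
    D = None
    if mu0 is None:
        D = jc_distance_matrix(aln)
        mu0 = _mu_guess(aln, D, config.root_calibration)

    if tree is None:
        start = initial_tree(aln, mu0)
    elif isinstance(tree, ClockTree):
        start = tree.copy()
    else:
        start = read_tree(tree, tip_ages=dict(zip(aln.taxon_labels, aln.ages)))

    priors = Priors(root_calibration=config.root_calibration,
                    tree_prior=config.tree_prior)
    init = {
        "mu": mu0,
        "N": max(start.root_age / 2.0, 1e-2),
        "alpha": config.alpha_init,
        "p_inv": min(max(config.pinv_init, 1e-3), 0.97),
        "exch_free": np.full(len(model_free_params(config.model)), 2.0),
    }
    engine = LikelihoodEngine(aln)
    chain, every = config.effective_chain()
    trace = run_mcmc(
        engine, start, config.model, freqs, config.rhas, config.k,
        priors, init, chain, every, seed,
        representative=config.representative, sample_exch=config.sample_exch,
        adapt_fraction=config.burn_in,
    )
    summaries = summarize(trace, burn_in=config.burn_in, ess_warn=0.0)
    data, _ = trace.post_burn_in(config.burn_in)
    log_ml = harmonic_mean_log_ml(data["loglik"])
    return InferenceResult(
        trace=trace,
        summaries=summaries,
        log_ml=log_ml,
        mean_tree=trace.mean_tree(config.burn_in),
        config=config,
        freqs=freqs,
        seed=seed,
    )
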