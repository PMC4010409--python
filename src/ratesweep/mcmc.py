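"""Metropolis-Hastings sampling for the tip-dated strict-clock model.

The state is (mu, N, alpha, p_inv, exchangeabilities, node ages) with a
constant-size coalescent prior on the tree.  Topology is fixed; node-age and
root-age moves explore times only.  Scalar parameters use multiplicative
scale moves (p_inv moves on the logit scale).  Proposal step sizes adapt
towards a target acceptance rate during burn-in and are frozen afterwards so
the sampled portion of the chain is a valid Markov chain.

Default priors: mu and N log-uniform, alpha exponential with mean 1, p_inv
uniform on (0,1), free exchangeabilities log-normal(0,1).  An optional
normal calibration density can be placed on the root age (used for
isochronous data, where tip dates alone cannot calibrate the clock).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .likelihood import LikelihoodEngine
from .seq_io import ClockTree
from .site_rate_models import compose_mixture
from .subst_models import SubstModel, exch_from_free, model_free_params

__all__ = [
    "Priors",
    "Trace",
    "PosteriorSummary",
    "coalescent_log_prior",
    "run_mcmc",
    "summarize",
    "effective_sample_size",
    "harmonic_mean_log_ml",
]


def coalescent_log_prior(tree: ClockTree, N: float) -> float:
    """Log density of a serial-sample constant-size coalescent tree.

    Backward in time, lineages activate at their sampling ages; between
    events with j active lineages the waiting time is exponential with rate
    j(j-1)/(2N), and each coalescence contributes a factor 1/N (the per-pair
    rate).
    """
    if N <= 0:
        raise ValueError("N must be positive")
    tree.validate()
    n = tree.n_tips
    events = [(tree.ages[v], 0) for v in range(n)]
    events += [(tree.ages[v], 1) for v in range(n, tree.n_nodes)]
    events.sort()  # samplings (0) before coalescences (1) at equal age
    logp = 0.0
    j = 0
    t = events[0][0]
    for age, typ in events:
        dt = age - t
        if dt > 0:
            logp -= j * (j - 1) / 2.0 * dt / N
            t = age
        if typ == 0:
            j += 1
        else:
            j -= 1
            logp -= np.log(N)
    return float(logp)


@dataclass
class Priors:
    mu_bounds: tuple = (1e-12, 1e-1)
    n_bounds: tuple = (1e-3, 1e13)
    alpha_mean: float = 1.0
    alpha_bounds: tuple = (1e-3, 1e3)
    exch_sigma: float = 1.0
    exch_bounds: tuple = (1e-4, 1e4)
    root_calibration: tuple | None = None  # (mean, sd) normal density on root age
    tree_prior: str = "coalescent"  # or "none"

    def log_mu(self, mu):
        lo, hi = self.mu_bounds
        return -np.log(mu) if lo <= mu <= hi else -np.inf

    def log_n(self, N):
        lo, hi = self.n_bounds
        return -np.log(N) if lo <= N <= hi else -np.inf

    def log_alpha(self, alpha):
        lo, hi = self.alpha_bounds
        return -alpha / self.alpha_mean if lo <= alpha <= hi else -np.inf

    def log_exch(self, values):
        v = np.asarray(values, dtype=float)
        lo, hi = self.exch_bounds
        if v.size == 0:
            return 0.0
        if np.any(v < lo) or np.any(v > hi):
            return -np.inf
        lg = np.log(v)
        return float(np.sum(-lg - lg**2 / (2 * self.exch_sigma**2)))

    def log_root(self, root_age):
        if self.root_calibration is None:
            return 0.0
        m, s = self.root_calibration
        return -0.5 * ((root_age - m) / s) ** 2 - np.log(s)

    def log_tree(self, tree, N):
        out = self.log_root(tree.root_age)
        if self.tree_prior == "coalescent":
            out += coalescent_log_prior(tree, N)
        return out


@dataclass
class Trace:
    """Thinned MCMC samples plus per-sample node ages for the mean tree."""

    data: dict[str, np.ndarray]
    node_ages: np.ndarray  # (n_samples, n_nodes)
    tree_template: ClockTree
    sample_every: int
    chain_length: int
    seed: int

    def __getitem__(self, key):
        return self.data[key]

    @property
    def n_samples(self):
        return len(self.node_ages)

    def post_burn_in(self, burn_in: float = 0.1):
        cut = int(np.floor(self.n_samples * burn_in))
        return {k: v[cut:] for k, v in self.data.items()}, self.node_ages[cut:]

    def mean_tree(self, burn_in: float = 0.1) -> ClockTree:
        """Tree with posterior-mean node ages (ordering holds samplewise)."""
        _, ages = self.post_burn_in(burn_in)
        t = self.tree_template.copy()
        t.ages[:] = ages.mean(axis=0)
        return ClockTree(t.labels, t.parent, t.ages)


@dataclass
class PosteriorSummary:
    mean: float
    lower: float  # 2.5th percentile
    upper: float  # 97.5th percentile
    ess: float

    @property
    def ci_width(self):
        return self.upper - self.lower

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper


class _Move:
    def __init__(self, name, weight, scale=0.5):
        self.name = name
        self.weight = weight
        self.scale = scale
        self.proposed = 0
        self.accepted = 0
        self._window = [0, 0]

    def record(self, accepted, adapting, target=0.25):
        self.proposed += 1
        self.accepted += accepted
        self._window[0] += 1
        self._window[1] += accepted
        if adapting and self._window[0] >= 50:
            rate = self._window[1] / self._window[0]
            self.scale = float(np.clip(self.scale * np.exp(rate - target), 1e-4, 50.0))
            self._window = [0, 0]


def run_mcmc(
    engine: LikelihoodEngine | None,
    tree: ClockTree,
    model_name: str,
    freqs: np.ndarray,
    rhas_kind: str,
    k: int,
    priors: Priors,
    init: dict,
    chain_length: int,
    sample_every: int,
    seed: int,
    representative: str = "mean",
    sample_exch: bool = True,
    adapt_fraction: float = 0.1,
) -> Trace:
    """Run the sampler; deterministic for a given seed.

    ``engine=None`` switches the likelihood off (prior-only sampling).
    ``init`` supplies mu, N, alpha, p_inv and exch_free starting values.
    """
    rng = np.random.default_rng(seed)
    tree = tree.copy()
    n_tips = tree.n_tips

    mu = float(init.get("mu", 1e-3))
    N = float(init.get("N", max(tree.root_age, 1.0)))
    alpha = float(init.get("alpha", 0.5))
    p_inv = float(init.get("p_inv", 0.2))
    free_names = model_free_params(model_name)
    exch_free = np.asarray(
        init.get("exch_free", np.full(len(free_names), 2.0)), dtype=float
    )

    has_gamma = rhas_kind in ("gamma", "gamma_inv")
    has_inv = rhas_kind in ("inv", "gamma_inv")
    likelihood_on = engine is not None

    def make_subst():
        return SubstModel(model_name, exch_from_free(model_name, exch_free), freqs)

    def make_site():
        return compose_mixture(
            rhas_kind,
            alpha=alpha if has_gamma else None,
            p_inv=p_inv if has_inv else 0.0,
            k=k,
            representative=representative,
        )

    subst = make_subst()
    site = make_site()

    def loglik(t=None, m=None, sm=None, rm=None):
        if not likelihood_on:
            return 0.0
        return engine.log_likelihood(
            t if t is not None else tree,
            m if m is not None else mu,
            sm if sm is not None else subst,
            rm if rm is not None else site,
        )

    def scalar_prior():
        out = priors.log_mu(mu) + (priors.log_n(N) if priors.tree_prior == "coalescent" else 0.0)
        if has_gamma:
            out += priors.log_alpha(alpha)
        if sample_exch:
            out += priors.log_exch(exch_free)
        return out

    cur_ll = loglik()
    cur_scalar = scalar_prior()
    cur_tree = priors.log_tree(tree, N)
    if not np.isfinite(cur_ll + cur_scalar + cur_tree):
        raise ValueError("initial state has non-finite posterior")

    internal_nonroot = [
        v for v in range(n_tips, tree.n_nodes) if v != tree.root
    ]
    moves = [_Move("mu", 1.0, 0.5)]
    if priors.tree_prior == "coalescent":
        moves.append(_Move("N", 0.7, 0.8))
    if has_gamma:
        moves.append(_Move("alpha", 1.0, 0.6))
    if has_inv:
        moves.append(_Move("p_inv", 1.0, 0.8))
    if sample_exch and len(free_names):
        moves.append(_Move("exch", 0.8, 0.4))
    if internal_nonroot:
        moves.append(_Move("ages", max(1.0, 0.3 * len(internal_nonroot)), 0.0))
    moves.append(_Move("root", 1.0, 0.4))
    if likelihood_on and n_tips > 2:
        # joint rate-up/ages-down scale: mixes along the mu x time ridge,
        # which is by far the slowest posterior direction under a clock
        moves.append(_Move("updown", 2.0, 0.1))
    weights = np.array([m.weight for m in moves])
    weights = weights / weights.sum()

    adapt_until = int(adapt_fraction * chain_length)

    rec: dict[str, list] = {
        "iteration": [], "mu": [], "N": [], "alpha": [], "p_inv": [],
        "root_age": [], "loglik": [], "logprior": [],
    }
    for nm in free_names:
        rec[f"exch_{nm}"] = []
    ages_rec: list[np.ndarray] = []

    def record(it):
        rec["iteration"].append(it)
        rec["mu"].append(mu)
        rec["N"].append(N)
        rec["alpha"].append(alpha if has_gamma else np.nan)
        rec["p_inv"].append(p_inv if has_inv else 0.0)
        rec["root_age"].append(tree.root_age)
        rec["loglik"].append(cur_ll)
        rec["logprior"].append(cur_scalar + cur_tree)
        for i, nm in enumerate(free_names):
            rec[f"exch_{nm}"].append(exch_free[i])
        ages_rec.append(tree.ages.copy())

    move_idx = rng.choice(len(moves), size=chain_length, p=weights)
    for it in range(1, chain_length + 1):
        mv = moves[move_idx[it - 1]]
        adapting = it <= adapt_until
        accepted = False

        if mv.name == "mu":
            f = np.exp(mv.scale * (rng.random() - 0.5))
            new_mu = mu * f
            new_scalar = cur_scalar - priors.log_mu(mu) + priors.log_mu(new_mu)
            if np.isfinite(new_scalar):
                new_ll = loglik(m=new_mu)
                if _accept(rng, new_ll + new_scalar - cur_ll - cur_scalar + np.log(f)):
                    mu, cur_ll, cur_scalar = new_mu, new_ll, new_scalar
                    accepted = True

        elif mv.name == "N":
            f = np.exp(mv.scale * (rng.random() - 0.5))
            new_N = N * f
            new_scalar = cur_scalar - priors.log_n(N) + priors.log_n(new_N)
            if np.isfinite(new_scalar):
                new_tp = priors.log_tree(tree, new_N)
                if _accept(rng, new_scalar + new_tp - cur_scalar - cur_tree + np.log(f)):
                    N, cur_scalar, cur_tree = new_N, new_scalar, new_tp
                    accepted = True

        elif mv.name == "alpha":
            f = np.exp(mv.scale * (rng.random() - 0.5))
            new_alpha = alpha * f
            new_scalar = cur_scalar - priors.log_alpha(alpha) + priors.log_alpha(new_alpha)
            if np.isfinite(new_scalar):
                old_alpha = alpha
                alpha = new_alpha
                new_site = make_site()
                new_ll = loglik(rm=new_site)
                if _accept(rng, new_ll + new_scalar - cur_ll - cur_scalar + np.log(f)):
                    site, cur_ll, cur_scalar = new_site, new_ll, new_scalar
                    accepted = True
                else:
                    alpha = old_alpha

        elif mv.name == "p_inv":
            x = np.log(p_inv / (1 - p_inv)) + mv.scale * rng.normal()
            new_p = float(np.clip(1.0 / (1.0 + np.exp(-x)), 1e-12, 1 - 1e-12))
            logh = (np.log(new_p * (1 - new_p)) - np.log(p_inv * (1 - p_inv)))
            old_p = p_inv
            p_inv = new_p
            new_site = make_site()
            new_ll = loglik(rm=new_site)
            if _accept(rng, new_ll - cur_ll + logh):
                site, cur_ll = new_site, new_ll
                accepted = True
            else:
                p_inv = old_p

        elif mv.name == "exch":
            i = rng.integers(len(exch_free))
            f = np.exp(mv.scale * (rng.random() - 0.5))
            old = exch_free[i]
            exch_free[i] = old * f
            new_scalar = (
                cur_scalar
                - priors.log_exch(np.array([old]))
                + priors.log_exch(np.array([old * f]))
            )
            if np.isfinite(new_scalar):
                new_subst = make_subst()
                new_ll = loglik(sm=new_subst)
                if _accept(rng, new_ll + new_scalar - cur_ll - cur_scalar + np.log(f)):
                    subst, cur_ll, cur_scalar = new_subst, new_ll, new_scalar
                    accepted = True
                else:
                    exch_free[i] = old
            else:
                exch_free[i] = old

        elif mv.name == "ages":
            v = internal_nonroot[rng.integers(len(internal_nonroot))]
            lo = max(tree.ages[c] for c in tree.children[v])
            hi = tree.ages[tree.parent[v]]
            if hi > lo:
                old = tree.ages[v]
                tree.ages[v] = rng.uniform(lo, hi)
                new_tp = priors.log_tree(tree, N)
                new_ll = loglik()
                if _accept(rng, new_ll + new_tp - cur_ll - cur_tree):
                    cur_ll, cur_tree = new_ll, new_tp
                    accepted = True
                else:
                    tree.ages[v] = old

        elif mv.name == "root":
            r = tree.root
            lo = max(tree.ages[c] for c in tree.children[r])
            gap = tree.ages[r] - lo
            if gap > 0:
                f = np.exp(mv.scale * (rng.random() - 0.5))
                old = tree.ages[r]
                tree.ages[r] = lo + gap * f
                new_tp = priors.log_tree(tree, N)
                new_ll = loglik()
                if _accept(rng, new_ll + new_tp - cur_ll - cur_tree + np.log(f)):
                    cur_ll, cur_tree = new_ll, new_tp
                    accepted = True
                else:
                    tree.ages[r] = old

        elif mv.name == "updown":
            f = np.exp(mv.scale * (rng.random() - 0.5))
            new_mu = mu * f
            internal = slice(n_tips, tree.n_nodes)
            old_ages = tree.ages[internal].copy()
            tree.ages[internal] = old_ages / f
            valid = True
            for v in range(n_tips, tree.n_nodes):
                for c in tree.children[v]:
                    if tree.ages[v] < tree.ages[c]:
                        valid = False
                        break
                if not valid:
                    break
            new_scalar = cur_scalar - priors.log_mu(mu) + priors.log_mu(new_mu)
            if valid and np.isfinite(new_scalar):
                n_int = tree.n_nodes - n_tips
                logh = (1 - n_int) * np.log(f)
                new_tp = priors.log_tree(tree, N)
                new_ll = loglik(m=new_mu)
                if _accept(rng, new_ll + new_scalar + new_tp
                           - cur_ll - cur_scalar - cur_tree + logh):
                    mu, cur_ll, cur_scalar, cur_tree = (
                        new_mu, new_ll, new_scalar, new_tp)
                    accepted = True
                else:
                    tree.ages[internal] = old_ages
            else:
                tree.ages[internal] = old_ages

        mv.record(accepted, adapting)
        if it % sample_every == 0:
            record(it)

    for mv in moves:
        if mv.proposed >= 200 and mv.accepted == 0:
            warnings.warn(
                f"move {mv.name!r}: zero acceptance over {mv.proposed} proposals "
                "(poor mixing)", RuntimeWarning, stacklevel=2,
            )

    data = {k_: np.asarray(v) for k_, v in rec.items()}
    return Trace(
        data=data,
        node_ages=np.asarray(ages_rec),
        tree_template=tree,
        sample_every=sample_every,
        chain_length=chain_length,
        seed=seed,
    )


def _accept(rng, log_ratio: float) -> bool:
    if not np.isfinite(log_ratio):
        return False
    return log_ratio >= 0 or rng.random() < np.exp(log_ratio)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the integrated autocorrelation time (initial positive
    pair-sum truncation)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return np.nan
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    t = 0
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        s += pair
        t += 2
    tau = max(2.0 * s - 1.0, 1.0 / n)
    return float(n / tau)


def summarize(trace: Trace, burn_in: float = 0.1, ess_warn: float = 200.0) -> dict[str, PosteriorSummary]:
    """Posterior mean, central 95% credible interval and ESS per parameter."""
    data, _ = trace.post_burn_in(burn_in)
    out = {}
    for name, x in data.items():
        if name in ("iteration",):
            continue
        x = np.asarray(x, dtype=float)
        if np.all(np.isnan(x)):
            continue
        lo, hi = np.percentile(x, [2.5, 97.5])
        ess = effective_sample_size(x)
        out[name] = PosteriorSummary(float(np.mean(x)), float(lo), float(hi), ess)
    low = [n for n, s in out.items()
           if np.isfinite(s.ess) and s.ess < ess_warn and s.ci_width > 0]
    if low:
        warnings.warn(f"low ESS (<{ess_warn:g}) for: {', '.join(sorted(low))}",
                      RuntimeWarning, stacklevel=2)
    return out


def harmonic_mean_log_ml(logliks: np.ndarray) -> float:
    """Harmonic-mean marginal-likelihood estimator from posterior logL samples.

    Known to be upwardly biased and high-variance; retained because it is
    cheap and adequate for comparing RHAS treatments on the same data.
    """
    L = np.asarray(logliks, dtype=float)
    if len(L) < 10:
        raise ValueError("need at least 10 log-likelihood samples")
    return float(-(logsumexp(-L) - np.log(len(L))))
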