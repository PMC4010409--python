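"""Per-site substitution counts on a fixed clock tree.

Two inference routes are provided, and the pipeline reports both:

* Fitch small parsimony — the minimum number of state changes per site,
  with ambiguity codes contributing their full state sets;
* stochastic mutational mapping — for each site, a rate category is drawn
  from its posterior given the pattern, ancestral states are drawn from
  their joint conditional distribution, and substitution histories are
  sampled along each branch by uniformization conditioned on the endpoint
  states.  Counts are averaged over realizations and rounded half away
  from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .likelihood import LikelihoodEngine
from .seq_io import Alignment, ClockTree
from .site_rate_models import SiteRateModel
from .subst_models import SubstModel

__all__ = [
    "SiteCounts",
    "fitch_counts",
    "stochastic_map_counts",
    "proportion_constant",
    "sample_conditioned_counts",
]


@dataclass
class SiteCounts:
    counts: np.ndarray        # rounded integer counts, one per original site
    method: str               # "parsimony" or "stochastic_mapping"
    realizations: int = 1
    mean_counts: np.ndarray | None = None  # pre-rounding means (mapping only)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.mean_counts is None:
            self.mean_counts = self.counts.astype(float)


def fitch_counts(alignment: Alignment, tree: ClockTree) -> SiteCounts:
    """Minimum state changes per site (Fitch parsimony), all sites at once."""
    order = _tip_order(alignment, tree)
    pat = alignment.patterns[order]  # (ntips, npat) bitmasks
    npat = pat.shape[1]
    sets = np.zeros((tree.n_nodes, npat), dtype=np.uint8)
    changes = np.zeros(npat, dtype=np.int64)
    for v in tree.postorder:
        if v < tree.n_tips:
            sets[v] = pat[v]
            continue
        a, b = tree.children[v]
        inter = sets[a] & sets[b]
        union = sets[a] | sets[b]
        empty = inter == 0
        sets[v] = np.where(empty, union, inter)
        changes += empty
    per_site = changes[alignment.pattern_index]
    return SiteCounts(per_site, "parsimony")


def _tip_order(alignment: Alignment, tree: ClockTree) -> np.ndarray:
    index = {lb: i for i, lb in enumerate(alignment.taxon_labels)}
    try:
        return np.array([index[lb] for lb in tree.labels])
    except KeyError as exc:
        raise ValueError(f"tree taxon {exc.args[0]!r} not in alignment") from None


def stochastic_map_counts(
    alignment: Alignment,
    tree: ClockTree,
    subst_model: SubstModel,
    site_model: SiteRateModel,
    mu: float,
    realizations: int = 100,
    seed: int = 0,
) -> SiteCounts:
    """Posterior mean mapped substitution counts per site."""
    if realizations < 1:
        raise ValueError("realizations must be >= 1")
    rng = np.random.default_rng(seed)
    engine = LikelihoodEngine(alignment)
    partial, logscale, P = engine.full_pruning(tree, mu, subst_model, site_model)
    cat_ll = engine.category_site_logliks(tree, partial, logscale, subst_model)
    with np.errstate(divide="ignore"):
        logw = np.where(site_model.weights > 0, np.log(site_model.weights), -np.inf)
    logpost = logw[:, None] + cat_ll  # (ncat, npat)
    logpost -= logpost.max(axis=0, keepdims=True)
    cat_post = np.exp(logpost)
    cat_post /= cat_post.sum(axis=0, keepdims=True)

    S = alignment.n_sites
    pat_of_site = alignment.pattern_index
    site_cat_cdf = cat_post[:, pat_of_site].T.cumsum(axis=1)  # (S, ncat)

    durations = tree.durations()
    rates = site_model.rates
    sampler = _UniformizationSampler(subst_model)

    preorder = tree.postorder[::-1]
    total = np.zeros(S)
    root = tree.root
    pi = subst_model.freqs
    for _ in range(realizations):
        cat = (site_cat_cdf < rng.random(S)[:, None]).sum(axis=1)
        cat = np.clip(cat, 0, len(rates) - 1)
        states = np.empty((tree.n_nodes, S), dtype=np.int64)
        probs = pi[None, :] * partial[root][cat, pat_of_site, :]
        states[root] = _sample_rows(probs, rng)
        for v in preorder:
            if v == root:
                continue
            par = states[tree.parent[v]]
            rows = P[cat, v, par, :] * partial[v][cat, pat_of_site, :]
            states[v] = _sample_rows(rows, rng)
        for v in preorder:
            if v == root:
                continue
            d = mu * durations[v] * rates[cat]
            total += sampler.sample_counts(states[tree.parent[v]], states[v], d, rng)
    mean = total / realizations
    rounded = np.floor(mean + 0.5).astype(np.int64)
    return SiteCounts(rounded, "stochastic_mapping", realizations, mean)


def _sample_rows(probs: np.ndarray, rng) -> np.ndarray:
    """Categorical sample per row of an unnormalised (n, 4) matrix."""
    cdf = probs.cumsum(axis=1)
    tot = cdf[:, -1:]
    bad = tot[:, 0] <= 0
    if bad.any():  # impossible rows only arise from numerical underflow
        probs = probs.copy()
        probs[bad] = 0.25
        cdf = probs.cumsum(axis=1)
        tot = cdf[:, -1:]
    u = rng.random(len(probs))[:, None] * tot
    return np.clip((cdf < u).sum(axis=1), 0, 3)


class _UniformizationSampler:
    """Endpoint-conditioned substitution counts along a branch.

    With uniformization rate Omega = max_i(-Q_ii) and R = I + Q/Omega, the
    number of jumps n given endpoints (a, b) and distance d has
    P(n) proportional to Poisson(Omega d)(n) * (R^n)[a, b]; intermediate
    states of the jump chain are then drawn bridge-style and self-jumps are
    discarded from the count.
    """

    def __init__(self, subst_model: SubstModel, nmax: int = 256):
        Q = subst_model.Q
        self.omega = float(-Q.diagonal().min())
        self.R = np.eye(4) + Q / self.omega
        self.nmax = nmax
        self._powers = [np.eye(4), self.R.copy()]
        self.model = subst_model

    def _rpow(self, n: int) -> np.ndarray:
        while len(self._powers) <= n:
            self._powers.append(self._powers[-1] @ self.R)
        return self._powers[n]

    def _jump_dist(self, a: int, b: int, od: float) -> np.ndarray:
        """P(n jumps | a, b) for n = 0..ncut, unnormalised then normalised."""
        ncut = min(self.nmax, max(8, int(od + 8 * np.sqrt(od) + 8)))
        logpois = stats.poisson.logpmf(np.arange(ncut + 1), od)
        vals = np.array([self._rpow(n)[a, b] for n in range(ncut + 1)])
        with np.errstate(divide="ignore"):
            w = np.exp(logpois + np.log(np.where(vals > 0, vals, 1e-300)))
        w[vals <= 0] = 0.0
        tot = w.sum()
        if tot <= 0:  # endpoint pair essentially impossible; treat as direct
            w = np.zeros(ncut + 1)
            w[1 if a != b else 0] = 1.0
            tot = 1.0
        return w / tot

    def sample_counts(self, a: np.ndarray, b: np.ndarray, d: np.ndarray, rng) -> np.ndarray:
        """Vectorised over sites sharing this branch; d may vary per site."""
        S = len(a)
        out = np.zeros(S)
        if self.omega <= 0:
            return out
        od = self.omega * np.asarray(d, dtype=float)
        # group sites by (distance value, endpoints); distances come from a
        # small set of category rates, so groups are few
        keys = np.stack([od, a.astype(float), b.astype(float)], axis=1)
        uniq, inv = np.unique(keys, axis=0, return_inverse=True)
        inv = inv.ravel()
        n_jumps = np.zeros(S, dtype=np.int64)
        for g, (odv, av, bv) in enumerate(uniq):
            members = np.flatnonzero(inv == g)
            if odv <= 0:
                continue
            w = self._jump_dist(int(av), int(bv), odv)
            cdf = np.cumsum(w)
            n_jumps[members] = np.searchsorted(cdf, rng.random(len(members)))
        # real substitutions: walk the jump chain for n >= 2; n<=1 is direct
        out[(n_jumps == 1) & (a != b)] = 1.0
        multi = np.flatnonzero(n_jumps >= 2)
        for s in multi:
            out[s] = self._count_real_jumps(int(a[s]), int(b[s]), int(n_jumps[s]), rng)
        return out

    def _count_real_jumps(self, a: int, b: int, n: int, rng) -> int:
        real = 0
        x = a
        for t in range(1, n):
            probs = self.R[x] * self._rpow(n - t)[:, b]
            tot = probs.sum()
            if tot <= 0:
                nxt = b
            else:
                nxt = int(np.searchsorted(np.cumsum(probs / tot), rng.random()))
                nxt = min(nxt, 3)
            real += nxt != x
            x = nxt
        real += x != b
        return real


def sample_conditioned_counts(subst_model, a, b, distance, n_draws, rng) -> np.ndarray:
    """Draws of the substitution count on a single branch with fixed
    endpoints; exposed for distribution checks against direct simulation."""
    sampler = _UniformizationSampler(subst_model)
    aa = np.full(n_draws, a, dtype=np.int64)
    bb = np.full(n_draws, b, dtype=np.int64)
    dd = np.full(n_draws, float(distance))
    # draw one at a time to avoid the shared-jump-count grouping shortcut
    out = np.empty(n_draws)
    for i in range(n_draws):
        out[i] = sampler.sample_counts(aa[i : i + 1], bb[i : i + 1], dd[i : i + 1], rng)[0]
    return out


def proportion_constant(counts: SiteCounts, threshold: float = 0.5) -> float:
    """Fraction of sites whose (pre-rounding) mapped mean count is below
    ``threshold``."""
    return float(np.mean(counts.mean_counts < threshold))
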