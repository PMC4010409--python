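"""Poisson and negative-binomial fits to site substitution-count histograms.

Without rate heterogeneity among sites, per-site substitution counts should
be Poisson; with gamma-distributed rates they should be negative binomial,
whose shape parameter estimates the gamma shape alpha.  Both families are
fitted by minimising the chi-squared statistic over pooled count bins, and
compared by goodness-of-fit P value and by AIC.

Binning: one bin per count value, pooled from the upper tail until every
bin's expected count is at least 5 under a moment-matched Poisson reference;
the same binning is shared by both families so the fits are nested.  The
AIC uses the exact unpooled per-site log-likelihood evaluated at the
chi-squared-minimising parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["Histogram", "DistFit", "fit_poisson_chi2", "fit_negbin_chi2", "compare_fits"]

_MIN_SITES = 20
_ALPHA_MAX = 1e6  # negbin -> Poisson limit


@dataclass
class Histogram:
    """Counts-of-counts: frequencies[v] = number of sites with count v."""

    frequencies: np.ndarray

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=np.int64)

    @classmethod
    def from_counts(cls, counts) -> "Histogram":
        counts = np.asarray(counts, dtype=np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        return cls(np.bincount(counts))

    @property
    def total(self) -> int:
        return int(self.frequencies.sum())

    @property
    def mean(self) -> float:
        v = np.arange(len(self.frequencies))
        return float((v * self.frequencies).sum() / self.total)

    @property
    def variance(self) -> float:
        v = np.arange(len(self.frequencies))
        m = self.mean
        return float((self.frequencies * (v - m) ** 2).sum() / self.total)


@dataclass
class DistFit:
    family: str
    params: dict
    chi2: float
    dof: int
    p_value: float
    aic: float
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    flag: str | None = None  # "untestable", "failed", ...

    @property
    def ok(self) -> bool:
        return self.flag is None


def _pool_edges(hist: Histogram) -> np.ndarray:
    """Bin start values [v0, v1, ...]; bin i covers [v_i, v_{i+1}), the last
    bin is open-ended.  Pooled from the tail so each bin's expected count is
    >= 5 under Poisson(sample mean)."""
    S = hist.total
    lam = max(hist.mean, 1e-9)
    vmax = len(hist.frequencies) - 1
    # expected counts per single value under the reference
    uppers = []
    cut = 0
    for v in range(vmax + 1):
        exp_tail = S * stats.poisson.sf(v - 1, lam)  # expected in [v, inf)
        exp_here = S * stats.poisson.pmf(v, lam)
        if exp_tail < 5 or exp_here < 5:
            break
        cut = v
    edges = np.arange(cut + 1)
    return edges if len(edges) else np.array([0])


def _binned_expected(pmf_cdf, edges: np.ndarray, S: int) -> np.ndarray:
    """Expected counts per pooled bin; last bin open-ended."""
    pmf, cdf = pmf_cdf
    exp = np.empty(len(edges))
    for i, v in enumerate(edges[:-1]):
        lo, hi = edges[i], edges[i + 1]
        exp[i] = S * (cdf(hi - 1) - (cdf(lo - 1) if lo > 0 else 0.0))
    last = edges[-1]
    exp[-1] = S * (1.0 - (cdf(last - 1) if last > 0 else 0.0))
    return np.maximum(exp, 1e-12)


def _binned_observed(hist: Histogram, edges: np.ndarray) -> np.ndarray:
    freq = hist.frequencies
    obs = np.empty(len(edges), dtype=np.int64)
    for i in range(len(edges) - 1):
        obs[i] = freq[edges[i] : edges[i + 1]].sum()
    obs[-1] = freq[edges[-1] :].sum()
    return obs


def _chi2_stat(obs, exp) -> float:
    return float(np.sum((obs - exp) ** 2 / exp))


def _poisson_pmf_cdf(lam):
    return (lambda v: stats.poisson.pmf(v, lam), lambda v: stats.poisson.cdf(v, lam))


def _negbin_pmf_cdf(m, a):
    # scipy's nbinom: n = shape a, p = a / (a + m)
    p = a / (a + m)
    return (lambda v: stats.nbinom.pmf(v, a, p), lambda v: stats.nbinom.cdf(v, a, p))


def fit_poisson_chi2(hist: Histogram) -> DistFit:
    """Chi-squared-minimising Poisson fit with tail pooling."""
    S = hist.total
    if S < _MIN_SITES:
        raise ValueError(f"need at least {_MIN_SITES} sites, got {S}")
    if hist.mean == 0:
        return DistFit("poisson", {"lam": 0.0}, 0.0, 0, np.nan, np.nan,
                       np.array([0]), flag="untestable")
    edges = _pool_edges(hist)
    obs = _binned_observed(hist, edges)
    if len(edges) < 2:
        return DistFit("poisson", {"lam": hist.mean}, 0.0, 0, np.nan, np.nan,
                       edges, flag="untestable")

    def objective(lam):
        return _chi2_stat(obs, _binned_expected(_poisson_pmf_cdf(lam), edges, S))

    res = optimize.minimize_scalar(
        objective, bounds=(1e-9, max(10 * hist.mean, 1.0)), method="bounded"
    )
    lam = float(res.x)
    chi2 = float(res.fun)
    dof = len(edges) - 1 - 1
    p = float(stats.chi2.sf(chi2, dof)) if dof >= 1 else np.nan
    lnl = _unpooled_loglik(hist, _poisson_pmf_cdf(lam)[0])
    aic = 2 * 1 - 2 * lnl
    flag = None if dof >= 1 else "untestable"
    return DistFit("poisson", {"lam": lam}, chi2, dof, p, aic, edges, flag)


def fit_negbin_chi2(hist: Histogram) -> DistFit:
    """Joint chi-squared minimisation over (mean m, shape alpha).

    Nelder-Mead in log space from a moment start, with a log-spaced grid
    fallback and the Poisson-limit candidate (alpha at its upper bound) so
    the negative binomial never fits worse than the Poisson on shared bins.
    """
    S = hist.total
    if S < _MIN_SITES:
        raise ValueError(f"need at least {_MIN_SITES} sites, got {S}")
    if hist.variance == 0 or hist.mean == 0:
        return DistFit("negbin", {"m": hist.mean, "alpha": np.nan}, 0.0, 0,
                       np.nan, np.nan, np.array([0]), flag="untestable")
    edges = _pool_edges(hist)
    obs = _binned_observed(hist, edges)
    if len(edges) < 2:
        return DistFit("negbin", {"m": hist.mean, "alpha": np.nan}, 0.0, 0,
                       np.nan, np.nan, edges, flag="untestable")

    def objective(logparams):
        m, a = np.exp(logparams)
        if not (1e-9 < m < 1e6) or not (1e-6 < a <= _ALPHA_MAX):
            return 1e12
        return _chi2_stat(obs, _binned_expected(_negbin_pmf_cdf(m, a), edges, S))

    mean, var = hist.mean, hist.variance
    a0 = mean**2 / (var - mean) if var > mean else _ALPHA_MAX / 10
    a0 = float(np.clip(a0, 1e-4, _ALPHA_MAX))
    candidates = [np.log([mean, a0])]
    # Poisson-limit start and fallback grid
    candidates.append(np.log([mean, _ALPHA_MAX]))
    best = None
    for x0 in candidates:
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        grid_m = np.geomspace(max(mean / 10, 1e-6), mean * 10, 10)
        grid_a = np.geomspace(1e-3, _ALPHA_MAX, 10)
        vals = [(objective(np.log([m, a])), m, a) for m in grid_m for a in grid_a]
        fv, m, a = min(vals)
        if not np.isfinite(fv):
            return DistFit("negbin", {"m": np.nan, "alpha": np.nan}, np.nan, 0,
                           np.nan, np.nan, edges, flag="failed")
        best = optimize.minimize(objective, np.log([m, a]), method="Nelder-Mead")
    m, a = np.exp(best.x)
    chi2 = float(best.fun)
    dof = len(edges) - 1 - 2
    p = float(stats.chi2.sf(chi2, dof)) if dof >= 1 else np.nan
    lnl = _unpooled_loglik(hist, _negbin_pmf_cdf(m, a)[0])
    aic = 2 * 2 - 2 * lnl
    flag = None if dof >= 1 else "untestable"
    return DistFit("negbin", {"m": float(m), "alpha": float(a)}, chi2, dof, p,
                   aic, edges, flag)


def _unpooled_loglik(hist: Histogram, pmf) -> float:
    v = np.arange(len(hist.frequencies))
    mask = hist.frequencies > 0
    with np.errstate(divide="ignore"):
        lp = np.log(np.maximum(pmf(v[mask]), 1e-300))
    return float((hist.frequencies[mask] * lp).sum())


@dataclass
class FitComparison:
    delta_aic: float          # AIC(negbin) - AIC(poisson)
    p_poisson: float
    p_negbin: float
    p_ratio: float            # P(negbin) / P(poisson)
    preferred: str
    flag: str | None = None


def compare_fits(poisson_fit: DistFit, negbin_fit: DistFit) -> FitComparison:
    """AIC and P-value comparison of the two fits."""
    if not (poisson_fit.ok and negbin_fit.ok):
        return FitComparison(np.nan, poisson_fit.p_value, negbin_fit.p_value,
                             np.nan, "none", flag="flagged_fit")
    delta = negbin_fit.aic - poisson_fit.aic
    pp, pn = poisson_fit.p_value, negbin_fit.p_value
    flag = None
    if pp < 1e-12 and pn < 1e-12:
        ratio = np.nan
        flag = "p_ratio_ill_conditioned"
    else:
        ratio = pn / pp if pp > 0 else np.inf
    preferred = "negbin" if delta < 0 else "poisson"
    return FitComparison(float(delta), pp, pn, ratio, preferred, flag)
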