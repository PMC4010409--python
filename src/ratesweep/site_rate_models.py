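"""Among-site rate-heterogeneity (RHAS) models as discrete rate mixtures.

Four treatments: equal rates, discrete gamma with k equal-probability
categories (+G), invariable sites (+I), and their mixture (+G+I).  Every
model is reduced to category rates r_c and weights w_c with sum(w) = 1 and
sum(w*r) = 1, so the clock rate stays identifiable across treatments.

The discrete gamma uses equal-percentile bins of the unit-mean gamma
distribution; each bin is represented by its conditional mean (default) or
its median.  With invariable sites, the gamma rates are inflated by
1/(1 - p_inv) so the overall mean stays 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = ["SiteRateModel", "discretize_gamma", "compose_mixture", "RHAS_KINDS"]

RHAS_KINDS = ("equal", "gamma", "inv", "gamma_inv")


def discretize_gamma(alpha: float, k: int, representative: str = "mean"):
    """Rates and weights of the k-category discrete unit-mean gamma.

    The gamma with shape ``alpha`` and mean 1 is cut into k bins of equal
    probability 1/k.  With ``representative="mean"`` each category rate is
    the bin's conditional mean, which leaves the overall mean exactly 1.
    With ``"median"`` the mid-quantile of each bin is used and the rates are
    rescaled to mean 1 afterwards.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    k = int(k)
    if k < 1:
        raise ValueError("k must be >= 1")
    weights = np.full(k, 1.0 / k)
    if k == 1:
        return np.array([1.0]), weights
    if representative == "mean":
        # X ~ Gamma(alpha, theta=1/alpha); edges at quantiles i/k.
        # E[X; (lo,hi)] = P(alpha+1, hi*alpha) - P(alpha+1, lo*alpha)
        # (regularised lower incomplete gamma), so the conditional mean of a
        # 1/k-probability bin is k times that difference.
        probs = np.linspace(0.0, 1.0, k + 1)
        edges = special.gammaincinv(alpha, probs[1:-1])
        upper = np.concatenate([special.gammainc(alpha + 1, edges), [1.0]])
        lower = np.concatenate([[0.0], special.gammainc(alpha + 1, edges)])
        rates = k * (upper - lower)
    elif representative == "median":
        mid = (2 * np.arange(k) + 1) / (2.0 * k)
        rates = special.gammaincinv(alpha, mid) / alpha
        rates = rates / (weights @ rates)
    else:
        raise ValueError("representative must be 'mean' or 'median'")
    return rates, weights


@dataclass(frozen=True)
class SiteRateModel:
    kind: str
    k: int
    alpha: float | None
    p_inv: float
    representative: str
    rates: np.ndarray
    weights: np.ndarray

    @property
    def n_categories(self) -> int:
        return len(self.rates)

    def with_params(self, alpha: float | None = None, p_inv: float | None = None) -> "SiteRateModel":
        """Same kind/k/representative with updated shape and p_inv."""
        return compose_mixture(
            self.kind,
            alpha=self.alpha if alpha is None else alpha,
            p_inv=self.p_inv if p_inv is None else p_inv,
            k=self.k,
            representative=self.representative,
        )


def compose_mixture(
    kind: str,
    alpha: float | None = None,
    p_inv: float = 0.0,
    k: int = 4,
    representative: str = "mean",
) -> SiteRateModel:
    """Build a SiteRateModel of the requested kind.

    gamma_inv places weight p_inv on a rate-0 category and (1-p_inv)/k on
    each gamma category, whose rates are divided by (1-p_inv) so the
    mixture mean is 1.
    """
    if kind not in RHAS_KINDS:
        raise ValueError(f"unknown RHAS kind {kind!r}")
    if kind in ("equal", "gamma") and p_inv != 0.0:
        raise ValueError(f"p_inv must be 0 for kind={kind!r}")
    if kind in ("inv", "gamma_inv") and not (0.0 <= p_inv < 1.0):
        raise ValueError("p_inv must lie in [0, 1)")

    if kind == "equal":
        return SiteRateModel("equal", 1, None, 0.0, representative,
                             np.array([1.0]), np.array([1.0]))
    if kind == "inv":
        rates = np.array([0.0, 1.0 / (1.0 - p_inv)])
        weights = np.array([p_inv, 1.0 - p_inv])
        return SiteRateModel("inv", 1, None, p_inv, representative, rates, weights)
    if alpha is None:
        raise ValueError("gamma kinds require alpha")
    g_rates, g_weights = discretize_gamma(alpha, k, representative)
    if kind == "gamma":
        return SiteRateModel("gamma", k, alpha, 0.0, representative, g_rates, g_weights)
    rates = np.concatenate([[0.0], g_rates / (1.0 - p_inv)])
    weights = np.concatenate([[p_inv], (1.0 - p_inv) * g_weights])
    return SiteRateModel("gamma_inv", k, alpha, p_inv, representative, rates, weights)
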