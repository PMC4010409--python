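"""Independent reference implementations used only to check the package.

Everything here is deliberately brute-force: likelihoods by exhaustive
enumeration of ancestral states, gamma bin means by adaptive quadrature,
continuous-gamma mixing by generalised Gauss-Laguerre quadrature.  None of
it shares code with the implementations it validates.
"""

import numpy as np
from scipy import integrate, special, stats


def enumeration_log_likelihood(tree, alignment, subst_model, site_model, mu):
    """Sum over all ancestral state assignments, site by site.

    L(site) = sum_c w_c sum_{internal states} pi(root) *
              prod_branches P_c[parent_state, child_state](mu * dur * r_c)
    Tip states are summed over the states compatible with the (possibly
    ambiguous) observed code.
    """
    tip_index = {lb: i for i, lb in enumerate(alignment.taxon_labels)}
    internals = [v for v in range(tree.n_tips, tree.n_nodes)]
    dur = tree.durations()
    total = 0.0
    for s in range(alignment.n_sites):
        site_lik = 0.0
        for c in range(site_model.n_categories):
            w = site_model.weights[c]
            if w == 0:
                continue
            P = {}
            for v in range(tree.n_nodes):
                if v != tree.root:
                    P[v] = subst_model.transition_probs(
                        mu * dur[v] * site_model.rates[c]
                    )
            cat_lik = 0.0
            for assign in np.ndindex(*(4,) * len(internals)):
                states = dict(zip(internals, assign))
                # tips: sum over compatible states
                prob = subst_model.freqs[states[tree.root]]
                ok = True
                for v in range(tree.n_nodes):
                    if v == tree.root:
                        continue
                    p_state = states[tree.parent[v]]
                    if v < tree.n_tips:
                        code = alignment.codes[tip_index[tree.labels[v]], s]
                        comp = [b for b in range(4) if code >> b & 1]
                        prob *= sum(P[v][p_state, b] for b in comp)
                    else:
                        prob *= P[v][p_state, states[v]]
                    if prob == 0.0:
                        ok = False
                        break
                if ok:
                    cat_lik += prob
            site_lik += w * cat_lik
        total += np.log(site_lik)
    return total


def quadrature_gamma_bin_means(alpha, k):
    """Conditional means of equal-probability bins of the unit-mean gamma,
    by adaptive quadrature on each quantile bin."""
    qs = np.linspace(0, 1, k + 1)
    edges = stats.gamma.ppf(qs, alpha, scale=1.0 / alpha)
    means = np.empty(k)
    pdf = lambda x: stats.gamma.pdf(x, alpha, scale=1.0 / alpha)
    for i in range(k):
        lo, hi = edges[i], edges[i + 1]
        if not np.isfinite(hi):
            hi = stats.gamma.ppf(1 - 1e-13, alpha, scale=1.0 / alpha)
        num, _ = integrate.quad(lambda x: x * pdf(x), lo, hi, limit=200)
        means[i] = num * k  # each bin has probability 1/k
    return means


def gauss_laguerre_continuous_gamma_loglik(engine, tree, mu, subst_model,
                                           alpha, n_nodes_quad=80):
    """Continuous-gamma mixture likelihood via generalised Gauss-Laguerre.

    With rate r = x / alpha and x ~ Gamma(alpha, 1),
    integral f(r) L(r) dr = (1/Gamma(alpha)) * sum_i w_i L(x_i / alpha)
    for nodes/weights of the generalised Laguerre rule with exponent
    alpha - 1.
    """
    from ratesweep.site_rate_models import SiteRateModel

    x, w = special.roots_genlaguerre(n_nodes_quad, alpha - 1)
    rates = x / alpha
    # per-pattern likelihood at each fixed rate: use a single-category model
    pat_logliks = np.empty((len(rates), engine.n_patterns))
    for i, r in enumerate(rates):
        srm = SiteRateModel("equal", 1, None, 0.0, "mean",
                            np.array([r]), np.array([1.0]))
        pat_logliks[i] = engine.pattern_log_likelihoods(tree, mu, subst_model, srm)
    logw = np.log(w) - special.gammaln(alpha)
    mixed = special.logsumexp(pat_logliks + logw[:, None], axis=0)
    return float(engine.pattern_weights @ mixed)
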