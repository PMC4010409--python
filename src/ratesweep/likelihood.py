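"""Alignment likelihood on a tip-dated clock tree (pruning algorithm).

The distance handed to the substitution model for a branch is
mu * duration_in_years * r_c, where r_c is the rate of the mixture category.
Category contributions are combined per site pattern as
sum_c w_c L_c(pattern); per-node rescaling keeps partial likelihoods in
range for long alignments.

Gaps and ambiguity codes are treated as partial observations: the tip
partial is an indicator over the compatible states.  An invariable (rate-0)
category therefore contributes to any pattern for which a single state is
compatible with every tip.  No ascertainment correction is applied; full
alignments, constant columns included, are analysed as observed.
"""

from __future__ import annotations

import numpy as np

from ._kernels import prune_loglik
from .seq_io import Alignment, ClockTree
from .site_rate_models import SiteRateModel
from .subst_models import SubstModel

__all__ = ["LikelihoodEngine"]


class LikelihoodEngine:
    """Caches tip partials for one alignment; evaluates tree likelihoods.

    Tip partials are stored in the engine's own taxon order and permuted to
    each tree's tip order by label at evaluation time.
    """

    def __init__(self, alignment: Alignment):
        self.alignment = alignment
        self._tip_partials = alignment.tip_partials()  # (ntaxa, npat, 4)
        self._label_index = {lb: i for i, lb in enumerate(alignment.taxon_labels)}
        self.n_patterns = alignment.n_patterns
        self.pattern_weights = alignment.pattern_weights.astype(float)
        self._ws: dict[tuple, tuple] = {}  # (n_nodes, ncat) -> work arrays
        self._tree_cache: dict[int, tuple] = {}  # per-topology tip data

    def _tip_order(self, tree: ClockTree) -> np.ndarray:
        try:
            return np.array([self._label_index[lb] for lb in tree.labels])
        except KeyError as exc:
            raise ValueError(f"tree taxon {exc.args[0]!r} not in alignment") from None

    def log_likelihood(
        self,
        tree: ClockTree,
        mu: float,
        subst_model: SubstModel,
        site_model: SiteRateModel,
    ) -> float:
        if mu <= 0:
            raise ValueError("clock rate mu must be positive")
        P, _ = self._branch_probs(tree, mu, subst_model, site_model)
        key = id(tree.labels)
        cached = self._tree_cache.get(key)
        if cached is None or cached[0] != tree.labels:
            order = self._tip_order(tree)
            # (ntips, 4, npat): state-major so kernel inner loops vectorise
            tipPT = np.ascontiguousarray(
                self._tip_partials[order].transpose(0, 2, 1))
            children = np.full((tree.n_nodes, 2), -1, dtype=np.int64)
            for v in range(tree.n_tips, tree.n_nodes):
                children[v] = tree.children[v]
            cached = (list(tree.labels), tipPT, children)
            self._tree_cache[key] = cached
        _, tipPT, children = cached
        ncat = site_model.n_categories
        wkey = ("kernel", tree.n_nodes, ncat)
        if wkey not in self._ws:
            self._ws[wkey] = (
                np.empty((tree.n_nodes, ncat, 4, self.n_patterns)),
                np.empty((ncat, self.n_patterns)),
                [None],  # id of the tip data last written into this buffer
            )
        partial, logscale, tip_marker = self._ws[wkey]
        # tipPT is kept alive by _tree_cache, so its id is a stable token
        write_tips = tip_marker[0] != id(tipPT)
        total = prune_loglik(
            tree.postorder, children, tree.n_tips, tree.root,
            np.ascontiguousarray(P), site_model.weights, subst_model.freqs,
            self.pattern_weights, partial, logscale, write_tips, tipPT,
        )
        tip_marker[0] = id(tipPT)
        total = float(total)
        if np.isnan(total):
            raise FloatingPointError("non-finite log-likelihood")
        return total

    # -- internals ---------------------------------------------------------

    def _branch_probs(self, tree, mu, subst_model, site_model):
        """(ncat, nnodes, 4, 4) transition matrices for every branch/category."""
        dur = tree.durations()
        dist = mu * np.multiply.outer(site_model.rates, dur)  # (ncat, nnodes)
        P = subst_model.transition_probs_many(dist.reshape(-1))
        return P.reshape(dist.shape + (4, 4)), dist

    def _prune(self, tree, mu, subst_model, site_model):
        ncat = site_model.n_categories
        npat = self.n_patterns
        P, _ = self._branch_probs(tree, mu, subst_model, site_model)
        order = self._tip_order(tree)
        key = ("numpy", tree.n_nodes, ncat)
        if key not in self._ws:
            self._ws[key] = (
                np.empty((tree.n_nodes, ncat, npat, 4)),
                np.empty((tree.n_nodes, ncat, npat)),
            )
        partial, logscale = self._ws[key]
        logscale.fill(0.0)
        tipP = self._tip_partials[order]  # (ntips, npat, 4)
        # rescaling every node is wasteful; every few levels keeps partials
        # far from the underflow threshold (values shrink ~1e-4/level at worst)
        scale_interval = 8
        n_internal = 0
        for v in tree.postorder:
            if v < tree.n_tips:
                partial[v] = tipP[v][None, :, :]
                continue
            c0, c1 = tree.children[v]
            # down[c,p,i] = sum_j P[cat, branch][i, j] * partial_child[c,p,j]
            acc = np.matmul(partial[c0], P[:, c0].transpose(0, 2, 1))
            acc *= np.matmul(partial[c1], P[:, c1].transpose(0, 2, 1))
            sc = logscale[c0] + logscale[c1]
            n_internal += 1
            if n_internal % scale_interval == 0 or v == tree.root:
                m = acc.max(axis=2)
                safe = np.where(m > 0, m, 1.0)
                acc = acc / safe[:, :, None]
                with np.errstate(divide="ignore"):
                    sc = sc + np.where(m > 0, np.log(safe), -np.inf)
            partial[v] = acc
            logscale[v] = sc
        return partial, logscale, P

    def _root_site_logliks(self, tree, partial, logscale, subst_model, site_model):
        """(npat,) per-pattern log-likelihoods mixed over categories."""
        root = tree.root
        site = partial[root] @ subst_model.freqs  # (ncat, npat)
        with np.errstate(divide="ignore"):
            logs = np.log(site) + logscale[root]
            logw = np.log(np.where(site_model.weights > 0, site_model.weights, 1.0))
            logs = logs + np.where(site_model.weights > 0, logw, -np.inf)[:, None]
        mx = logs.max(axis=0)
        mx = np.where(np.isfinite(mx), mx, 0.0)
        out = mx + np.log(np.exp(logs - mx[None, :]).sum(axis=0))
        return out

    def pattern_log_likelihoods(self, tree, mu, subst_model, site_model):
        partial, logscale, _ = self._prune(tree, mu, subst_model, site_model)
        return self._root_site_logliks(tree, partial, logscale, subst_model, site_model)

    def full_pruning(self, tree, mu, subst_model, site_model):
        """Partials, scale logs and branch matrices, for stochastic mapping."""
        partial, logscale, P = self._prune(tree, mu, subst_model, site_model)
        return partial, logscale, P

    def category_site_logliks(self, tree, partial, logscale, subst_model):
        """(ncat, npat) unweighted per-category log site likelihoods."""
        root = tree.root
        site = partial[root] @ subst_model.freqs
        with np.errstate(divide="ignore"):
            return np.log(site) + logscale[root]
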