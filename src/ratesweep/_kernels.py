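"""Compiled pruning kernel.

The MCMC evaluates the pruning likelihood tens of thousands of times per
run; this kernel fuses the per-node loops that dominate that cost.  The
pure-numpy implementation in ``likelihood`` remains the reference (and the
path used when numba is unavailable); the two are asserted equal in the
test suite.

Layout: partials are stored (node, category, state, pattern) so the inner
loops run over contiguous patterns and vectorise.  Because only the root
likelihood is returned, rescaling factors from any node can be accumulated
in one (category, pattern) matrix: each factor propagates multiplicatively
to the root exactly once.  Rescaling runs every eighth internal node, which
keeps partials far from the underflow threshold at any tree size.
"""

from __future__ import annotations

import numpy as np

try:
    import numba as _nb

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally installed
    _nb = None
    HAVE_NUMBA = False


def _prune_loglik_py(postorder, children, n_tips, root, P, weights,
                     freqs, patw, partial, logscale, write_tips, tipPT):
    ncat = P.shape[0]
    nnodes = children.shape[0]
    npat = partial.shape[3]
    for c in range(ncat):
        for p in range(npat):
            logscale[c, p] = 0.0
    if write_tips:
        for v in range(n_tips):
            for c in range(ncat):
                for i in range(4):
                    for p in range(npat):
                        partial[v, c, i, p] = tipPT[v, i, p]
    n_internal = 0
    for oi in range(nnodes):
        v = postorder[oi]
        if v < n_tips:
            continue
        c0 = children[v, 0]
        c1 = children[v, 1]
        n_internal += 1
        do_scale = (n_internal % 8 == 0) or v == root
        for c in range(ncat):
            P0 = P[c, c0]
            P1 = P[c, c1]
            A0 = partial[c0, c]
            A1 = partial[c1, c]
            OUT = partial[v, c]
            for i in range(4):
                a0 = P0[i, 0]
                a1 = P0[i, 1]
                a2 = P0[i, 2]
                a3 = P0[i, 3]
                b0 = P1[i, 0]
                b1 = P1[i, 1]
                b2 = P1[i, 2]
                b3 = P1[i, 3]
                for p in range(npat):
                    s0 = (a0 * A0[0, p] + a1 * A0[1, p]
                          + a2 * A0[2, p] + a3 * A0[3, p])
                    s1 = (b0 * A1[0, p] + b1 * A1[1, p]
                          + b2 * A1[2, p] + b3 * A1[3, p])
                    OUT[i, p] = s0 * s1
            if do_scale:
                for p in range(npat):
                    m = OUT[0, p]
                    if OUT[1, p] > m:
                        m = OUT[1, p]
                    if OUT[2, p] > m:
                        m = OUT[2, p]
                    if OUT[3, p] > m:
                        m = OUT[3, p]
                    if m > 0.0 and m != 1.0:
                        inv = 1.0 / m
                        OUT[0, p] *= inv
                        OUT[1, p] *= inv
                        OUT[2, p] *= inv
                        OUT[3, p] *= inv
                        logscale[c, p] += np.log(m)
    total = 0.0
    R = partial[root]
    for p in range(npat):
        best = -np.inf
        for c in range(ncat):
            if weights[c] <= 0.0:
                continue
            site = (freqs[0] * R[c, 0, p] + freqs[1] * R[c, 1, p]
                    + freqs[2] * R[c, 2, p] + freqs[3] * R[c, 3, p])
            if site > 0.0:
                lv = np.log(weights[c] * site) + logscale[c, p]
                if lv > best:
                    best = lv
        if not np.isfinite(best):
            return -np.inf
        acc = 0.0
        for c in range(ncat):
            if weights[c] <= 0.0:
                continue
            site = (freqs[0] * R[c, 0, p] + freqs[1] * R[c, 1, p]
                    + freqs[2] * R[c, 2, p] + freqs[3] * R[c, 3, p])
            if site > 0.0:
                acc += np.exp(np.log(weights[c] * site) + logscale[c, p] - best)
        total += patw[p] * (best + np.log(acc))
    return total


if HAVE_NUMBA:
    prune_loglik = _nb.njit(cache=True, nogil=True, fastmath=True)(_prune_loglik_py)
else:  # pragma: no cover
    prune_loglik = _prune_loglik_py
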