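"""Time-reversible nucleotide substitution models.

A model is defined by six symmetric exchangeabilities s_ij (order AC, AG, AT,
CG, CT, GT) and stationary frequencies pi.  The generator is
Q_ij = s_ij * pi_j (i != j), with the diagonal set so rows sum to zero, and
the whole matrix rescaled so that -sum_i pi_i Q_ii = 1: one expected
substitution per unit of rate-time.  Named submodels (JC, HKY, TrN, TVM, GTR)
are constraint patterns on the exchangeabilities.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SubstModel", "build_model", "MODEL_NAMES", "model_free_params"]

MODEL_NAMES = ("JC", "HKY", "TrN", "TVM", "GTR")

# index pairs for the exchangeability vector (AC, AG, AT, CG, CT, GT)
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
_TRANSITIONS = (1, 4)  # AG, CT entries of the vector
_TRANSVERSIONS = (0, 2, 3, 5)  # AC, AT, CG, GT


class SubstModel:
    """Reversible rate matrix with a cached symmetric eigendecomposition."""

    def __init__(self, name: str, exchangeabilities, freqs):
        exch = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(freqs, dtype=float)
        if exch.shape != (6,) or np.any(exch <= 0):
            raise ValueError("need 6 positive exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("freqs must be 4 positive values summing to 1")
        self.model_name = name
        self.exchangeabilities = exch
        self.freqs = pi / pi.sum()

        Q = np.zeros((4, 4))
        for s, (i, j) in zip(exch, _PAIRS):
            Q[i, j] = s * self.freqs[j]
            Q[j, i] = s * self.freqs[i]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.dot(self.freqs, np.diag(Q))
        self.Q = Q / scale

        # pi-symmetrised eigendecomposition: B = D Q D^-1 is symmetric for
        # D = diag(sqrt(pi)); P(t) = D^-1 U exp(L t) U' D.
        d = np.sqrt(self.freqs)
        B = (d[:, None] * self.Q) / d[None, :]
        evals, U = np.linalg.eigh((B + B.T) / 2)
        self.eigenvalues = evals
        self._left = U.T * d[None, :]         # U' D
        self._right = (U / d[:, None])        # D^-1 U

    def transition_probs(self, distance: float) -> np.ndarray:
        """P(d) for a branch of ``distance`` expected substitutions per site."""
        if distance < 0:
            raise ValueError("distance must be non-negative")
        P = (self._right * np.exp(self.eigenvalues * distance)) @ self._left
        return np.clip(P, 0.0, None)

    def transition_probs_many(self, distances: np.ndarray) -> np.ndarray:
        """Vectorised P(d): returns (len(distances), 4, 4)."""
        d = np.asarray(distances, dtype=float)
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        E = np.exp(np.multiply.outer(d, self.eigenvalues))  # (..., 4)
        P = (self._right * E[..., None, :]) @ self._left
        return np.clip(P, 0.0, None)

    def __repr__(self):
        return f"SubstModel({self.model_name}, exch={np.round(self.exchangeabilities, 4)})"


def _check_equal(vals, what, tol=1e-9):
    vals = np.asarray(vals)
    if np.any(np.abs(vals - vals[0]) > tol * max(1.0, abs(vals[0]))):
        raise ValueError(f"{what} must be equal for this model")


def build_model(name: str, exchangeabilities=None, freqs=None) -> SubstModel:
    """Construct a named reversible model, enforcing its constraint pattern.

    JC: all exchangeabilities equal and uniform frequencies.
    HKY: one transition/transversion ratio.  TrN: two transition rates.
    TVM: free transversions, both transitions equal.  GTR: all free.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    if exchangeabilities is None:
        exchangeabilities = np.ones(6)
    exch = np.asarray(exchangeabilities, dtype=float)
    if freqs is None:
        freqs = np.full(4, 0.25)
    freqs = np.asarray(freqs, dtype=float)

    if name == "JC":
        _check_equal(exch, "JC exchangeabilities")
        if np.any(np.abs(freqs - 0.25) > 1e-9):
            raise ValueError("JC requires uniform base frequencies")
    elif name == "HKY":
        _check_equal(exch[list(_TRANSVERSIONS)], "HKY transversion rates")
        _check_equal(exch[list(_TRANSITIONS)], "HKY transition rates")
    elif name == "TrN":
        _check_equal(exch[list(_TRANSVERSIONS)], "TrN transversion rates")
    elif name == "TVM":
        _check_equal(exch[list(_TRANSITIONS)], "TVM transition rates")
    # GTR: no constraints
    return SubstModel(name, exch, freqs)


def model_free_params(name: str) -> list[str]:
    """Names of the free exchangeability parameters sampled during inference.

    One exchangeability is fixed at 1 as the reference (GT, or a transversion).
    """
    return {
        "JC": [],
        "HKY": ["kappa"],
        "TrN": ["kappa_ag", "kappa_ct"],
        "TVM": ["ac", "at", "cg", "kappa"],
        "GTR": ["ac", "ag", "at", "cg", "ct"],
    }[name]


def exch_from_free(name: str, values: np.ndarray) -> np.ndarray:
    """Expand the free-parameter vector into the 6 exchangeabilities."""
    v = np.asarray(values, dtype=float)
    if name == "JC":
        return np.ones(6)
    if name == "HKY":
        (k,) = v
        return np.array([1.0, k, 1.0, 1.0, k, 1.0])
    if name == "TrN":
        k1, k2 = v
        return np.array([1.0, k1, 1.0, 1.0, k2, 1.0])
    if name == "TVM":
        ac, at, cg, k = v
        return np.array([ac, k, at, cg, k, 1.0])
    if name == "GTR":
        ac, ag, at, cg, ct = v
        return np.array([ac, ag, at, cg, ct, 1.0])
    raise ValueError(f"unknown model {name!r}")
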