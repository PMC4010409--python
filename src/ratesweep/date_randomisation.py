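"""Date-randomisation test for temporal signal.

Tip sampling dates are permuted over the taxa (the multiset of observed
ages is reassigned, never resampled) and the full rate inference is rerun
for each replicate with identical settings.  If the mean posterior rate
from the original data lies inside any replicate's 95% credible interval,
the sequence ages are judged to carry insufficient temporal structure for
calibrating the clock ("no_signal"); otherwise the verdict is "signal".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import InferenceConfig, InferenceResult, infer
from .seq_io import Alignment

__all__ = ["DRTResult", "date_randomisation_test"]


@dataclass
class DRTResult:
    original_mean: float
    original_ci: tuple
    replicate_means: np.ndarray
    replicate_cis: np.ndarray  # (replicates, 2)
    replicates: int
    verdict: str  # "signal" or "no_signal"

    @property
    def n_covering(self) -> int:
        lo, hi = self.replicate_cis[:, 0], self.replicate_cis[:, 1]
        return int(np.sum((lo <= self.original_mean) & (self.original_mean <= hi)))


def _permuted_ages(ages: np.ndarray, rng) -> np.ndarray:
    """A non-identity permutation of the observed ages (as a multiset)."""
    for _ in range(1000):
        perm = rng.permutation(ages)
        if not np.array_equal(perm, ages):
            return perm
    raise ValueError("could not draw a non-identity permutation of the ages")


def date_randomisation_test(
    aln: Alignment,
    config: InferenceConfig,
    replicates: int = 20,
    seed: int = 0,
    original: InferenceResult | None = None,
) -> DRTResult:
    """Run the test; ``original`` may supply an already-computed base run."""
    if len(np.unique(aln.ages)) < 2:
        raise ValueError("date-randomisation test undefined for isochronous tips")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    if original is None:
        original = infer(aln, config, seed=seed)
    omu = original.mu

    rep_means = np.empty(replicates)
    rep_cis = np.empty((replicates, 2))
    for r in range(replicates):
        ages = _permuted_ages(aln.ages, rng)
        permuted = Alignment(list(aln.taxon_labels), ages, aln.codes.copy())
        rep_seed = int(rng.integers(2**31 - 1))
        res = infer(permuted, config, seed=rep_seed)
        rep_means[r] = res.mu.mean
        rep_cis[r] = (res.mu.lower, res.mu.upper)

    covered = np.any((rep_cis[:, 0] <= omu.mean) & (omu.mean <= rep_cis[:, 1]))
    return DRTResult(
        original_mean=omu.mean,
        original_ci=(omu.lower, omu.upper),
        replicate_means=rep_means,
        replicate_cis=rep_cis,
        replicates=replicates,
        verdict="no_signal" if covered else "signal",
    )
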