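"""Heterochronous coalescent simulation of trees and alignments.

The generator is the forward counterpart of the inference model: a
constant-size serial coalescent produces a clock tree over tips with known
sampling ages, and sequences evolve down it under a reversible substitution
model with site rates drawn from the configured RHAS treatment.  Site rates
may come from the discrete k-category gamma or from the continuous gamma
(the "true k = infinity" target of the category sweep), optionally with a
"hotspot" fraction of sites whose rate is multiplied by a constant — a
deliberate non-gamma contamination emulating data with an excess of
high-substitution sites.

Presets mirror the dimensions of intraspecific study designs (mitogenome,
D-loop, influenza PB2, HIV concatenated fragments) at tip counts scaled for
fast testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .seq_io import Alignment, ClockTree
from .site_rate_models import compose_mixture
from .subst_models import SubstModel, build_model

__all__ = ["SimScenario", "simulate_coalescent", "simulate_alignment", "preset", "PRESETS"]


@dataclass
class SimScenario:
    """Parameters of one simulated data set.

    ``n_tips`` tips are sampled uniformly over ``span`` years (youngest at 0)
    unless ``sampling_ages`` lists explicit ages.  ``coalescent_n`` is the
    constant population-size parameter of the coalescent, in years.
    """

    n_tips: int = 20
    n_sites: int = 1000
    span: float = 50.0
    sampling_ages: list[float] | None = None
    coalescent_n: float = 25.0
    mu: float = 1e-3
    model: str = "HKY"
    exchangeabilities: list[float] | None = None
    freqs: list[float] | None = None
    rhas: str = "gamma"
    alpha: float | None = 0.5
    p_inv: float = 0.0
    k: int = 8
    continuous_gamma: bool = False
    hotspot_fraction: float = 0.0
    hotspot_multiplier: float = 20.0
    name: str = "custom"

    def build_model(self) -> SubstModel:
        exch = self.exchangeabilities
        freqs = self.freqs
        if self.model == "JC":
            return build_model("JC")
        if exch is None:
            exch = [1.0, 4.0, 1.0, 1.0, 4.0, 1.0]  # mild transition bias
        if freqs is None:
            freqs = [0.3, 0.2, 0.2, 0.3]
        return build_model(self.model, exch, freqs)

    def tip_ages(self, rng: np.random.Generator) -> np.ndarray:
        if self.sampling_ages is not None:
            ages = np.asarray(self.sampling_ages, dtype=float)
        elif self.span <= 0:
            ages = np.zeros(self.n_tips)
        else:
            ages = rng.uniform(0.0, self.span, size=self.n_tips)
            ages[np.argmin(ages)] = 0.0
        return ages - ages.min()

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimScenario":
        return cls(**json.loads(text))


def simulate_coalescent(scenario: SimScenario, rng: np.random.Generator) -> ClockTree:
    """Draw a serial-sample coalescent tree under a constant population size.

    Going backward in time, lineages activate at their sampling ages; with j
    active lineages the waiting time to the next coalescence is exponential
    with rate j(j-1)/(2N), and a uniformly chosen pair merges.
    """
    ages = scenario.tip_ages(rng)
    n = len(ages)
    if n < 2:
        raise ValueError("need at least 2 tips")
    N = float(scenario.coalescent_n)
    if N <= 0:
        raise ValueError("coalescent_n must be positive")
    labels = [f"t{i}|{ages[i]:.6g}" for i in range(n)]
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_ages = np.zeros(2 * n - 1)
    node_ages[:n] = ages

    order = np.argsort(ages)
    pending = list(order)  # tips not yet activated, youngest first
    active: list[int] = []
    t = 0.0
    next_internal = n
    while len(active) > 1 or pending:
        j = len(active)
        if j >= 2:
            wait = rng.exponential(2.0 * N / (j * (j - 1)))
            t_coal = t + wait
        else:
            t_coal = np.inf
        t_sample = node_ages[pending[0]] if pending else np.inf
        if t_coal < t_sample:
            i1, i2 = rng.choice(j, size=2, replace=False)
            a, b = active[i1], active[i2]
            v = next_internal
            next_internal += 1
            parent[a] = v
            parent[b] = v
            node_ages[v] = t_coal
            active = [x for x in active if x not in (a, b)]
            active.append(v)
            t = t_coal
        else:
            t = t_sample
            while pending and node_ages[pending[0]] <= t + 1e-12:
                active.append(pending.pop(0))
    return ClockTree(labels, parent, node_ages)


def _draw_site_rates(scenario: SimScenario, rng: np.random.Generator) -> np.ndarray:
    S = scenario.n_sites
    rates = np.ones(S)
    if scenario.rhas in ("gamma", "gamma_inv"):
        if scenario.continuous_gamma:
            rates = rng.gamma(scenario.alpha, 1.0 / scenario.alpha, size=S)
        else:
            srm = compose_mixture("gamma", alpha=scenario.alpha, k=scenario.k)
            rates = srm.rates[rng.choice(len(srm.rates), size=S, p=srm.weights)]
    if scenario.rhas in ("inv", "gamma_inv") and scenario.p_inv > 0:
        inv = rng.random(S) < scenario.p_inv
        rates[inv] = 0.0
        # keep the mean rate at 1 so mu retains its meaning
        if (~inv).any():
            rates[~inv] /= 1.0 - scenario.p_inv
    if scenario.hotspot_fraction > 0:
        variable = np.flatnonzero(rates > 0)
        n_hot = int(round(scenario.hotspot_fraction * scenario.n_sites))
        if n_hot > 0 and len(variable) >= n_hot:
            hot = rng.choice(variable, size=n_hot, replace=False)
            rates[hot] *= scenario.hotspot_multiplier
    return rates


def simulate_alignment(
    tree: ClockTree, scenario: SimScenario, rng: np.random.Generator
) -> Alignment:
    """Evolve sequences down ``tree`` under the scenario's model."""
    model = scenario.build_model()
    rates = _draw_site_rates(scenario, rng)
    S = scenario.n_sites
    durations = tree.durations()
    states = np.empty((tree.n_nodes, S), dtype=np.int64)
    states[tree.root] = rng.choice(4, size=S, p=model.freqs)
    for v in tree.postorder[::-1]:  # preorder
        if v == tree.root:
            continue
        d = scenario.mu * durations[v] * rates
        states[v] = _evolve_states(model, states[tree.parent[v]], d, rng)
    codes = (1 << states[: tree.n_tips]).astype(np.uint8)
    ages = tree.ages[: tree.n_tips]
    return Alignment(list(tree.labels), ages, codes)


def _evolve_states(model: SubstModel, parent_states, dists, rng) -> np.ndarray:
    """Sample child states given parent states and per-site distances."""
    E = np.exp(np.outer(dists, model.eigenvalues))  # (S, 4)
    rows = np.einsum("sk,sk,kj->sj", model._right[parent_states], E, model._left)
    rows = np.clip(rows, 0.0, None)
    rows /= rows.sum(axis=1, keepdims=True)
    u = rng.random(len(dists))
    return (rows.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(0, 3)


def simulate_dataset(scenario: SimScenario, seed: int):
    """Convenience: (tree, alignment, site_rates) from one seed."""
    rng = np.random.default_rng(seed)
    tree = simulate_coalescent(scenario, rng)
    aln = simulate_alignment(tree, scenario, rng)
    return tree, aln


PRESETS = {
    # Hominin-style mitogenome: long sampling window, slow clock, strong RHAS
    # with many invariable sites; site count scaled down from ~16.6 kb.
    "mito_like": SimScenario(
        name="mito_like", n_tips=16, n_sites=2000, span=65000.0,
        coalescent_n=120000.0, mu=2.5e-8, model="TrN",
        exchangeabilities=[1, 12, 1, 1, 20, 1], freqs=[0.31, 0.31, 0.13, 0.25],
        rhas="gamma_inv", alpha=0.1, p_inv=0.5, k=4,
    ),
    # Muskox-style mitochondrial D-loop: ancient-DNA window, moderate clock.
    "dloop_like": SimScenario(
        name="dloop_like", n_tips=24, n_sites=682, span=45740.0,
        coalescent_n=30000.0, mu=3e-7, model="HKY",
        exchangeabilities=[1, 8, 1, 1, 8, 1], freqs=[0.32, 0.22, 0.14, 0.32],
        rhas="gamma", alpha=0.24, k=8,
    ),
    # Influenza-PB2-style: decades-long window, fast clock, shallow tree.
    "flu_like": SimScenario(
        name="flu_like", n_tips=20, n_sites=1200, span=82.0,
        coalescent_n=30.0, mu=2e-3, model="HKY",
        exchangeabilities=[1, 6, 1, 1, 6, 1], freqs=[0.33, 0.2, 0.25, 0.22],
        rhas="gamma", alpha=0.31, k=8,
    ),
    # HIV-style: fast clock plus a non-gamma excess of hotspot sites.
    "hiv_like": SimScenario(
        name="hiv_like", n_tips=20, n_sites=1063, span=46.0,
        coalescent_n=60.0, mu=3e-3, model="GTR",
        exchangeabilities=[2.0, 8.0, 1.0, 1.5, 10.0, 1.0],
        freqs=[0.36, 0.18, 0.24, 0.22],
        rhas="gamma", alpha=0.39, k=8,
        hotspot_fraction=0.05, hotspot_multiplier=20.0,
    ),
}


def preset(name: str) -> SimScenario:
    """A named, documented scenario (fresh copy safe to modify)."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return SimScenario(**asdict(base))
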