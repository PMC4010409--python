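import numpy as np
import pytest
from scipy import stats

from ratesweep import build_model, compose_mixture
from ratesweep.mutation_counts import (
    SiteCounts,
    fitch_counts,
    proportion_constant,
    sample_conditioned_counts,
    stochastic_map_counts,
)
from ratesweep.synthetic import SimScenario, simulate_dataset

from conftest import make_alignment, make_tree


class TestFitch:
    def test_constant_column_needs_no_changes(self):
        tree = make_tree([4, 4, 5, 5, 6, 6, -1], [0, 0, 0, 0, 1, 2, 3])
        aln = make_alignment(["A", "A", "A", "A"])
        assert fitch_counts(aln, tree).counts[0] == 0

    def test_alternating_pattern_on_balanced_tree(self):
        # (A,C,A,C) on ((t0,t1),(t2,t3)) needs 2 changes (brute-force checked)
        tree = make_tree([4, 4, 5, 5, 6, 6, -1], [0, 0, 0, 0, 1, 2, 3])
        aln = make_alignment(["A", "C", "A", "C"])
        assert fitch_counts(aln, tree).counts[0] == 2

    def test_brute_force_on_random_columns(self):
        """Fitch equals minimisation over all internal labelings."""
        tree = make_tree([4, 4, 5, 5, 6, 6, -1], [0, 0, 0, 0, 1, 2, 3])
        rng = np.random.default_rng(0)
        for _ in range(20):
            col = "".join(rng.choice(list("ACGT"), 4))
            aln = make_alignment(list(col))
            got = fitch_counts(aln, tree).counts[0]
            best = 4
            for a4 in range(4):
                for a5 in range(4):
                    for a6 in range(4):
                        cost = ((a4 != "ACGT".index(col[0]))
                                + (a4 != "ACGT".index(col[1]))
                                + (a5 != "ACGT".index(col[2]))
                                + (a5 != "ACGT".index(col[3]))
                                + (a6 != a4) + (a6 != a5))
                        best = min(best, cost)
            assert got == best

    def test_ambiguity_never_increases_count(self):
        tree = make_tree([4, 4, 5, 5, 6, 6, -1], [0, 0, 0, 0, 1, 2, 3])
        strict = make_alignment(["A", "C", "G", "C"])
        relaxed = make_alignment(["A", "N", "G", "C"])
        assert (fitch_counts(relaxed, tree).counts[0]
                <= fitch_counts(strict, tree).counts[0])

    def test_counts_bounded_by_taxa_minus_one(self):
        scen = SimScenario(n_tips=10, n_sites=200, span=20.0, coalescent_n=10.0,
                           mu=5e-3, rhas="equal")
        tree, aln = simulate_dataset(scen, 11)
        counts = fitch_counts(aln, tree).counts
        assert counts.max() <= 9
        assert len(counts) == 200

    def test_taxon_mismatch_rejected(self):
        tree = make_tree([2, 2, -1], [0, 0, 1], labels=["x|0", "y|0"])
        aln = make_alignment(["A", "C"])
        with pytest.raises(ValueError):
            fitch_counts(aln, tree)


class TestStochasticMapping:
    def test_zero_duration_branches_give_zero_counts(self):
        tree = make_tree([2, 2, -1], [0, 0, 0])
        aln = make_alignment(["AC", "AC"])
        counts = stochastic_map_counts(aln, tree, build_model("JC"),
                                       compose_mixture("equal"), 0.01,
                                       realizations=10, seed=1)
        assert np.all(counts.counts == 0)
        assert np.all(counts.mean_counts == 0)

    def test_unconditioned_single_branch_mean_matches_poisson_rate(self):
        """Marginalising the endpoint, the expected number of mapped events
        on one branch equals the branch distance (unit-normalised model)."""
        model = build_model("JC")
        d = 0.7
        rng = np.random.default_rng(4)
        P = model.transition_probs(d)
        draws = []
        for _ in range(4000):
            a = rng.choice(4, p=model.freqs)
            b = rng.choice(4, p=P[a])
            draws.append(sample_conditioned_counts(model, a, b, d, 1, rng)[0])
        draws = np.array(draws)
        se = draws.std() / np.sqrt(len(draws))
        assert draws.mean() == pytest.approx(d, abs=3 * se)

    def test_uniformization_matches_gillespie_in_distribution(self):
        """Endpoint-conditioned event counts agree with rejection-sampled
        Gillespie paths (chi-squared on the count histogram)."""
        model = build_model("JC")
        d, a, b = 0.8, 0, 2
        rng = np.random.default_rng(5)
        uni = sample_conditioned_counts(model, a, b, d, 4000, rng)

        gil = []
        while len(gil) < 2000:
            state, t, events = a, 0.0, 0
            while True:
                rate = -model.Q[state, state]
                t += rng.exponential(1 / rate)
                if t > d:
                    break
                probs = model.Q[state].copy()
                probs[state] = 0
                state = rng.choice(4, p=probs / probs.sum())
                events += 1
            if state == b:
                gil.append(events)
        gil = np.array(gil)
        top = int(max(uni.max(), gil.max()))
        f_uni = np.bincount(uni.astype(int), minlength=top + 1)
        f_gil = np.bincount(gil, minlength=top + 1)
        keep = (f_uni + f_gil) >= 10
        table = np.stack([f_uni[keep], f_gil[keep]])
        assert stats.chi2_contingency(table).pvalue > 0.01

    def test_constant_sites_under_strong_inv_model_map_to_zero(self):
        tree = make_tree([4, 4, 5, 5, 6, 6, -1], [0, 0, 0, 0, 5, 10, 15])
        aln = make_alignment(["AAAA", "AAAA", "AAAA", "AAAA"])
        srm = compose_mixture("inv", p_inv=0.9)
        counts = stochastic_map_counts(aln, tree, build_model("JC"), srm,
                                       0.01, realizations=50, seed=2)
        assert counts.mean_counts.max() < 0.2
        assert np.all(counts.counts == 0)

    def test_total_mapped_counts_track_expected_tree_length(self):
        """Summed over sites, mapped counts approximate mu x tree length
        (in expected substitutions per site)."""
        scen = SimScenario(n_tips=10, n_sites=1500, span=40.0, coalescent_n=20.0,
                           mu=3e-3, model="JC", rhas="gamma", alpha=0.7, k=8)
        tree, aln = simulate_dataset(scen, 12)
        srm = compose_mixture("gamma", alpha=0.7, k=8)
        counts = stochastic_map_counts(aln, tree, build_model("JC"), srm,
                                       3e-3, realizations=40, seed=3)
        expected = 3e-3 * tree.tree_length()
        got = counts.mean_counts.mean()
        assert got == pytest.approx(expected, rel=0.05)

    def test_seed_reproducibility(self):
        scen = SimScenario(n_tips=6, n_sites=100, span=30.0, coalescent_n=15.0,
                           mu=2e-3, model="JC", rhas="equal")
        tree, aln = simulate_dataset(scen, 13)
        kw = dict(realizations=10, seed=42)
        c1 = stochastic_map_counts(aln, tree, build_model("JC"),
                                   compose_mixture("equal"), 2e-3, **kw)
        c2 = stochastic_map_counts(aln, tree, build_model("JC"),
                                   compose_mixture("equal"), 2e-3, **kw)
        assert np.array_equal(c1.mean_counts, c2.mean_counts)


class TestProportionConstant:
    def test_integer_examples(self):
        assert proportion_constant(SiteCounts(np.array([0, 0, 1, 2]),
                                              "parsimony")) == 0.5
        assert proportion_constant(SiteCounts(np.zeros(7, dtype=int),
                                              "parsimony")) == 1.0

    def test_threshold_applies_to_premature_mean(self):
        sc = SiteCounts(np.array([0, 1]), "stochastic_mapping", 10,
                        mean_counts=np.array([0.49, 0.51]))
        assert proportion_constant(sc) == 0.5
        assert proportion_constant(sc, threshold=0.6) == 1.0

    def test_low_alpha_low_rate_regime_more_constant_than_hot_fast(self):
        """A slow, strongly-heterogeneous scenario leaves more sites
        untouched than a fast hotspot-contaminated one."""
        slow = SimScenario(n_tips=8, n_sites=600, span=100.0, coalescent_n=50.0,
                           mu=5e-5, model="JC", rhas="gamma", alpha=0.1, k=8)
        fast = SimScenario(n_tips=8, n_sites=600, span=40.0, coalescent_n=40.0,
                           mu=4e-3, model="JC", rhas="gamma", alpha=0.4, k=8,
                           hotspot_fraction=0.05, hotspot_multiplier=20.0)
        fractions = {}
        for name, scen in [("slow", slow), ("fast", fast)]:
            tree, aln = simulate_dataset(scen, 17)
            srm = compose_mixture("gamma", alpha=scen.alpha, k=8)
            c = stochastic_map_counts(aln, tree, build_model("JC"), srm,
                                      scen.mu, realizations=20, seed=3)
            fractions[name] = proportion_constant(c)
        assert fractions["slow"] > fractions["fast"]
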