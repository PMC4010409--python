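import numpy as np
import pytest

from ratesweep import LikelihoodEngine, build_model, compose_mixture
from ratesweep.seq_io import Alignment, ClockTree
from ratesweep.subst_models import exch_from_free

from conftest import make_alignment, make_tree, tiny_trees
from oracles import enumeration_log_likelihood, gauss_laguerre_continuous_gamma_loglik

FREQS = np.array([0.35, 0.15, 0.2, 0.3])


def _site_models():
    return {
        "equal": compose_mixture("equal"),
        "gamma": compose_mixture("gamma", alpha=0.4, k=3),
        "inv": compose_mixture("inv", p_inv=0.3),
        "gamma_inv": compose_mixture("gamma_inv", alpha=0.4, p_inv=0.25, k=3),
    }


def _model(name):
    free = {"JC": [], "HKY": [4.0], "TrN": [2.0, 7.0],
            "TVM": [1.5, 0.6, 1.2, 5.0], "GTR": [1.5, 4.0, 0.6, 1.2, 5.5]}[name]
    freqs = np.full(4, 0.25) if name == "JC" else FREQS
    return build_model(name, exch_from_free(name, free), freqs)


def _alignment_for(tree, with_ambiguity=True):
    rng = np.random.default_rng(hash(tree.n_tips) % 1000)
    n = tree.n_tips
    chars = list("ACGT")
    seqs = ["".join(rng.choice(chars, 6)) for _ in range(n)]
    if with_ambiguity and n >= 3:
        seqs[1] = seqs[1][:2] + "N" + seqs[1][3:]
        seqs[2] = "R" + seqs[2][1:]
    return Alignment.from_sequences(tree.labels, seqs,
                                    tree.ages[:n] - tree.ages[:n].min())


def test_single_tip_single_site_is_log_quarter():
    aln = make_alignment(["A"], labels=["t0|0"])
    tree = ClockTree(["t0|0"], np.array([-1]), np.array([0.0]))
    eng = LikelihoodEngine(aln)
    ll = eng.log_likelihood(tree, 1e-3, build_model("JC"), compose_mixture("equal"))
    assert ll == pytest.approx(np.log(0.25), abs=1e-12)


@pytest.mark.parametrize("model_name", ["JC", "HKY", "TrN", "TVM", "GTR"])
@pytest.mark.parametrize("kind", ["equal", "gamma", "inv", "gamma_inv"])
def test_pruning_equals_enumeration_on_small_trees(model_name, kind):
    """Pruning log-likelihood equals exhaustive ancestral-state enumeration
    on 2-5-tip trees, every substitution model x RHAS treatment."""
    model = _model(model_name)
    site_model = _site_models()[kind]
    mu = 0.05
    for name, tree in tiny_trees():
        aln = _alignment_for(tree)
        eng = LikelihoodEngine(aln)
        got = eng.log_likelihood(tree, mu, model, site_model)
        want = enumeration_log_likelihood(tree, aln, model, site_model, mu)
        assert got == pytest.approx(want, rel=1e-10), (name, model_name, kind)


def test_three_taxon_gamma_brute_force():
    """3-taxon JC + 2-category gamma against direct enumeration."""
    tree = make_tree([3, 3, 4, 4, -1], [0, 0, 0, 1, 2])
    aln = make_alignment(["ACGT", "ACGA", "AGGT"])
    model = build_model("JC")
    srm = compose_mixture("gamma", alpha=0.5, k=2)
    eng = LikelihoodEngine(aln)
    got = eng.log_likelihood(tree, 0.1, model, srm)
    want = enumeration_log_likelihood(tree, aln, model, srm, 0.1)
    assert got == pytest.approx(want, rel=1e-12)


def test_likelihood_decreases_as_mu_vanishes_with_variable_column():
    tree = make_tree([3, 3, 4, 4, -1], [0, 0, 0, 1, 2])
    aln = make_alignment(["AAAA", "AAAC", "AAAA"])
    eng = LikelihoodEngine(aln)
    model, srm = build_model("JC"), compose_mixture("equal")
    lls = [eng.log_likelihood(tree, m, model, srm)
           for m in (1e-1, 1e-3, 1e-6, 1e-9)]
    assert np.all(np.diff(lls) < 0)


def test_mixture_with_identical_category_rates_collapses():
    tree = make_tree([4, 4, 5, 5, 6, 6, -1], [0, 0, 0, 0, 1, 2, 3])
    aln = make_alignment(["ACGTA", "ACGCA", "AGGTT", "ACGTA"])
    eng = LikelihoodEngine(aln)
    model = _model("HKY")
    single = compose_mixture("equal")
    from ratesweep.site_rate_models import SiteRateModel
    fake = SiteRateModel("gamma", 4, 1.0, 0.0, "mean",
                         np.ones(4), np.full(4, 0.25))
    a = eng.log_likelihood(tree, 0.07, model, single)
    b = eng.log_likelihood(tree, 0.07, model, fake)
    assert a == pytest.approx(b, rel=1e-12)


def test_mu_duration_product_identifiability():
    """Doubling mu and halving all durations leaves the likelihood unchanged."""
    tree = make_tree([3, 3, 4, 4, -1], [0, 0, 0, 1, 2])
    half = make_tree([3, 3, 4, 4, -1], [0, 0, 0, 0.5, 1])
    aln = make_alignment(["ACGT", "ACGA", "AGGT"])
    eng = LikelihoodEngine(aln)
    model, srm = _model("GTR"), compose_mixture("gamma", alpha=0.3, k=4)
    assert eng.log_likelihood(tree, 0.05, model, srm) == pytest.approx(
        eng.log_likelihood(half, 0.10, model, srm), rel=1e-12)


def test_invariable_category_rewards_constant_columns():
    """At equal alpha, +G+I assigns higher likelihood to a constant column
    than +G alone (the rate-0 class concentrates mass on no change)."""
    tree = make_tree([4, 4, 5, 5, 6, 6, -1], [0, 0, 0, 0, 1, 2, 3])
    aln = make_alignment(["A", "A", "A", "A"])
    eng = LikelihoodEngine(aln)
    model = build_model("JC")
    g = compose_mixture("gamma", alpha=0.3, k=4)
    gi = compose_mixture("gamma_inv", alpha=0.3, p_inv=0.4, k=4)
    assert eng.log_likelihood(tree, 0.3, model, gi) > \
        eng.log_likelihood(tree, 0.3, model, g)


def test_constant_column_limit_as_mu_vanishes():
    """With no substitutions a constant-A column's likelihood tends to pi_A."""
    tree = make_tree([3, 3, 4, 4, -1], [0, 0, 0, 1, 2])
    aln = make_alignment(["A", "A", "A"])
    eng = LikelihoodEngine(aln)
    model = _model("GTR")
    ll = eng.log_likelihood(tree, 1e-12, model, compose_mixture("equal"))
    assert ll == pytest.approx(np.log(model.freqs[0]), abs=1e-6)


def test_pattern_compression_matches_full_columns():
    """Likelihood is identical whether or not columns are duplicated."""
    tree = make_tree([3, 3, 4, 4, -1], [0, 0, 0, 1, 2])
    base = ["ACGT", "ACGA", "AGGT"]
    dup = [s + s + s for s in base]
    a1, a2 = make_alignment(base), make_alignment(dup)
    assert a2.n_patterns == a1.n_patterns
    e1, e2 = LikelihoodEngine(a1), LikelihoodEngine(a2)
    model, srm = _model("HKY"), compose_mixture("gamma", alpha=0.5, k=4)
    assert 3 * e1.log_likelihood(tree, 0.05, model, srm) == pytest.approx(
        e2.log_likelihood(tree, 0.05, model, srm), rel=1e-10)


def test_k64_discrete_approaches_continuous_gamma():
    """k=64 discrete-gamma likelihood within 1e-4 relative of the
    Gauss-Laguerre continuous-gamma likelihood on a 4-taxon tree."""
    tree = make_tree([4, 4, 5, 5, 6, 6, -1], [0, 0, 0, 0, 1, 2, 3])
    aln = make_alignment(["ACGTAAGGCT", "ACGCAAGGCT", "AGGTATGGCT", "ACGTAAGGTT"])
    eng = LikelihoodEngine(aln)
    model = _model("HKY")
    alpha = 0.35
    discrete = eng.log_likelihood(tree, 0.08, model,
                                  compose_mixture("gamma", alpha=alpha, k=64))
    continuous = gauss_laguerre_continuous_gamma_loglik(eng, tree, 0.08, model, alpha)
    assert discrete == pytest.approx(continuous, rel=1e-4)


def test_scaled_and_unscaled_agree():
    """Per-node rescaling must not change computable likelihood values;
    exercised by comparing a deep tree (forces rescales) with enumeration."""
    parent = [5, 5, 6, 7, 8, 6, 7, 8, -1]
    ages = [0, 0, 1, 2, 5, 1.5, 3, 6, 9]
    tree = make_tree(parent, ages, labels=[f"t{i}|{a}" for i, a in
                                           enumerate([0, 0, 1, 2, 5])])
    aln = _alignment_for(tree, with_ambiguity=False)
    eng = LikelihoodEngine(aln)
    model, srm = _model("GTR"), compose_mixture("gamma_inv", alpha=0.2,
                                                p_inv=0.3, k=3)
    got = eng.log_likelihood(tree, 0.4, model, srm)  # ~3.6 subs on deep paths
    want = enumeration_log_likelihood(tree, aln, model, srm, 0.4)
    assert got == pytest.approx(want, rel=1e-10)


def test_invalid_inputs_rejected(tree3=None):
    tree = make_tree([3, 3, 4, 4, -1], [0, 0, 0, 1, 2])
    aln = make_alignment(["ACGT", "ACGA", "AGGT"])
    eng = LikelihoodEngine(aln)
    with pytest.raises(ValueError):
        eng.log_likelihood(tree, 0.0, build_model("JC"), compose_mixture("equal"))
    other = make_tree([3, 3, 4, 4, -1], [0, 0, 0, 1, 2],
                      labels=["x|0", "y|0", "z|0"])
    with pytest.raises(ValueError):
        eng.log_likelihood(other, 0.1, build_model("JC"), compose_mixture("equal"))
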