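"""Codon models: rate-matrix validity, pruning, NG86, LRTs, classification."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from plastodecay.codon import (
    CODONS,
    CODON_INDEX,
    N_CODONS,
    STOP_CODONS,
    f3x4_from_nucleotide_freqs,
    translate_codon,
)
from plastodecay.selection_models import (
    BranchSiteResult,
    CodonAlignment,
    ModelFit,
    TreeModel,
    beb_bin_of,
    branch_rate_regression,
    classify_selection,
    codon_rate_matrix,
    fit_branch_models,
    fit_model,
    hky85_distance,
    lrt,
    mg94_loglik,
    ng86_rates,
    pairwise_rates_ml,
)
from plastodecay.synthetic_data import simulate_codon_alignment

UNIFORM_PI = f3x4_from_nucleotide_freqs(np.full((3, 4), 0.25))
SKEWED_PI = f3x4_from_nucleotide_freqs(
    np.array([[0.3, 0.2, 0.2, 0.3], [0.3, 0.2, 0.2, 0.3], [0.35, 0.15, 0.15, 0.35]])
)

TREE8 = (
    "(((t1:0.1,t2:0.1):0.05,(t3:0.1,t4:0.1):0.05):0.05,"
    "((t5:0.1,t6:0.1):0.05,(t7:0.1,t8:0.3#1):0.05):0.05);"
)


# ----------------------------------------------------------------------
# rate matrix


def test_rate_matrix_rows_sum_to_zero_and_detailed_balance():
    rng = np.random.default_rng(61)
    pi = rng.dirichlet(np.ones(61))
    Q = codon_rate_matrix(pi, omega=0.4, kappa=3.0)
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
    flux = pi[:, None] * Q
    assert np.allclose(flux, flux.T, atol=1e-10)
    # normalization: one expected substitution per unit time
    assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0, rel=1e-12)


def test_multi_nucleotide_changes_have_zero_rate():
    Q = codon_rate_matrix(UNIFORM_PI, 1.0, 2.0)
    i = CODON_INDEX["TTT"]
    j = CODON_INDEX["GGG"]
    assert Q[i, j] == 0.0


# ----------------------------------------------------------------------
# likelihood oracle


def _direct_two_taxon_loglik(s1, s2, pi, omega, kappa, t1, t2):
    Q = codon_rate_matrix(pi, omega, kappa)
    P1 = expm(Q * t1)
    P2 = expm(Q * t2)
    ll = 0.0
    for a, b in zip(s1, s2):
        ll += math.log(sum(pi[i] * P1[i, a] * P2[i, b] for i in range(61)))
    return ll


def test_two_taxon_pruning_matches_direct_summation():
    rng = np.random.default_rng(62)
    for _ in range(5):
        pi = rng.dirichlet(np.ones(61) * 5)
        omega = rng.uniform(0.05, 3.0)
        kappa = rng.uniform(0.5, 6.0)
        t1, t2 = rng.uniform(0.01, 1.0, 2)
        s1 = rng.integers(0, 61, 30)
        s2 = rng.integers(0, 61, 30)
        aln = CodonAlignment(["a", "b"], np.stack([s1, s2]))
        tree = TreeModel.from_newick(f"(a:{t1},b:{t2});")
        got = mg94_loglik(aln, tree, pi, omega, omega, kappa)
        want = _direct_two_taxon_loglik(s1, s2, pi, omega, kappa, t1, t2)
        assert got == pytest.approx(want, abs=1e-8)


def test_spectral_fast_path_agrees_with_expm():
    rng = np.random.default_rng(68)
    tree = TreeModel.from_newick("((a:0.2,b:0.05):0.1,(c:0.3,d:0.01):0.02);")
    aln = CodonAlignment(list("abcd"), rng.integers(0, 61, (4, 50)))
    pi = rng.dirichlet(np.ones(61) * 3)
    l1 = mg94_loglik(aln, tree, pi, 0.7, 0.7, 3.0, method="expm")
    l2 = mg94_loglik(aln, tree, pi, 0.7, 0.7, 3.0, method="spectral")
    assert l2 == pytest.approx(l1, abs=1e-6)


def test_zero_branch_limit_gives_log_pi():
    pi = SKEWED_PI
    ci = CODON_INDEX["ATG"]
    aln = CodonAlignment(["a", "b"], np.array([[ci], [ci]]))
    tree = TreeModel.from_newick("(a:1e-9,b:1e-9);")
    ll = mg94_loglik(aln, tree, pi, 1.0, 1.0, 2.0)
    assert ll == pytest.approx(math.log(pi[ci]), abs=1e-6)


def test_loglik_invariant_under_rerooting():
    rng = np.random.default_rng(63)
    tree1 = TreeModel.from_newick("((a:0.2,b:0.3):0.1,(c:0.25,d:0.15):0.1);")
    tree2 = TreeModel.from_newick("(a:0.2,(b:0.3,((c:0.25,d:0.15):0.2)):0.0);")
    seqs = rng.integers(0, 61, (4, 40))
    aln = CodonAlignment(list("abcd"), seqs)
    pi = SKEWED_PI
    l1 = mg94_loglik(aln, tree1, pi, 0.5, 0.5, 2.0)
    l2 = mg94_loglik(aln, tree2, pi, 0.5, 0.5, 2.0)
    assert l1 == pytest.approx(l2, abs=1e-8)


# ----------------------------------------------------------------------
# NG86


def ng86_pair_oracle(c1, c2):
    """Pathway enumeration for one codon pair, independent implementation."""
    diffs = [p for p in range(3) if c1[p] != c2[p]]
    results = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, ok = c1, 0, 0, True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_codon(cur) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((ok, sd, nd))
    valid = [(s, n) for ok, s, n in results if ok]
    if not valid:
        valid = [(s, n) for _, s, n in results]
    return (sum(s for s, _ in valid) / len(valid), sum(n for _, n in valid) / len(valid))


def test_identical_sequences_zero_rates():
    r = ng86_rates("ATGTTTAAA", "ATGTTTAAA")
    assert r.dN == 0.0 and r.dS == 0.0


def test_phe_synonymous_single_difference():
    r = ng86_rates("TTT", "TTC")
    sd, nd = ng86_pair_oracle("TTT", "TTC")
    assert (sd, nd) == (1.0, 0.0)
    assert r.pS == pytest.approx(1.0 / r.S_sites)
    assert r.pN == 0.0


def test_pathway_averaging_subset_of_pairs():
    rng = np.random.default_rng(64)
    from plastodecay.selection_models import _pair_differences

    idx = rng.integers(0, 61, 80).reshape(40, 2)
    for i, j in idx:
        if i == j:
            continue
        got = _pair_differences(int(i), int(j))
        want = ng86_pair_oracle(CODONS[i], CODONS[j])
        assert got == pytest.approx(want)


def test_ng86_recovers_simulated_omega_kappa_one():
    tree = TreeModel.from_newick("(a:0.15,b:0.15);")
    hits = 0
    for seed in range(5):
        aln, _ = simulate_codon_alignment(
            tree, UNIFORM_PI, 500, seed=seed, omega_fg=0.3, omega_bg=0.3, kappa=1.0
        )
        s = {t: "".join(CODONS[i] for i in aln.codons[k]) for k, t in enumerate(aln.taxa)}
        r = ng86_rates(s["a"], s["b"])
        if 0.2 <= r.omega <= 0.4:
            hits += 1
    assert hits >= 4


def test_saturation_flagged():
    from plastodecay.selection_models import _jc_correct

    d, sat = _jc_correct(0.8)
    assert math.isinf(d) and sat


# ----------------------------------------------------------------------
# model fitting / LRT


def test_nesting_inequalities():
    tree = TreeModel.from_newick(TREE8)
    aln, _ = simulate_codon_alignment(tree, SKEWED_PI, 150, seed=9, omega_fg=0.6, omega_bg=0.25)
    fits = fit_branch_models(aln, tree)
    assert fits["b_free"].lnl >= fits["M0"].lnl - 1e-6
    assert fits["b_free"].lnl >= fits["b_neut"].lnl - 1e-6


def test_branch_model_parameter_recovery_single_gene():
    tree = TreeModel.from_newick(TREE8)
    aln, _ = simulate_codon_alignment(tree, SKEWED_PI, 600, seed=17, omega_fg=0.9, omega_bg=0.2)
    fits = fit_branch_models(aln, tree)
    assert fits["b_free"].params["omega_bg"] == pytest.approx(0.2, abs=0.08)
    assert fits["b_free"].params["omega_fg"] > fits["b_free"].params["omega_bg"]


def test_lrt_requires_nested_order():
    a = ModelFit("b_free", -100.0, {}, True, 2)
    b = ModelFit("M0", -99.0, {}, True, 1)
    with pytest.raises(ValueError):
        lrt(a, b)  # alternative below null
    ok = lrt(ModelFit("b_free", -98.0, {}, True, 2), b)
    assert ok.statistic == pytest.approx(2.0)
    assert ok.df == 1


# ----------------------------------------------------------------------
# classification decision tree


def _fits(w_fg, w_bg, lnl_m0, lnl_bn, lnl_bf, kappa=2.0):
    return {
        "M0": ModelFit("M0", lnl_m0, {"omega": (w_fg + w_bg) / 2, "kappa": kappa}, True, 1),
        "b_neut": ModelFit("b_neut", lnl_bn, {"omega_fg": 1.0, "omega_bg": w_bg, "kappa": kappa}, True, 1),
        "b_free": ModelFit("b_free", lnl_bf, {"omega_fg": w_fg, "omega_bg": w_bg, "kappa": kappa}, True, 2),
    }


def test_classification_relaxed_and_relaxed_selection():
    # b_free vs M0 p ~ 0.01 (2dl = 6.6), b_free vs b_neut p ~ 0.3 (2dl = 1.07)
    fits = _fits(0.8, 0.2, lnl_m0=-1003.3, lnl_bn=-1000.54, lnl_bf=-1000.0)
    call = classify_selection(fits, "g")
    assert call.constraint_status == "Relaxed"
    assert call.relaxed_selection is True
    assert call.delta_omega == pytest.approx((0.8 - 0.2) / 0.2)


def test_classification_strengthened():
    fits = _fits(0.05, 0.5, lnl_m0=-1010.0, lnl_bn=-1009.0, lnl_bf=-1000.0)
    call = classify_selection(fits, "g")
    assert call.constraint_status == "Strengthened"
    assert call.relaxed_selection is False  # deviates from neutrality


def test_classification_ns_when_lrt_not_significant():
    fits = _fits(0.4, 0.35, lnl_m0=-1000.5, lnl_bn=-1000.4, lnl_bf=-1000.0)
    call = classify_selection(fits, "g")
    assert call.constraint_status == "NS"
    assert call.relaxed_selection is False


def test_equal_omegas_delta_zero_ns():
    fits = _fits(0.3, 0.3, lnl_m0=-1000.0, lnl_bn=-1005.0, lnl_bf=-1000.0)
    call = classify_selection(fits, "g")
    assert call.delta_omega == 0.0
    assert call.constraint_status == "NS"


def test_extreme_omega_excluded():
    fits = _fits(12.0, 0.2, lnl_m0=-1010.0, lnl_bn=-1008.0, lnl_bf=-1000.0)
    call = classify_selection(fits, "g")
    assert call.excluded is True
    fits2 = _fits(0.8, 0.0005, lnl_m0=-1010.0, lnl_bn=-1008.0, lnl_bf=-1000.0)
    assert classify_selection(fits2, "g").excluded is True


def test_classification_table_oracle_randomized():
    """Decision tree is a pure function of p-values and omegas."""
    rng = np.random.default_rng(65)
    from scipy.stats import chi2

    for _ in range(50):
        w_bg = float(rng.uniform(0.01, 2.0))
        w_fg = float(rng.uniform(0.01, 2.0))
        d_fm = float(rng.uniform(0, 8))
        d_fn = float(rng.uniform(0, 8))
        lnl_bf = -1000.0
        fits = _fits(w_fg, w_bg, lnl_m0=lnl_bf - d_fm / 2, lnl_bn=lnl_bf - d_fn / 2, lnl_bf=lnl_bf)
        call = classify_selection(fits, "g")
        p_fm = chi2.sf(d_fm, 1)
        p_fn = chi2.sf(d_fn, 1)
        if p_fm >= 0.05:
            assert call.constraint_status == "NS"
        elif w_fg > w_bg:
            assert call.constraint_status == "Relaxed"
        elif w_fg < w_bg:
            assert call.constraint_status == "Strengthened"
        assert call.relaxed_selection == (p_fm < 0.05 and p_fn >= 0.05)


def test_beb_ratio_bins():
    assert beb_bin_of(1 / 500) == "<0.25%"
    assert beb_bin_of(2 / 500) == "0.25-0.50%"
    assert beb_bin_of(0.0) == "none"


def test_missing_fit_raises():
    with pytest.raises(ValueError, match="b_neut"):
        classify_selection({"M0": ModelFit("M0", 0, {}, True, 1), "b_free": ModelFit("b_free", 0, {}, True, 2)})


# ----------------------------------------------------------------------
# branch-site (smoke-level: full calibration lives in the simulation studies)


def test_branch_site_statistic_nonnegative_and_bins():
    tree = TreeModel.from_newick(TREE8)
    aln, _ = simulate_codon_alignment(
        tree, SKEWED_PI, 120, seed=23,
        site_classes=[(0.7, 0.2, 0.2), (0.3, 1.0, 1.0)],  # bsA1-style null
    )
    from plastodecay.selection_models import branch_site_test

    res = branch_site_test(aln, tree)
    assert res.lrt.statistic >= 0
    assert 0 <= res.lrt.pvalue <= 1
    assert res.lrt.df == 1
    assert res.beb_bin in ("none", "<0.25%", "0.25-0.50%", ">0.50%")
    assert len(res.site_posteriors) == aln.n_codons


# ----------------------------------------------------------------------
# HKY85 distance


def test_hky_identical_zero():
    d, _ = hky85_distance("ACGTACGT", "ACGTACGT")
    assert d == 0.0


def test_hky_symmetric():
    rng = np.random.default_rng(66)
    s1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
    s2 = list(s1)
    for i in rng.choice(400, 40, replace=False):
        s2[i] = "ACGT"[(("ACGT".index(s2[i])) + 1 + int(rng.integers(0, 3))) % 4]
    s2 = "".join(s2)
    d12, _ = hky85_distance(s1, s2)
    d21, _ = hky85_distance(s2, s1)
    assert d12 == pytest.approx(d21, rel=1e-4)


def test_hky_matches_jc_closed_form_under_jc_data():
    # data with uniform composition and balanced substitution types
    rng = np.random.default_rng(67)
    n = 4000
    s1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
    s2 = list(s1)
    flip = rng.choice(n, int(0.1 * n), replace=False)
    for i in flip:
        s2[i] = "ACGT"[(("ACGT".index(s2[i])) + 1 + int(rng.integers(0, 3))) % 4]
    s2 = "".join(s2)
    p = np.mean([a != b for a, b in zip(s1, s2)])
    jc = -0.75 * math.log(1 - 4 * p / 3)
    d, kappa = hky85_distance(s1, s2)
    assert d == pytest.approx(jc, rel=0.05)


# ----------------------------------------------------------------------
# pairwise ML and regression


def test_pairwise_ml_omega_recovery():
    tree = TreeModel.from_newick("(a:0.25,b:0.25);")
    aln, _ = simulate_codon_alignment(tree, SKEWED_PI, 500, seed=29, omega_fg=0.3, omega_bg=0.3)
    s = {t: "".join(CODONS[i] for i in aln.codons[k]) for k, t in enumerate(aln.taxa)}
    r = pairwise_rates_ml(s["a"], s["b"])
    assert r.omega == pytest.approx(0.3, abs=0.12)
    assert r.dS > r.dN > 0


def test_branch_rate_regression_constructed_slope():
    dn = {f"b{i}": 0.01 * (i + 1) for i in range(6)}
    ds = {k: 4.0 * v for k, v in dn.items()}
    dn["special"] = 0.05
    ds["special"] = 0.07
    fit = branch_rate_regression(dn, ds, exclude_labels=["special"])
    assert fit.slope_ds_on_dn == pytest.approx(4.0, rel=1e-9)
    assert fit.excluded_ratios["special"] == pytest.approx(1.4)
    assert fit.n_branches == 6


def test_branch_rate_regression_needs_variance():
    dn = {"a": 0.01, "b": 0.01, "c": 0.01}
    ds = {"a": 0.04, "b": 0.04, "c": 0.04}
    with pytest.raises(ValueError):
        branch_rate_regression(dn, ds)
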