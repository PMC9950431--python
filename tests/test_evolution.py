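"""Distances, neighbour joining, bootstrap, site-rate estimation."""

import io

import numpy as np
import pytest
from scipy.stats import spearmanr
from skbio import TreeNode
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from knotminer.evolution import (MAX_DISTANCE, DistanceMatrix, PhyloTree,
                                 _AA, _column_codes, _column_likelihoods,
                                 bootstrap_support, kimura_distance, nj_tree,
                                 patristic_distances, protein_distance,
                                 site_rates)
from knotminer.regional_msa import RegionalAlignment
from knotminer.synthetic_data import NON_CYS, mutate, random_tree


def _aln(rows: dict) -> RegionalAlignment:
    ids = tuple(sorted(rows))
    w = len(next(iter(rows.values())))
    return RegionalAlignment(ids=ids, rows=tuple(rows[i] for i in ids),
                             anchor_columns=(), region_blocks=((0, w),))


# -- distances --------------------------------------------------------------

def test_identical_rows_have_zero_distance():
    aln = _aln({"a": "ACDEF", "b": "ACDEF"})
    assert protein_distance(aln).d[0, 1] == 0.0


def test_kimura_correction_closed_form():
    # d = -ln(1 - 0.1 - 0.2 * 0.01) = -ln(0.898)
    assert kimura_distance(0.1) == pytest.approx(0.10758521067993743,
                                                 abs=1e-12)
    assert kimura_distance(0.95) == MAX_DISTANCE  # saturation cap


def test_distance_within_10pct_of_simulated_truth():
    rng = np.random.default_rng(61)
    ok = 0
    for _ in range(100):
        anc = "".join(rng.choice(list(_AA), 400))
        t = float(rng.uniform(0.05, 0.35))
        child = mutate(anc, t, np.ones(400), rng, alphabet=_AA)
        aln = _aln({"a": anc, "b": child})
        p = np.mean([x != y for x, y in zip(anc, child)])
        if p > 0.3:
            continue
        d = protein_distance(aln).d[0, 1]
        if abs(d - t) <= 0.1 * t + 0.03:  # binomial noise at 400 sites
            ok += 1
    assert ok >= 90


def test_disjoint_gap_patterns_raise():
    aln = _aln({"a": "AC--", "b": "--DE"})
    with pytest.raises(ValueError, match="a"):
        protein_distance(aln)


# -- neighbour joining ------------------------------------------------------

def test_nj_recovers_additive_matrices_exactly():
    rng = np.random.default_rng(67)
    for _ in range(100):
        n = int(rng.integers(4, 13))
        true = random_tree([f"t{i:02d}" for i in range(n)], rng, (0.05, 0.5))
        D = patristic_distances(true)
        rec = nj_tree(D)
        D2 = patristic_distances(rec)
        assert D2.ids == D.ids
        np.testing.assert_allclose(D2.d, D.d, atol=1e-8)


def test_nj_topology_agrees_with_skbio_on_additive_input():
    rng = np.random.default_rng(71)
    true = random_tree([f"t{i}" for i in range(8)], rng, (0.1, 0.5))
    D = patristic_distances(true)
    mine = nj_tree(D)
    unrooted = mine.root.copy()
    unrooted.unroot()
    ref = skbio_nj(SkbioDM(D.d, ids=list(D.ids)))
    ref.unroot()
    assert unrooted.compare_rfd(ref) == 0.0


def test_equidistant_matrix_resolves_to_star():
    ids = ("a", "b", "c", "d")
    d = np.ones((4, 4)) - np.eye(4)
    tree = nj_tree(DistanceMatrix(ids=ids, d=d))
    D2 = patristic_distances(tree)
    np.testing.assert_allclose(D2.d, d, atol=1e-12)


def test_nj_needs_three_taxa():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(ids=("a", "b"), d=np.zeros((2, 2))))


# -- bootstrap --------------------------------------------------------------

def _two_clade_alignment(rng, n_per=5, within=0.03, between=1.2):
    anc = "".join(rng.choice(list(NON_CYS), 120))
    far = mutate(anc, between, np.ones(120), rng)
    rows = {}
    for k in range(n_per):
        rows[f"a{k}"] = mutate(anc, within, np.ones(120), rng)
        rows[f"b{k}"] = mutate(far, within, np.ones(120), rng)
    return _aln(rows)


def test_separating_bipartition_gets_high_support():
    rng = np.random.default_rng(73)
    aln = _two_clade_alignment(rng)
    tree = bootstrap_support(aln, n_reps=200, seed=5, collapse_below=50.0)
    # find the a* vs b* split and check its support
    found = False
    for node in tree.root.non_tips():
        tips = {t.name for t in node.tips()}
        if tips in ({f"a{k}" for k in range(5)},
                    {f"b{k}" for k in range(5)}):
            assert node.support >= 95.0
            found = True
    assert found


def test_single_replicate_supports_are_binary():
    rng = np.random.default_rng(79)
    aln = _two_clade_alignment(rng, n_per=3)
    tree = bootstrap_support(aln, n_reps=1, seed=1, collapse_below=0.0)
    sups = [n.support for n in tree.root.non_tips()]
    assert sups and all(s in (0.0, 100.0) for s in sups)


def test_fixed_seed_gives_byte_identical_newick():
    rng = np.random.default_rng(83)
    aln = _two_clade_alignment(rng, n_per=4)
    t1 = bootstrap_support(aln, n_reps=50, seed=11)
    t2 = bootstrap_support(aln, n_reps=50, seed=11)
    assert t1.newick == t2.newick


def test_weak_edges_are_collapsed():
    rng = np.random.default_rng(89)
    # nearly identical sequences: internal structure is noise
    anc = "".join(rng.choice(list(NON_CYS), 60))
    rows = {f"s{k}": mutate(anc, 0.02, np.ones(60), rng) for k in range(6)}
    tree = bootstrap_support(_aln(rows), n_reps=100, seed=3,
                             collapse_below=101.0)  # collapse everything
    assert all(child.is_tip() for child in tree.root.children)


# -- site rates -------------------------------------------------------------

def test_two_taxon_pruning_equals_closed_form():
    tree = PhyloTree(root=TreeNode.read(io.StringIO("(a:0.3,b:0.7);")))
    aln = _aln({"a": "AR", "b": "AA"})
    codes = _column_codes(aln)
    lk = _column_likelihoods(codes, tree, np.array([1.0]),
                             {"a": 0, "b": 1})

    def p(same, t):
        lam = 20.0 / 19.0 * t
        return (1 + 19 * np.exp(-lam)) / 20 if same \
            else (1 - np.exp(-lam)) / 20

    for j, (x, y) in enumerate(zip("AR", "AA")):
        closed = sum((1 / 20) * p(z == x, 0.3) * p(z == y, 0.7)
                     for z in _AA)
        assert lk[j, 0] == pytest.approx(closed, abs=1e-10)


def test_conserved_column_rate_below_variable_column_rate():
    rng = np.random.default_rng(97)
    tree = random_tree([f"t{i}" for i in range(6)], rng, (0.1, 0.3))
    ids = sorted(t.name for t in tree.root.tips())
    rows = {}
    for i, sid in enumerate(ids):
        rows[sid] = "A" + "ACDEFG"[i]  # col0 conserved, col1 all-different
    prof = site_rates(_aln(rows), tree, alpha=0.8)
    assert prof.rates[0] < prof.rates[1]


def test_all_gap_column_is_unscored():
    rng = np.random.default_rng(101)
    tree = random_tree(["a", "b", "c"], rng, (0.1, 0.2))
    prof = site_rates(_aln({"a": "A-A", "b": "A-C", "c": "A-D"}), tree)
    assert not prof.scored[1]
    assert np.isnan(prof.rates[1])
    assert np.nanmean(prof.rates[prof.scored]) == pytest.approx(1.0,
                                                                abs=1e-9)


def test_rate_recovery_on_planted_slow_fast_benchmark():
    rng = np.random.default_rng(103)
    tree = random_tree([f"t{i:02d}" for i in range(10)], rng, (0.1, 0.4))
    true_rates = np.where(np.arange(60) < 30, 0.25, 1.75)
    anc = "".join(rng.choice(list(NON_CYS), 60))
    leaves = {}
    seqs = {id(tree.root): anc}
    for node in tree.root.preorder(include_self=False):
        child = mutate(seqs[id(node.parent)], node.length or 0.0,
                       true_rates, rng)
        seqs[id(node)] = child
        if node.is_tip():
            leaves[node.name] = child
    prof = site_rates(_aln(leaves), tree)
    rho = spearmanr(prof.rates, true_rates).statistic
    assert rho >= 0.6


def test_loglik_invariant_to_row_order_and_rerooting():
    rng = np.random.default_rng(107)
    tree = random_tree([f"t{i}" for i in range(5)], rng, (0.1, 0.3))
    leaves = {}
    anc = "".join(rng.choice(list(NON_CYS), 40))
    seqs = {id(tree.root): anc}
    for node in tree.root.preorder(include_self=False):
        child = mutate(seqs[id(node.parent)], node.length or 0.0,
                       np.ones(40), rng)
        seqs[id(node)] = child
        if node.is_tip():
            leaves[node.name] = child
    aln1 = _aln(leaves)
    p1 = site_rates(aln1, tree, alpha=1.0)
    # permuted row order
    ids = list(aln1.ids)[::-1]
    aln2 = RegionalAlignment(ids=tuple(ids),
                             rows=tuple(aln1.row(i) for i in ids),
                             anchor_columns=(),
                             region_blocks=((0, aln1.width),))
    p2 = site_rates(aln2, tree, alpha=1.0)
    assert p1.log_likelihood == pytest.approx(p2.log_likelihood, abs=1e-9)
    # reroot at an internal edge
    inner = next(n for n in tree.root.non_tips())
    rerooted = PhyloTree(root=tree.root.root_at(inner))
    p3 = site_rates(aln1, rerooted, alpha=1.0)
    assert p3.log_likelihood == pytest.approx(p1.log_likelihood, abs=1e-6)
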