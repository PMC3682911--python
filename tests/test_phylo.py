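"""Likelihood engine: model construction, pruning vs exhaustive oracles,
parsimony, branch-length/model optimization, NNI moves."""
import itertools

import numpy as np
import pytest

from sparsephylo.assembly import Supermatrix
from sparsephylo.formats import PartitionDef
from sparsephylo.phylo import (GTRGammaModel, LikelihoodEngine, ModelError,
                               PartitionedModel, PatternData, build_rate_matrix,
                               discrete_gamma_rates, fitch_score, ml_search,
                               nni_neighbors, nni_search, stepwise_addition_tree,
                               transition_probabilities, tree_log_likelihood)
from sparsephylo.simulate import (default_partitioned_model, simulate_alignment,
                                  simulate_tree)
from sparsephylo.trees import Node, Tree, robinson_foulds
from sparsephylo.assembly import concatenate

from conftest import build_tree, random_matrix, random_tree


# --------------------------------------------------------------- brute force

def brute_force_lnl(tree, matrix, pm):
    """Sum over all internal-state assignments, all sites, all categories."""
    total = 0.0
    ti = {t: i for i, t in enumerate(matrix.taxa)}
    for pdef, model in pm.parts:
        cols = matrix.data[:, np.asarray(pdef.columns0())]
        rates = model.category_rates() * model.rate_multiplier
        nodes = list(tree.postorder())
        internals = [n for n in nodes if not n.is_leaf]
        for site in range(cols.shape[1]):
            lik = 0.0
            for rate in rates:
                Ps = {id(n): transition_probabilities(model, n.length, rate)
                      for n in nodes if n is not tree.root}
                s = 0.0
                for assign in itertools.product(range(4), repeat=len(internals)):
                    amap = dict(zip([id(n) for n in internals], assign))
                    pr = model.pi[amap[id(tree.root)]]
                    for n in nodes:
                        if n is tree.root:
                            continue
                        parent_state = amap[id(n.parent)]
                        if n.is_leaf:
                            code = cols[ti[n.label], site]
                            if code < 4:
                                pr *= Ps[id(n)][parent_state, code]
                        else:
                            pr *= Ps[id(n)][parent_state, amap[id(n)]]
                    s += pr
                lik += s / len(rates)
            total += np.log(lik)
    return total


def brute_force_fitch(tree, column, taxa):
    leaves = tree.leaves()
    internals = [n for n in tree.postorder() if not n.is_leaf]
    codes = dict(zip(taxa, column))
    leaf_states = {}
    for lf in leaves:
        c = codes[lf.label]
        leaf_states[id(lf)] = [c] if c < 4 else [0, 1, 2, 3]
    best = np.inf
    for assign in itertools.product(range(4), repeat=len(internals)):
        amap = dict(zip([id(n) for n in internals], assign))
        for leaf_assign in itertools.product(*[leaf_states[id(lf)] for lf in leaves]):
            lmap = dict(zip([id(lf) for lf in leaves], leaf_assign))
            changes = 0
            for n in tree.postorder():
                if n is tree.root:
                    continue
                s = lmap.get(id(n), amap.get(id(n)))
                sp = amap[id(n.parent)]
                changes += s != sp
            best = min(best, changes)
    return int(best)


# -------------------------------------------------------------- rate matrix

def test_rate_matrix_properties():
    m = GTRGammaModel(pi=np.array([0.1, 0.2, 0.3, 0.4]),
                      rates=np.array([0.5, 2.0, 0.3, 0.7, 4.0, 1.0]))
    Q = build_rate_matrix(m)
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
    assert -np.sum(m.pi * np.diag(Q)) == pytest.approx(1.0)
    assert np.allclose(m.pi @ Q, 0.0, atol=1e-12)  # stationarity
    # detailed balance
    for i in range(4):
        for j in range(4):
            assert m.pi[i] * Q[i, j] == pytest.approx(m.pi[j] * Q[j, i])


def test_jukes_cantor_structure():
    Q = build_rate_matrix(GTRGammaModel())
    off = Q[~np.eye(4, dtype=bool)]
    assert np.allclose(off, off[0])


def test_invalid_model_rejected():
    with pytest.raises(ModelError):
        GTRGammaModel(pi=np.array([0.5, 0.5, 0.0, 0.0]))
    with pytest.raises(ModelError):
        GTRGammaModel(alpha=-1)
    with pytest.raises(ModelError):
        GTRGammaModel(rates=np.array([1, 1, 1, 1, 1, -1.0]))


def test_transition_probabilities_limits():
    m = GTRGammaModel(pi=np.array([0.1, 0.2, 0.3, 0.4]),
                      rates=np.array([0.5, 2.0, 0.3, 0.7, 4.0, 1.0]))
    assert np.allclose(transition_probabilities(m, 0.0), np.eye(4), atol=1e-12)
    P = transition_probabilities(m, 500.0)
    assert np.allclose(P, np.tile(m.pi, (4, 1)), atol=1e-8)  # ergodic limit
    assert np.allclose(transition_probabilities(m, 0.37).sum(axis=1), 1.0)
    with pytest.raises(ModelError):
        transition_probabilities(m, -0.1)


def test_jc_closed_form_everywhere():
    jc = GTRGammaModel(n_categories=1)
    for t in (0.01, 0.1, 0.5, 2.0):
        P = transition_probabilities(jc, t)
        same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
        diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
        expect = np.full((4, 4), diff)
        np.fill_diagonal(expect, same)
        assert np.allclose(P, expect, atol=1e-10)


def test_discrete_gamma_categories():
    assert discrete_gamma_rates(0.5, 1) == pytest.approx([1.0])
    for alpha in (0.2, 0.5, 1.0, 5.0):
        r = discrete_gamma_rates(alpha, 4)
        assert r.mean() == pytest.approx(1.0)
        assert np.all(np.diff(r) > 0)


# ------------------------------------------------------------------- pruning

def test_two_taxon_hand_formula():
    t = build_tree([("A", 0.07), ("B", 0.03)])
    m = Supermatrix.from_strings(["A", "B"], ["A", "A"])
    pm = PartitionedModel([(m.partitions[0], GTRGammaModel(n_categories=1))])
    lnl, site = tree_log_likelihood(t, m, pm)
    p_aa = 0.25 + 0.75 * np.exp(-4.0 * 0.1 / 3.0)  # total path 0.1
    assert lnl == pytest.approx(np.log(0.25 * p_aa), abs=1e-10)
    assert site.shape == (1,)


@pytest.mark.parametrize("seed", range(4))
def test_pruning_equals_brute_force(seed, mixed_model, small_matrix):
    rng = np.random.default_rng(seed)
    t = random_tree(rng, list("ABCDE"))
    lnl, site = tree_log_likelihood(t, small_matrix, mixed_model)
    assert lnl == pytest.approx(brute_force_lnl(t, small_matrix, mixed_model),
                                abs=1e-8)
    assert np.all(site <= 0.0)
    assert site.sum() == pytest.approx(lnl)


def test_all_missing_column_contributes_nothing(five_taxon_tree, mixed_model):
    m1 = Supermatrix.from_strings(
        ["A", "B", "C", "D", "E"], ["ACG", "AC?", "GC-", "TNG", "ACG"],
        [PartitionDef("p1", 1, 2), PartitionDef("p2", 3, 3)])
    m2 = Supermatrix.from_strings(
        ["A", "B", "C", "D", "E"], ["AC?G", "AC??", "GC?-", "TN?G", "AC?G"],
        [PartitionDef("p1", 1, 3), PartitionDef("p2", 4, 4)])
    pm2 = PartitionedModel([(m2.partitions[0], mixed_model.parts[0][1]),
                            (m2.partitions[1], mixed_model.parts[1][1])])
    lnl1, _ = tree_log_likelihood(five_taxon_tree, m1, mixed_model)
    lnl2, _ = tree_log_likelihood(five_taxon_tree, m2, pm2)
    assert lnl1 == pytest.approx(lnl2, abs=1e-9)


def test_likelihood_invariant_to_root_placement(five_taxon_tree, small_matrix,
                                                mixed_model):
    ref, _ = tree_log_likelihood(five_taxon_tree, small_matrix, mixed_model)
    for node in list(five_taxon_tree.postorder()):
        if node is five_taxon_tree.root or node.is_leaf:
            continue
        t2 = five_taxon_tree.copy()
        target = [n for n in t2.postorder()
                  if not n.is_leaf and t2.leaf_set(n) == five_taxon_tree.leaf_set(node)][0]
        t2.reroot_at(target)
        lnl, _ = tree_log_likelihood(t2, small_matrix, mixed_model)
        assert lnl == pytest.approx(ref, abs=1e-8)


def test_likelihood_invariant_to_site_and_taxon_order(five_taxon_tree, mixed_model):
    rng = np.random.default_rng(8)
    m = random_matrix(rng, list("ABCDE"), 60, missing=0.3)
    pm = PartitionedModel([(m.partitions[0], mixed_model.parts[0][1])])
    ref, _ = tree_log_likelihood(five_taxon_tree, m, pm)
    # site order: pattern compression must make this exact
    perm = rng.permutation(60)
    m_sites = Supermatrix(list(m.taxa), m.data[:, perm], list(m.partitions))
    lnl_s, _ = tree_log_likelihood(five_taxon_tree, m_sites, pm)
    assert lnl_s == pytest.approx(ref, abs=1e-12)
    # taxon order
    order = rng.permutation(5)
    m_tax = m.subset(list(order))
    lnl_t, _ = tree_log_likelihood(five_taxon_tree, m_tax, pm)
    assert lnl_t == pytest.approx(ref, abs=1e-12)


def test_missing_leaf_errors(five_taxon_tree, mixed_model):
    m = Supermatrix.from_strings(["A", "B", "C", "D"], ["A", "A", "A", "A"])
    pm = PartitionedModel([(m.partitions[0], GTRGammaModel())])
    with pytest.raises(Exception, match="absent"):
        tree_log_likelihood(five_taxon_tree, m, pm)


def test_gtr_gamma_k1_reduces_to_gtr(five_taxon_tree, small_matrix):
    g1 = GTRGammaModel(alpha=0.5, n_categories=1)
    g2 = GTRGammaModel(alpha=77.7, n_categories=1)  # alpha ignored at k=1
    for g in (g1, g2):
        pm = PartitionedModel([
            (PartitionDef("all", 1, 3), g)])
        m = Supermatrix.from_strings(small_matrix.taxa,
                                     [small_matrix.row_string(i) for i in range(5)])
        lnl, _ = tree_log_likelihood(five_taxon_tree, m, pm)
        if g is g1:
            ref = lnl
    assert lnl == pytest.approx(ref, abs=1e-12)


# ----------------------------------------------------------------- parsimony

def test_fitch_trivial_cases(five_taxon_tree):
    taxa = list("ABCDE")
    assert fitch_score(five_taxon_tree, [0] * 5, taxa) == 0
    t2 = build_tree([("X", 1.0), ("Y", 1.0)])
    assert fitch_score(t2, [0, 1], ["X", "Y"]) == 1


@pytest.mark.parametrize("seed", range(5))
def test_fitch_matches_exhaustive_minimization(seed):
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(6)]
    t = random_tree(rng, taxa)
    column = rng.integers(0, 5, size=6)  # includes missing code 4
    column = np.where(column == 4, 6, column)
    assert fitch_score(t, column, taxa) == brute_force_fitch(t, column, taxa)


def test_stepwise_addition_determinism_and_quality():
    rng = np.random.default_rng(0)
    tree = simulate_tree(8, seed=5, height=0.8)
    pm = default_partitioned_model({"g": 400}, alpha=1.0)
    aln = simulate_alignment(tree, pm, seed=6)
    m = concatenate(aln, ["g"])
    t1 = stepwise_addition_tree(m, seed=3)
    t2 = stepwise_addition_tree(m, seed=3)
    assert t1.newick() == t2.newick()
    assert sorted(t1.leaf_labels()) == sorted(m.taxa)

    data = PatternData.from_matrix(m)
    from sparsephylo.phylo import _fitch_total, _pattern_masks
    masks = [_pattern_masks(data, 0)]
    rows = {t: i for i, t in enumerate(data.taxa)}
    sw_scores, rnd_scores = [], []
    for s in range(20):
        sw = stepwise_addition_tree(m, seed=s)
        rnd = random_tree(np.random.default_rng(1000 + s), m.taxa)
        sw_scores.append(_fitch_total(sw, masks, data.weights, rows))
        rnd_scores.append(_fitch_total(rnd, masks, data.weights, rows))
    assert np.median(sw_scores) <= np.median(rnd_scores)


def test_stepwise_requires_three_taxa():
    m = Supermatrix.from_strings(["A", "B"], ["ACGT", "ACGA"])
    with pytest.raises(Exception):
        stepwise_addition_tree(m, seed=0)


def test_three_taxa_unique_topology():
    m = Supermatrix.from_strings(["A", "B", "C"], ["ACGT", "ACGA", "AGGA"])
    t = stepwise_addition_tree(m, seed=9)
    assert sorted(t.leaf_labels()) == ["A", "B", "C"]
    assert len(t.root.children) == 3


# ------------------------------------------------- branch-length optimization

def test_branch_optimization_recovers_jc_distance():
    t = build_tree([("X", 0.05), ("Y", 0.05)])
    x = "A" * 100
    y = "C" * 10 + "A" * 90
    m = Supermatrix.from_strings(["X", "Y"], [x, y])
    pm = PartitionedModel([(m.partitions[0], GTRGammaModel(n_categories=1))])
    eng = LikelihoodEngine(t, m, pm)
    before = eng.full_pass()
    after = eng.optimize_branch_lengths(tol=1e-6)
    assert after >= before  # lnL never decreases
    total = sum(c.length for c in t.root.children)
    assert total == pytest.approx(-0.75 * np.log(1 - 4 * 0.1 / 3), abs=1e-4)


def test_branch_length_recovery_within_5_percent():
    """Simulate on known lengths with plenty of sites; optimized lengths
    match truth to 5% in the median."""
    truth = simulate_tree(6, seed=21, height=0.5)
    truth.deroot()
    pm = default_partitioned_model({"g": 20000}, alpha=0.8, seed=2)
    aln = simulate_alignment(truth, pm, seed=22)
    m = concatenate(aln, ["g"])
    fitted = truth.copy()
    for n in fitted.postorder():
        if n is not fitted.root:
            n.length = 0.1
    eng = LikelihoodEngine(fitted, m, pm)
    eng.optimize_branch_lengths(tol=1e-4)
    rel = []
    true_map = {truth.leaf_set(n): n.length for n in truth.postorder()
                if n is not truth.root}
    for n in fitted.postorder():
        if n is fitted.root:
            continue
        key = fitted.leaf_set(n)
        if key in true_map and true_map[key] > 0.01:
            rel.append(abs(n.length - true_map[key]) / true_map[key])
    assert np.median(rel) < 0.05


def test_optimize_model_never_decreases_lnl(five_taxon_tree, small_matrix,
                                            mixed_model):
    eng = LikelihoodEngine(five_taxon_tree, small_matrix, mixed_model)
    before = eng.full_pass()
    eng.optimize_model(rounds=1)
    assert eng.full_pass() >= before - 1e-9


def test_optimize_model_pins_alpha_for_uniform_data(five_taxon_tree):
    m = Supermatrix.from_strings(["A", "B", "C", "D", "E"], ["AAAA"] * 5)
    pm = PartitionedModel([(m.partitions[0], GTRGammaModel())])
    eng = LikelihoodEngine(five_taxon_tree, m, pm)
    with pytest.warns(UserWarning, match="pinned"):
        eng.optimize_model(rounds=1)
    assert pm.parts[0][1].alpha == pytest.approx(100.0)


# ------------------------------------------------------------------ NNI moves

def test_each_internal_edge_has_two_nni_alternatives():
    rng = np.random.default_rng(17)
    t = random_tree(rng, list("ABCDEFGH"))
    for e in t.internal_edges():
        alts = nni_neighbors(t, e)
        assert len(alts) == 2
        ref = t.unrooted_splits()
        for t2, local, _ in alts:
            assert sorted(t2.leaf_labels()) == sorted(t.leaf_labels())
            assert t2.unrooted_splits() != ref  # a genuine rearrangement


def balanced_eight_taxon_tree(internal=0.3, terminal=0.2):
    """Fixed topology with long internal branches (strong signal)."""
    quartet = lambda a, b, c, d: (
        [([(a, terminal), (b, terminal)], internal),
         ([(c, terminal), (d, terminal)], internal)], internal)
    return build_tree([quartet("A", "B", "C", "D"), quartet("E", "F", "G", "H")])


def test_nni_search_monotone_and_recovers_simple_topology():
    truth = balanced_eight_taxon_tree()
    truth.deroot()
    pm = default_partitioned_model({"g": 1500}, alpha=1.0, seed=4)
    aln = simulate_alignment(truth, pm, seed=32)
    m = concatenate(aln, ["g"])
    start = random_tree(np.random.default_rng(33), m.taxa)
    start.deroot()
    for n in start.postorder():
        if n is not start.root:
            n.length = 0.1
    eng = LikelihoodEngine(start.copy(), m, pm)
    initial = eng.full_pass()
    best, lnl = nni_search(start, m, pm)
    assert lnl >= initial
    assert robinson_foulds(best, truth) == 0


def test_ml_search_same_seed_same_tree():
    tree = simulate_tree(7, seed=41, height=0.7)
    pm = default_partitioned_model({"g": 300}, alpha=1.0)
    aln = simulate_alignment(tree, pm, seed=42)
    m = concatenate(aln, ["g"])
    t1, l1 = ml_search(m, pm, n_starts=2, seed=5, optimize_model_first=False)
    t2, l2 = ml_search(m, pm, n_starts=2, seed=5, optimize_model_first=False)
    assert t1.canonical_newick() == t2.canonical_newick()
    assert l1 == pytest.approx(l2, abs=1e-9)
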