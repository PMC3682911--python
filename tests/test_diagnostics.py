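"""Missing-data diagnostics: completeness, regression, support summary, rogues."""
import numpy as np
import pytest

from sparsephylo.assembly import Supermatrix
from sparsephylo.diagnostics import (DiagnosticsError, RogueFlag, completeness,
                                     completeness_regression, flag_rogues,
                                     support_summary)
from sparsephylo.formats import TaxonomyTable
from sparsephylo.simulate import plant_taxonomy, simulate_tree
from sparsephylo.trees import Node, Tree

from conftest import build_tree, random_matrix


def closed_form_regression(x, y):
    """Textbook formulas from raw sums (independent oracle)."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    from scipy.stats import t as tdist
    tstat = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * tdist.sf(abs(tstat), n - 2)
    return slope, intercept, r, p


def leafy_tree_with_lengths(lengths):
    root = Node()
    a = root.add(Node(None, 0.1))
    labels = [f"t{i}" for i in range(len(lengths))]
    nodes = [Node(lab, ln) for lab, ln in zip(labels, lengths)]
    cur = a
    for n in nodes[:-2]:
        cur.add(n)
        nxt = Node(None, 0.05)
        cur.add(nxt)
        cur = nxt
    cur.add(nodes[-2])
    root.add(nodes[-1])
    return Tree(root), labels


# -------------------------------------------------------------- completeness

def test_completeness_values():
    m = Supermatrix.from_strings(["full", "half"], ["ACGT" * 25, "AC" * 25 + "?" * 50])
    c = completeness(m)
    assert c[0] == pytest.approx(1.0)
    assert c[1] == pytest.approx(0.5)
    # published example: 2497 bp of 12896 -> 0.1936
    assert 2497 / 12896 == pytest.approx(0.1936, abs=5e-5)


def test_completeness_conservation():
    rng = np.random.default_rng(3)
    m = random_matrix(rng, list("ABCD"), 50, missing=0.4)
    assert completeness(m).sum() * m.n_columns == pytest.approx(
        m.present.sum())


# ---------------------------------------------------------------- regression

def test_regression_matches_closed_form_to_1e10():
    rng = np.random.default_rng(11)
    lengths = rng.uniform(0.01, 0.5, 10)
    tree, labels = leafy_tree_with_lengths(lengths)
    comp = rng.uniform(0.1, 0.9, 10)
    rows = []
    n_cols = 1000
    for c in comp:
        k = int(round(c * n_cols))
        rows.append("A" * k + "?" * (n_cols - k))
    m = Supermatrix.from_strings(labels, rows)
    res = completeness_regression(tree, m)
    x = np.array([m.per_taxon_present_bp[m.taxa.index(t)] / n_cols for t in tree.leaf_labels()])
    y = np.array([n.length for n in tree.leaves()])
    slope, intercept, r, p = closed_form_regression(x, y)
    assert res.slope == pytest.approx(slope, abs=1e-10)
    assert res.intercept == pytest.approx(intercept, abs=1e-10)
    assert res.r == pytest.approx(r, abs=1e-10)
    assert res.p_value == pytest.approx(p, abs=1e-10)


def test_regression_perfect_line():
    lengths = np.arange(100, 500, 50) / 1000.0  # exact thousandths
    tree, labels = leafy_tree_with_lengths(lengths)
    rows = []
    for ln in lengths:
        k = int(round(ln * 1000))
        rows.append("A" * k + "?" * (1000 - k))
    m = Supermatrix.from_strings(labels, rows)
    res = completeness_regression(tree, m)
    assert res.r == pytest.approx(1.0, abs=1e-6)
    assert res.p_value < 1e-8


def test_regression_degenerate_predictor_errors():
    lengths = [0.1, 0.2, 0.3, 0.4]
    tree, labels = leafy_tree_with_lengths(lengths)
    m = Supermatrix.from_strings(labels, ["ACGT"] * 4)
    with pytest.raises(DiagnosticsError, match="constant"):
        completeness_regression(tree, m)


# ------------------------------------------------------------ support summary

def test_support_summary_examples():
    t = build_tree([
        ([("A", 1), ("B", 1)], 1),
        ([([("C", 1), ("D", 1)], 1), ([("E", 1), ("F", 1)], 1)], 1),
    ])
    edges = t.internal_edges()
    for e, s in zip(edges, [100.0, 90.0, 50.0]):
        e.support = s
    res = support_summary(t, 85)
    assert res.n_internal_edges == 3
    assert res.fraction_above == pytest.approx(100 * 2 / 3)
    for e in edges:
        e.support = 100.0
    assert support_summary(t, 85).fraction_above == 100.0
    # strict vs inclusive threshold
    edges[0].support = 85.0
    assert support_summary(t, 85, strict=True).fraction_above < \
        support_summary(t, 85, strict=False).fraction_above


def test_support_summary_invariant_to_rerooting():
    t = build_tree([
        ([("A", 1), ("B", 1)], 1),
        ([([("C", 1), ("D", 1)], 1), ("E", 1)], 1),
    ])
    for e, s in zip(t.internal_edges(), [95.0, 40.0]):
        e.support = s
    ref = support_summary(t, 85).fraction_above
    t2 = t.copy()
    target = [n for n in t2.postorder() if n.label == "C"][0]
    t2.reroot_at(target.parent)
    assert support_summary(t2, 85).fraction_above == ref


def test_support_summary_requires_annotations():
    t = build_tree([([("A", 1), ("B", 1)], 1), ([("C", 1), ("D", 1)], 1)])
    with pytest.raises(DiagnosticsError):
        support_summary(t)


# ------------------------------------------------------------------- rogues

def make_taxonomy(tree, family_of):
    rows = {}
    for tip in tree.leaf_labels():
        fam = family_of(tip)
        rows[tip] = {"genus": tip.split()[0], "subfamily": "", "family": fam,
                     "higher_taxon": "", "incertae_sedis": False}
    return TaxonomyTable(rows)


def test_rogue_flagged_in_wrong_family_with_low_support():
    t = build_tree([
        ([([("X one", 1), ("A a", 1)], 1),
          ([("A b", 1), ("A c", 1)], 1)], 1),
        ([("A d", 1), ("A e", 1)], 1),
    ])
    for n in t.postorder():
        if not n.is_leaf and n is not t.root:
            n.support = 20.0
    tax = make_taxonomy(t, lambda tip: "Xidae" if tip.startswith("X") else "Aidae")
    flags = flag_rogues(t, tax, support_threshold=50, min_labeled=3)
    assert [f.taxon for f in flags] == ["X one"]
    assert flags[0].neighborhood_family == "Aidae"


def test_concordant_tree_yields_zero_flags():
    tree = simulate_tree(30, seed=3)
    table = plant_taxonomy(tree, [10, 10, 10])
    for n in tree.postorder():
        if not n.is_leaf and n is not tree.root:
            n.support = 99.0
    assert flag_rogues(tree, table) == []


def test_planted_rogues_are_recovered():
    """Move 3 tips into wrong families with weak attachment support; all
    three must be flagged with at most one false positive (median rule
    checked across seeds)."""
    false_pos, recovered = [], []
    for seed in range(10):
        tree = simulate_tree(60, seed=seed)
        table = plant_taxonomy(tree, [20, 20, 20], n_families=3)
        for n in tree.postorder():
            if not n.is_leaf and n is not tree.root:
                n.support = 98.0
        fams = table.rank_members("family")
        fam_names = sorted(fams)
        rogues = []
        for k in range(3):
            src, dst = fam_names[k % len(fam_names)], fam_names[(k + 1) % len(fam_names)]
            members = sorted(fams[src])
            tip = members[min(k, len(members) - 1)]
            # relabel the tip into a family it is not placed within
            table.rows[tip]["family"] = dst
            rogues.append(tip)
            # weaken its attachment edge
            leaf = [n for n in tree.postorder() if n.label == tip][0]
            if leaf.parent is not tree.root:
                leaf.parent.support = 10.0
        flags = {f.taxon for f in flag_rogues(tree, table)}
        recovered.append(len(flags & set(rogues)))
        false_pos.append(len(flags - set(rogues)))
    assert np.median(recovered) == 3
    assert np.median(false_pos) <= 1
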