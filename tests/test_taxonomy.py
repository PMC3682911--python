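"""Monophyly auditing: classification, conflict support, planted taxonomies."""
import itertools

import numpy as np
import pytest

from sparsephylo.formats import TaxonomyTable
from sparsephylo.simulate import plant_taxonomy, simulate_tree
from sparsephylo.taxonomy import (audit_classification, classify_taxon,
                                  conflict_support)
from sparsephylo.trees import TreeError

from conftest import build_tree, random_tree


def test_classify_monophyletic():
    t = build_tree([([("A1", 1), ("A2", 1)], 1), ([("B1", 1), ("B2", 1)], 1)])
    rep = classify_taxon(t, {"A1", "A2"})
    assert rep.status == "monophyletic" and rep.k_maximal_clades == 1
    assert rep.intruders == frozenset()


def test_classify_polyphyletic():
    t = build_tree([([("A1", 1), ("B1", 1)], 1), ([("A2", 1), ("B2", 1)], 1)])
    rep = classify_taxon(t, {"A1", "A2"})
    assert rep.status == "polyphyletic"
    assert rep.intruders == frozenset({"B1", "B2"})


def test_classify_paraphyletic_single_intruder_clade():
    t = build_tree([("A1", 1), ([("B1", 1), ([("A2", 1), ("A3", 1)], 1)], 1)])
    rep = classify_taxon(t, {"A1", "A2", "A3"})
    assert rep.status == "paraphyletic"
    assert rep.intruders == frozenset({"B1"})


def test_classify_trivial_and_errors():
    t = build_tree([("A", 1), ("B", 1), ("C", 1)])
    assert classify_taxon(t, {"A"}).status == "trivial"
    with pytest.raises(TreeError):
        classify_taxon(t, {"A", "Z"})


def test_paraphyly_implies_monophyletic_intruders():
    rng = np.random.default_rng(2)
    for _ in range(30):
        labels = [f"A{i}" for i in range(5)] + [f"B{i}" for i in range(4)]
        t = random_tree(rng, labels)
        rep = classify_taxon(t, {l for l in labels if l.startswith("A")})
        if rep.status == "paraphyletic":
            sub = classify_taxon(t, rep.intruders)
            assert sub.status in ("monophyletic", "trivial")


# ----------------------------------------------------------- conflict support

def _internal_nodes(t):
    return [n for n in t.postorder() if n is not t.root and not n.is_leaf]


def test_conflict_support_single_edge():
    t = build_tree([("A1", 1),
                    ([("B1", 1), ([("A2", 1), ("A3", 1)], 1)], 1)])
    # annotate: edge of clade {B1,A2,A3} conflicts ({A2,A3}+B1 vs A1)
    for n in _internal_nodes(t):
        n.support = 99.0 if t.leaf_set(n) == {"B1", "A2", "A3"} else None
    assert conflict_support(t, {"A1", "A2", "A3"}) == 99.0


def test_conflict_support_unannotated_is_none():
    t = build_tree([("A1", 1), ([("B1", 1), ([("A2", 1), ("A3", 1)], 1)], 1)])
    assert conflict_support(t, {"A1", "A2", "A3"}) is None


def test_conflict_support_errors_on_monophyly():
    t = build_tree([([("A1", 1), ("A2", 1)], 1), ("B", 1)])
    with pytest.raises(TreeError):
        conflict_support(t, {"A1", "A2"})


def test_conflict_support_matches_exhaustive_scan():
    """Oracle: apply the child-clade conflict rule to every edge directly."""
    rng = np.random.default_rng(5)
    for rep in range(25):
        labels = [f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)]
        t = random_tree(rng, labels)
        internal = [n for n in t.postorder() if n is not t.root and not n.is_leaf]
        for n in internal:
            n.support = float(rng.integers(0, 101))
        S = {l for l in labels if l.startswith("A")}
        status = classify_taxon(t, S).status
        if status == "monophyletic":
            continue
        expected = None
        for n in internal:
            clade = t.leaf_set(n)
            if 0 < len(clade & S) < len(S) and (clade - S):
                expected = n.support if expected is None else max(expected, n.support)
        assert conflict_support(t, S) == expected


# ------------------------------------------------------------------ auditing

def planted_case(seed=7, n=24, violations=()):
    tree = simulate_tree(n, seed=seed)
    table = plant_taxonomy(tree, [n // 4] * 4, violation_spec=violations)
    return tree, table


def test_concordant_taxonomy_is_fully_monophyletic():
    tree, table = planted_case()
    reports, summary = audit_classification(tree, table)
    nontrivial = [r for r in reports if r.status != "trivial"]
    assert nontrivial and all(r.status == "monophyletic" for r in nontrivial)
    assert summary["strongly_supported_conflicts"] == 0
    assert summary["unmatched_tips"] == []


def test_tip_swap_flags_exactly_two_genera():
    tree, table = planted_case()
    genera = table.rank_members("genus")
    g1, g2 = sorted(genera)[:2]
    t1 = sorted(genera[g1])[0]
    t2 = sorted(genera[g2])[0]
    # swap the two tips' genus assignments
    table.rows[t1]["genus"], table.rows[t2]["genus"] = g2, g1
    reports, _ = audit_classification(tree, table)
    bad = {r.taxon for r in reports if r.rank == "genus"
           and r.status in ("paraphyletic", "polyphyletic")}
    assert bad == {g1, g2}


def test_nested_genus_reported_as_paraphyletic():
    """A genus whose tips surround a nested clade of two other genera, as in
    skinks where two small genera render a large one paraphyletic."""
    t = build_tree([
        ([("Eumeces a", 1), ("Eumeces b", 1)], 1),
        ([([("Scincus s1", 1), ("Scincopus s2", 1)], 1),
          ([("Eumeces c", 1), ("Eumeces d", 1)], 1)], 1),
    ])
    rows = {}
    for tip in t.leaf_labels():
        genus = tip.split()[0]
        rows[tip] = {"genus": genus, "subfamily": "Scincinae",
                     "family": "Scincidae", "higher_taxon": "",
                     "incertae_sedis": False}
    for n in _internal_nodes(t):
        n.support = 97.0
    reports, _ = audit_classification(t, TaxonomyTable(rows), threshold=85.0)
    by = {(r.rank, r.taxon): r for r in reports}
    eumeces = by[("genus", "Eumeces")]
    assert eumeces.status == "paraphyletic"
    assert eumeces.strongly_supported_conflict
    assert by[("family", "Scincidae")].status == "monophyletic"


def test_reports_invariant_to_child_rotation():
    tree, table = planted_case(seed=9)
    reports1, _ = audit_classification(tree, table)
    rotated = tree.copy()
    for n in rotated.postorder():
        n.children.reverse()
    reports2, _ = audit_classification(rotated, table)
    key = lambda rs: sorted((r.rank, r.taxon, r.status, r.k_maximal_clades) for r in rs)
    assert key(reports1) == key(reports2)


def test_k_clades_sum_bound():
    tree, table = planted_case(seed=11)
    genera = table.rank_members("genus")
    t1 = sorted(genera[sorted(genera)[0]])[0]
    table.rows[t1]["genus"] = sorted(genera)[1]
    reports, _ = audit_classification(tree, table, ranks=("genus",))
    ks = [r.k_maximal_clades for r in reports]
    assert sum(ks) >= len(ks)
    assert any(k > 1 for k in ks)
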