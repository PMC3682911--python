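"""Shared fixtures: tiny hand-built trees/matrices and random generators.

Everything is generated programmatically; no binary fixtures.
"""
from __future__ import annotations

import numpy as np
import pytest

from sparsephylo.assembly import Supermatrix
from sparsephylo.formats import PartitionDef
from sparsephylo.phylo import GTRGammaModel, PartitionedModel
from sparsephylo.trees import Node, Tree


def build_tree(spec) -> Tree:
    """Build a tree from a nested (label, length) / (children, length) spec."""

    def rec(s) -> Node:
        if isinstance(s[0], str):
            return Node(s[0], s[1])
        n = Node(None, s[1])
        for c in s[0]:
            n.add(rec(c))
        return n

    return Tree(rec((spec, 0.0)))


@pytest.fixture
def five_taxon_tree() -> Tree:
    return build_tree([
        ([("A", 0.1), ("B", 0.2)], 0.3),
        ([([("C", 0.05), ("D", 0.3)], 0.12), ("E", 0.4)], 0.15),
    ])


@pytest.fixture
def small_matrix() -> Supermatrix:
    rows = ["ACG", "AC?", "GC-", "TNG", "ACG"]
    return Supermatrix.from_strings(
        ["A", "B", "C", "D", "E"], rows,
        [PartitionDef("p1", 1, 2), PartitionDef("p2", 3, 3)])


@pytest.fixture
def mixed_model(small_matrix) -> PartitionedModel:
    return PartitionedModel([
        (small_matrix.partitions[0],
         GTRGammaModel(pi=np.array([0.3, 0.2, 0.3, 0.2]),
                       rates=np.array([1.5, 2.0, 0.8, 1.2, 3.0, 1.0]),
                       alpha=0.7, n_categories=4)),
        (small_matrix.partitions[1],
         GTRGammaModel(alpha=0.4, n_categories=2, rate_multiplier=1.7)),
    ])


def random_tree(rng: np.random.Generator, labels, min_len=0.02, max_len=0.5) -> Tree:
    """Random rooted binary topology with uniform random branch lengths."""
    nodes = [Node(lab, float(rng.uniform(min_len, max_len))) for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(None, float(rng.uniform(min_len, max_len)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for n in nodes:
        root.add(n)
    return Tree(root)


def random_matrix(rng: np.random.Generator, taxa, n_sites, missing=0.2,
                  partitions=None) -> Supermatrix:
    chars = np.array(list("ACGT?"))
    probs = [(1 - missing) / 4] * 4 + [missing]
    data = rng.choice(5, size=(len(taxa), n_sites), p=probs)
    rows = ["".join(chars[r]) for r in data]
    return Supermatrix.from_strings(list(taxa), rows, partitions)
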