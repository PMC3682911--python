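"""Support-aware monophyly auditing of a ranked taxonomy against a tree.

Every named taxon at each rank is classified as monophyletic, paraphyletic
(a single nested intruder clade), or polyphyletic on the rooted tree, and
the strongest support among the branches that conflict with its monophyly
is recorded.  Taxa sampled by a single tip are "trivial": monophyly is
undefined for singletons and they are never flagged.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .formats import TaxonomyTable
from .trees import Node, Tree, TreeError

#: conflicts supported at or above this are "strongly supported"
STRONG_CONFLICT = 85.0

STATUSES = ("monophyletic", "paraphyletic", "polyphyletic", "trivial")


@dataclass
class MonophylyReport:
    taxon: str
    rank: str
    status: str
    n_sampled_tips: int
    k_maximal_clades: int
    intruders: frozenset
    max_conflict_support: Optional[float]
    strongly_supported_conflict: bool

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "monophyletic" and (
                self.k_maximal_clades != 1 or self.intruders):
            raise ValueError("monophyly requires one clade and no intruders")
        if self.strongly_supported_conflict and self.status in ("monophyletic", "trivial"):
            raise ValueError("supported conflict implies non-monophyly")


def classify_taxon(tree: Tree, tip_set: Sequence[str] | set,
                   taxon: str = "", rank: str = "") -> MonophylyReport:
    """Monophyly status of `tip_set` on the rooted tree.

    k_maximal_clades counts the maximal tip_set-pure clades; the taxon is
    monophyletic iff k = 1, paraphyletic if the intruders inside its MRCA
    form exactly one clade, polyphyletic otherwise.
    """
    S = set(tip_set)
    leaves = set(tree.leaf_labels())
    unknown = S - leaves
    if unknown:
        raise TreeError(f"tips not on tree: {sorted(unknown)}")
    if len(S) <= 1:
        return MonophylyReport(taxon, rank, "trivial", len(S), 1,
                               frozenset(), None, False)
    # leaf sets bottom-up; find maximal S-pure nodes
    cache: dict[int, frozenset] = {}
    k = 0
    for n in tree.postorder():
        if n.is_leaf:
            cache[id(n)] = frozenset([n.label])
        else:
            cache[id(n)] = frozenset().union(*(cache[id(c)] for c in n.children))
    for n in tree.postorder():
        s = cache[id(n)]
        if s <= S:
            parent_pure = n.parent is not None and cache[id(n.parent)] <= S
            if not parent_pure:
                k += 1
    mrca = tree.mrca(sorted(S))
    intruders = frozenset(cache[id(mrca)] - S)
    if k == 1:
        return MonophylyReport(taxon, rank, "monophyletic", len(S), 1,
                               frozenset(), None, False)
    # paraphyletic iff the intruder set is exactly one clade
    one_clade = any(cache[id(n)] == intruders for n in tree.postorder())
    status = "paraphyletic" if one_clade else "polyphyletic"
    return MonophylyReport(taxon, rank, status, len(S), k, intruders, None, False)


def conflict_support(tree: Tree, tip_set: Sequence[str] | set) -> Optional[float]:
    """Maximum support among internal edges conflicting with monophyly of
    the tip set: edges whose child clade contains a proper non-empty subset
    of the set together with at least one non-member.  None when no
    conflicting edge carries a support value."""
    S = set(tip_set)
    report = classify_taxon(tree, S)
    if report.status in ("monophyletic", "trivial"):
        raise TreeError("conflict support is defined for non-monophyletic taxa only")
    best: Optional[float] = None
    for node in tree.postorder():
        if node is tree.root or node.is_leaf:
            continue
        clade = tree.leaf_set(node)
        inside = clade & S
        if 0 < len(inside) < len(S) and (clade - S):
            if node.support is not None:
                best = node.support if best is None else max(best, node.support)
    return best


def audit_classification(tree: Tree, taxonomy: TaxonomyTable,
                         threshold: float = STRONG_CONFLICT,
                         ranks: Sequence[str] = ("genus", "subfamily", "family"),
                         ) -> tuple[list[MonophylyReport], dict]:
    """One monophyly report per named taxon per rank, plus summary counts.

    Tree tips missing from the taxonomy are reported in the summary and act
    only as potential intruders.
    """
    leaves = set(tree.leaf_labels())
    unmatched = sorted(leaves - set(taxonomy.rows))
    reports: list[MonophylyReport] = []
    for rank in ranks:
        for name, members in sorted(taxonomy.rank_members(rank).items()):
            sampled = members & leaves
            if not sampled:
                continue
            rep = classify_taxon(tree, sampled, taxon=name, rank=rank)
            if rep.status in ("paraphyletic", "polyphyletic"):
                mx = conflict_support(tree, sampled)
                rep.max_conflict_support = mx
                rep.strongly_supported_conflict = mx is not None and mx >= threshold
            reports.append(rep)
    summary = {
        "n_taxa_audited": len(reports),
        "unmatched_tips": unmatched,
        "by_status": {s: sum(1 for r in reports if r.status == s) for s in STATUSES},
        "strongly_supported_conflicts":
            sum(1 for r in reports if r.strongly_supported_conflict),
        "threshold": threshold,
    }
    return reports, summary


def write_audit_table(reports: Sequence[MonophylyReport],
                      path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\trank\tstatus\tn_tips\tk_clades\tintruders\t"
                 "max_conflict_support\tstrong_conflict\n")
        for r in reports:
            mx = "" if r.max_conflict_support is None else f"{r.max_conflict_support:.1f}"
            fh.write(f"{r.taxon}\t{r.rank}\t{r.status}\t{r.n_sampled_tips}\t"
                     f"{r.k_maximal_clades}\t{'|'.join(sorted(r.intruders))}\t"
                     f"{mx}\t{int(r.strongly_supported_conflict)}\n")
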