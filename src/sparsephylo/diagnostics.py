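"""Missing-data diagnostics and support summaries.

The central check: regress each terminal branch length on the taxon's
proportional completeness (present bp / total matrix length).  A supermatrix
whose sparse taxa get systematically shorter or longer terminal branches
shows up as a significant slope; absence of a relationship supports using
the branch lengths at face value.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .assembly import Supermatrix
from .formats import TaxonomyTable
from .trees import Node, Tree, TreeError


class DiagnosticsError(ValueError):
    pass


@dataclass
class RegressionResult:
    r: float
    p_value: float
    n: int
    slope: float
    intercept: float

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise DiagnosticsError("correlation outside [-1, 1]")
        if self.n < 3:
            raise DiagnosticsError("regression needs at least 3 taxa")


@dataclass
class SupportSummary:
    n_internal_edges: int
    threshold: float
    fraction_above: float  # percent

    def __post_init__(self):
        if not 0.0 <= self.fraction_above <= 100.0:
            raise DiagnosticsError("fraction outside [0, 100]")


def completeness(m: Supermatrix) -> np.ndarray:
    """Per-taxon proportion of non-missing cells, aligned with m.taxa."""
    return m.per_taxon_present_bp / m.n_columns


def terminal_branch_lengths(tree: Tree) -> dict[str, float]:
    return {n.label: n.length for n in tree.leaves()}


def completeness_regression(tree: Tree, m: Supermatrix) -> RegressionResult:
    """OLS of terminal branch length on proportional completeness, with
    Pearson r and its two-sided t-test p-value."""
    comp = dict(zip(m.taxa, completeness(m)))
    tips = tree.leaf_labels()
    missing = [t for t in tips if t not in comp]
    if missing:
        raise TreeError(f"tree leaves absent from matrix: {sorted(missing)[:5]}")
    if len(tips) < 3:
        raise DiagnosticsError("regression needs at least 3 taxa")
    x = np.array([comp[t] for t in tips])
    y = np.array([n.length for n in tree.leaves()])
    if np.allclose(x, x[0]):
        raise DiagnosticsError("degenerate regression: completeness is constant")
    res = stats.linregress(x, y)
    return RegressionResult(r=float(res.rvalue), p_value=float(res.pvalue),
                            n=len(tips), slope=float(res.slope),
                            intercept=float(res.intercept))


def support_summary(tree: Tree, threshold: float = 85.0,
                    strict: bool = True) -> SupportSummary:
    """Share of internal edges with support above `threshold` (strictly,
    by default, matching the '>85' reporting convention)."""
    supports = [e.support for e in tree.internal_edges() if e.support is not None]
    if not supports:
        raise DiagnosticsError("tree carries no internal-edge supports")
    s = np.asarray(supports, dtype=float)
    above = (s > threshold) if strict else (s >= threshold)
    return SupportSummary(
        n_internal_edges=len(s),
        threshold=threshold,
        fraction_above=float(100.0 * above.mean()),
    )


@dataclass
class RogueFlag:
    taxon: str
    attachment_support: Optional[float]
    own_family: str
    neighborhood_family: str
    reason: str


def flag_rogues(tree: Tree, taxonomy: TaxonomyTable,
                support_threshold: float = 50.0,
                min_labeled: int = 5) -> list[RogueFlag]:
    """Report-only rogue screen: a terminal is flagged when its attachment
    edge is weakly supported AND the smallest enclosing clade with at least
    `min_labeled` taxonomy-labeled tips is majority a different family."""
    fam = {sp: row["family"] for sp, row in taxonomy.rows.items() if row["family"]}
    flags: list[RogueFlag] = []
    for leaf in tree.leaves():
        own = fam.get(leaf.label)
        if own is None:
            continue
        node = leaf.parent
        support = node.support if (node is not None and node is not tree.root) else None
        if support is not None and support >= support_threshold:
            continue
        # climb to the smallest clade with enough labeled tips besides this one
        anc = leaf.parent
        while anc is not None:
            labeled = [t for t in tree.leaf_set(anc) if t in fam and t != leaf.label]
            if len(labeled) >= min_labeled:
                break
            anc = anc.parent
        if anc is None:
            continue
        fams, counts = np.unique([fam[t] for t in labeled], return_counts=True)
        majority = fams[np.argmax(counts)]
        if counts.max() > len(labeled) / 2 and majority != own:
            flags.append(RogueFlag(
                taxon=leaf.label,
                attachment_support=support,
                own_family=own,
                neighborhood_family=str(majority),
                reason=(f"attachment support "
                        f"{'absent' if support is None else f'{support:.0f}'}"
                        f" < {support_threshold:.0f} and neighborhood is "
                        f"majority {majority}, not {own}"),
            ))
    return flags
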