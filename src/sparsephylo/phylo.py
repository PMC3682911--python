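"""Partitioned GTR+Γ likelihood, parsimony starting trees, and NNI search.

The engine implements Felsenstein pruning over compressed site patterns with
per-node scaling, a discrete gamma (category-mean) treatment of among-site
rate variation, per-branch Brent optimization against cached "outside"
partial likelihoods, and a nearest-neighbor-interchange hill climb.  Branch
lengths are shared across partitions; each partition carries its own GTR+Γ
parameters and a positive rate multiplier (mean 1 across partitions).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .assembly import Supermatrix
from .formats import MISSING_CODES, PartitionDef
from .trees import Node, Tree, TreeError

BRLEN_MIN, BRLEN_MAX = 1e-8, 10.0
ALPHA_MIN, ALPHA_MAX = 0.02, 100.0
RATE_MIN, RATE_MAX = 1e-4, 1e4
MULT_MIN, MULT_MAX = 0.05, 20.0

#: index pairs for the six exchangeabilities, order AC, AG, AT, CG, CT, GT
RATE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


class ModelError(ValueError):
    pass


@dataclass
class GTRGammaModel:
    """General time-reversible model with discrete-gamma rate variation.

    `rates` are the six exchangeabilities (AC, AG, AT, CG, CT, GT); GT is the
    reference and is held at 1.  `alpha` is the gamma shape; rate categories
    are the means of `n_categories` equal-probability slices (mean 1).
    `rate_multiplier` scales all branch lengths for the partition this model
    is attached to.
    """

    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    rates: np.ndarray = field(default_factory=lambda: np.ones(6))
    alpha: float = 1.0
    n_categories: int = 4
    rate_multiplier: float = 1.0

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.pi.shape != (4,) or (self.pi <= 0).any():
            raise ModelError("base frequencies must be 4 positive values")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ModelError("base frequencies must sum to 1")
        if self.rates.shape != (6,) or (self.rates <= 0).any():
            raise ModelError("exchangeabilities must be 6 positive values")
        if self.alpha <= 0:
            raise ModelError("gamma shape must be positive")
        if self.n_categories < 1:
            raise ModelError("need at least one rate category")
        if self.rate_multiplier <= 0:
            raise ModelError("rate multiplier must be positive")
        self.rates = self.rates / self.rates[5]  # GT == 1 by convention

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_categories)


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability gamma(alpha, mean 1) categories."""
    if k == 1:
        return np.ones(1)
    bounds = _gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    x = np.concatenate([[0.0], alpha * bounds, [np.inf]])
    upper = gammainc(alpha + 1.0, x[1:])
    lower = gammainc(alpha + 1.0, x[:-1])
    r = k * (upper - lower)
    return r / r.mean()


def build_rate_matrix(model: GTRGammaModel) -> np.ndarray:
    """Normalized GTR rate matrix: Q[i,j] = r_ij * pi_j, rows sum to zero,
    expected rate -sum_i pi_i Q_ii = 1."""
    Q = np.zeros((4, 4))
    for r, (i, j) in zip(model.rates, RATE_PAIRS):
        Q[i, j] = r * model.pi[j]
        Q[j, i] = r * model.pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(model.pi * np.diag(Q)).sum()
    return Q / scale


@dataclass
class _Eigen:
    A: np.ndarray  # P(t) = (A * exp(lam t)) @ B
    lam: np.ndarray
    B: np.ndarray
    pi: np.ndarray

    @classmethod
    def from_model(cls, model: GTRGammaModel) -> "_Eigen":
        Q = build_rate_matrix(model)
        d = np.sqrt(model.pi)
        S = (Q * d[:, None]) / d[None, :]
        S = 0.5 * (S + S.T)
        lam, R = np.linalg.eigh(S)
        A = R / d[:, None]
        B = R.T * d[None, :]
        return cls(A, lam, B, model.pi.copy())

    def transition(self, t_eff: np.ndarray) -> np.ndarray:
        """Stacked P(Q * t) for each effective time in `t_eff`."""
        e = np.exp(t_eff[:, None] * self.lam[None, :])
        P = (self.A[None, :, :] * e[:, None, :]) @ self.B[None, :, :]
        return np.maximum(P, 0.0, out=P)


def transition_probabilities(model: GTRGammaModel, t: float, rate: float = 1.0) -> np.ndarray:
    """P(t) = exp(Q * rate * t) for a single branch length."""
    if t < 0:
        raise ModelError("branch length must be non-negative")
    return _Eigen.from_model(model).transition(np.array([rate * t]))[0]


@dataclass
class PartitionedModel:
    parts: list[tuple[PartitionDef, GTRGammaModel]]

    def __post_init__(self):
        if not self.parts:
            raise ModelError("partitioned model needs at least one partition")

    @classmethod
    def uniform(cls, partitions: Sequence[PartitionDef], **kw) -> "PartitionedModel":
        return cls([(p, GTRGammaModel(**kw)) for p in partitions])

    def normalize_multipliers(self, tree: Optional[Tree] = None) -> None:
        """Rescale multipliers to mean 1; if a tree is given its branch
        lengths absorb the factor so all effective rates are unchanged."""
        g = float(np.mean([m.rate_multiplier for _, m in self.parts]))
        for _, m in self.parts:
            m.rate_multiplier /= g
        if tree is not None:
            for n in tree.postorder():
                if n is not tree.root:
                    n.length = min(max(n.length * g, BRLEN_MIN), BRLEN_MAX)

    def __iter__(self):
        return iter(self.parts)

    def __len__(self):
        return len(self.parts)


# -------------------------------------------------------------- site patterns

_TIP_PARTIAL = np.zeros((7, 4))
_TIP_PARTIAL[:4] = np.eye(4)
_TIP_PARTIAL[list(MISSING_CODES)] = 1.0  # gap / N / ? carry no information

_FITCH_MASK = np.array([1, 2, 4, 8, 15, 15, 15], dtype=np.uint8)


@dataclass
class PatternData:
    """Per-partition compressed site patterns for a fixed taxon set."""

    taxa: list[str]
    partitions: list[PartitionDef]
    patterns: list[np.ndarray]       # per partition: (n_taxa, n_pat) uint8
    weights: list[np.ndarray]        # per partition: (n_pat,) float
    site_index: list[np.ndarray]     # per partition: (n_sites,) -> pattern idx

    @classmethod
    def from_matrix(cls, matrix: Supermatrix) -> "PatternData":
        patterns, weights, site_index = [], [], []
        for p in matrix.partitions:
            cols = matrix.data[:, np.asarray(p.columns0())]
            pat, idx, cnt = np.unique(cols, axis=1, return_inverse=True,
                                      return_counts=True)
            patterns.append(np.ascontiguousarray(pat))
            weights.append(cnt.astype(float))
            site_index.append(idx.astype(int))
        return cls(list(matrix.taxa), list(matrix.partitions),
                   patterns, weights, site_index)

    @property
    def n_sites(self) -> int:
        return sum(len(ix) for ix in self.site_index)

    def taxon_rows(self, labels: Sequence[str]) -> np.ndarray:
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [l for l in labels if l not in index]
        if missing:
            raise TreeError(f"tree leaves absent from matrix: {sorted(missing)}")
        return np.array([index[l] for l in labels])


# ---------------------------------------------------------------------- engine

class LikelihoodEngine:
    """Pruning likelihood for one tree over compressed patterns.

    Partials are cached per node; `full_pass` refreshes them and returns the
    total log-likelihood.  `optimize_branch_lengths` runs monotone
    Gauss-Seidel sweeps of per-branch Brent optimization against outside
    partials that are kept consistent during the traversal.
    """

    def __init__(self, tree: Tree, data: PatternData | Supermatrix,
                 pm: PartitionedModel):
        if isinstance(data, Supermatrix):
            data = PatternData.from_matrix(data)
        self.tree = tree
        self.data = data
        self.pm = pm
        self._leaf_rows = dict(zip(
            [n.label for n in tree.leaves()],
            data.taxon_rows([n.label for n in tree.leaves()]),
        ))
        self._refresh_models()
        self._down: list[dict] = [dict() for _ in pm.parts]   # id(node) -> (arr, ls)
        self._lnl: Optional[float] = None

    # ----------------------------------------------------------------- models
    def _refresh_models(self, only: Optional[int] = None) -> None:
        if only is None:
            self._eig = [_Eigen.from_model(m) for _, m in self.pm.parts]
            self._cat = [m.category_rates() * m.rate_multiplier for _, m in self.pm.parts]
        else:
            _, m = self.pm.parts[only]
            self._eig[only] = _Eigen.from_model(m)
            self._cat[only] = m.category_rates() * m.rate_multiplier

    def set_partition_model(self, i: int, model: GTRGammaModel) -> None:
        self.pm.parts[i] = (self.pm.parts[i][0], model)
        self._refresh_models(only=i)
        self._down[i].clear()
        self._lnl = None

    # ------------------------------------------------------------- primitives
    def _tip_partial(self, p: int, node: Node) -> np.ndarray:
        row = self._leaf_rows[node.label]
        return _TIP_PARTIAL[self.data.patterns[p][row]]  # (npat, 4)

    def _edge_contrib(self, p: int, child: Node) -> tuple[np.ndarray, np.ndarray]:
        """P(t_child) applied to the child's down partial: (k,npat,4), logscale."""
        P = self._eig[p].transition(self._cat[p] * child.length)  # (k,4,4)
        if child.is_leaf:
            tip = self._tip_partial(p, child)
            return tip[None] @ P.transpose(0, 2, 1), 0.0
        arr, ls = self._down[p][id(child)]
        return arr @ P.transpose(0, 2, 1), ls

    def _combine_down(self, p: int, node: Node) -> None:
        res, ls_total = None, 0.0
        for c in node.children:
            contrib, ls = self._edge_contrib(p, c)
            res = contrib if res is None else res * contrib
            ls_total = ls_total + ls
        mx = res.max(axis=(0, 2))
        mx = np.where(mx > 0, mx, 1.0)
        res = res / mx[None, :, None]
        self._down[p][id(node)] = (res, ls_total + np.log(mx))

    def _partition_lnl(self, p: int, refresh: bool = True) -> float:
        """Partition log-likelihood.  With ``refresh=False`` cached partials
        are trusted where present (they are kept consistent internally)."""
        for n in self.tree.postorder():
            if not n.is_leaf and (refresh or id(n) not in self._down[p]):
                self._combine_down(p, n)
        arr, ls = self._down[p][id(self.tree.root)]
        sitelik = (arr @ self._eig[p].pi).mean(axis=0)
        lnlpat = np.log(sitelik) + ls
        return float(self.data.weights[p] @ lnlpat)

    def full_pass(self) -> float:
        self._lnl = sum(self._partition_lnl(p, refresh=False)
                        for p in range(len(self.pm.parts)))
        return self._lnl

    def invalidate(self) -> None:
        """Drop cached partials (required after external edits to branch
        lengths or topology)."""
        for d in self._down:
            d.clear()
        self._lnl = None

    def seed_down(self, other: "LikelihoodEngine", seedable: dict[int, Node]) -> None:
        """Adopt another engine's cached down partials for structurally
        identical subtrees (`seedable` maps that engine's node ids to this
        tree's nodes)."""
        for p in range(len(self.pm.parts)):
            src, dst = other._down[p], self._down[p]
            for old_id, new in seedable.items():
                if old_id in src:
                    dst[id(new)] = src[old_id]

    @property
    def lnl(self) -> float:
        if self._lnl is None:
            return self.full_pass()
        return self._lnl

    # ------------------------------------------------------------- site lnL
    def site_log_likelihoods(self) -> np.ndarray:
        """Per-site log-likelihood vector over all partitions, in column
        order (sites expanded from patterns)."""
        out = []
        for p in range(len(self.pm.parts)):
            for n in self.tree.postorder():
                if not n.is_leaf:
                    self._combine_down(p, n)
            arr, ls = self._down[p][id(self.tree.root)]
            sitelik = (arr @ self._eig[p].pi).mean(axis=0)
            lnlpat = np.log(sitelik) + ls
            out.append(lnlpat[self.data.site_index[p]])
        return np.concatenate(out)

    # ---------------------------------------------------- branch optimization
    def _edge_objective(self, piW, downs, ls_const):
        """Closure computing (lnL(t), dlnL/dt) for one edge from cached
        inside/outside partials.  The outer product of the two partials is
        precomputed per pattern, so each evaluation costs one small batched
        matrix exponential plus one contraction per partition."""
        nparts = len(self.pm.parts)
        k = len(self._cat[0])
        w_all = self.data.weights
        # O[p]: (k, n_p, 16) outer products piW_i * down_j
        O = [
            (piW[p][:, :, :, None] *
             np.broadcast_to(downs[p], (k,) + downs[p].shape[1:])[:, :, None, :]
             ).reshape(k, -1, 16)
            for p in range(nparts)
        ]
        lam_eff = np.stack([np.outer(self._cat[p], self._eig[p].lam)
                            for p in range(nparts)])  # (P,k,4)
        A_all = np.stack([self._eig[p].A for p in range(nparts)])
        B_all = np.stack([self._eig[p].B for p in range(nparts)])

        def fg(t: float) -> tuple[float, float]:
            E = np.exp(t * lam_eff)                       # (P,k,4)
            both = np.stack([E, lam_eff * E], axis=0)     # (2,P,k,4)
            PD = (A_all[None, :, None] * both[:, :, :, None, :]) @ B_all[None, :, None]
            PD = PD.reshape(2, nparts, k, 16)
            f_total, g_total = ls_const, 0.0
            for p in range(nparts):
                res = np.einsum("ktx,skx->ts", O[p], PD[:, p])  # (n_p, 2)
                like = np.maximum(res[:, 0] / k, 1e-300)
                f_total += float(w_all[p] @ np.log(like))
                g_total += float(w_all[p] @ (res[:, 1] / (k * like)))
            return f_total, g_total

        return fg

    def _optimize_edge(self, piW, downs, ls_const, t0: float,
                       rtol: float = 1e-4) -> tuple[float, float]:
        """Maximize lnL along one branch: bracket the sign change of the
        derivative geometrically, then safeguarded secant iteration.  Never
        returns a point worse than the input length."""
        fg = self._edge_objective(piW, downs, ls_const)
        t0 = min(max(t0, BRLEN_MIN), BRLEN_MAX)
        f0, g0 = fg(t0)
        a = b = t0
        fa = fb = f0
        ga = gb = g0
        if g0 > 0:
            while gb > 0 and b < BRLEN_MAX:
                a, fa, ga = b, fb, gb
                b = min(b * 8.0, BRLEN_MAX)
                fb, gb = fg(b)
            if gb > 0:
                return (b, fb) if fb >= f0 else (t0, f0)
        else:
            while ga <= 0 and a > BRLEN_MIN:
                b, fb, gb = a, fa, ga
                a = max(a / 8.0, BRLEN_MIN)
                fa, ga = fg(a)
            if ga <= 0:
                return (a, fa) if fa >= f0 else (t0, f0)
        # ga > 0 >= gb: root of the derivative lies in (a, b)
        t, ft, gt = (a, fa, ga) if abs(ga) < abs(gb) else (b, fb, gb)
        t_prev, g_prev = (b, gb) if t == a else (a, ga)
        for _ in range(30):
            denom = g_prev - gt
            tn = t - gt * (t_prev - t) / denom if denom != 0 else np.sqrt(a * b)
            if not (a < tn < b):
                tn = np.sqrt(a * b) if b / max(a, BRLEN_MIN) > 16 else 0.5 * (a + b)
            fn, gn = fg(tn)
            if gn > 0:
                a, fa, ga = tn, fn, gn
            else:
                b, fb, gb = tn, fn, gn
            t_prev, g_prev = t, gt
            t, ft, gt = tn, fn, gn
            if abs(b - a) <= rtol * max(t, 1e-6) or gn == 0.0:
                break
        best_t, best_f = max(((a, fa), (b, fb), (t, ft)), key=lambda z: z[1])
        return (best_t, best_f) if best_f >= f0 else (t0, f0)

    def optimize_branch_lengths(self, tol: float = 0.01, max_sweeps: int = 50,
                                edges: Optional[set] = None,
                                warn: bool = True) -> float:
        """Sweep per-branch Brent optimization until the lnL improvement per
        sweep drops below `tol`.  If `edges` is given (a set of node ids),
        only those edges are re-optimized; partials are still propagated so
        the result is exact."""
        prev = None
        for sweep in range(max_sweeps):
            cur = self._sweep(edges)
            if cur is None:
                cur = self.full_pass()
            if prev is not None and cur - prev < tol:
                self._lnl = cur
                return cur
            prev = cur
        if warn:
            warnings.warn(f"branch optimization did not converge in {max_sweeps} sweeps")
        self._lnl = prev
        return prev

    def _sweep(self, edges: Optional[set] = None) -> Optional[float]:
        """One Gauss-Seidel pass; returns the exact tree lnL as of the last
        edge optimized (or None if no edge was optimized)."""
        last_val: list[Optional[float]] = [None]
        nparts = len(self.pm.parts)
        for p in range(nparts):
            for n in self.tree.postorder():
                if not n.is_leaf and id(n) not in self._down[p]:
                    self._combine_down(p, n)
        needed: Optional[set] = None
        if edges is not None:
            needed = set(edges)
            by_id = {id(n): n for n in self.tree.postorder()}
            for e in edges:
                n = by_id.get(e)
                while n is not None:
                    needed.add(id(n))
                    n = n.parent
        ones = [np.ones((len(self._cat[p]), self.data.patterns[p].shape[1], 4))
                for p in range(nparts)]
        zero = [np.zeros(self.data.patterns[p].shape[1]) for p in range(nparts)]

        def visit(u: Node, out_arr, out_ls) -> None:
            for c in u.children:
                if needed is not None and id(c) not in needed:
                    continue
                piW, downs, ls_const = [], [], 0.0
                W_arr, W_ls = [], []
                for p in range(nparts):
                    W = out_arr[p].copy()
                    wls = out_ls[p].copy()
                    for s in u.children:
                        if s is c:
                            continue
                        contrib, ls = self._edge_contrib(p, s)
                        W = W * contrib
                        wls = wls + ls
                    mx = W.max(axis=(0, 2))
                    mx = np.where(mx > 0, mx, 1.0)
                    W = W / mx[None, :, None]
                    wls = wls + np.log(mx)
                    if c.is_leaf:
                        d, dls = self._tip_partial(p, c)[None], zero[p]
                    else:
                        d, dls = self._down[p][id(c)]
                    piW.append(W * self._eig[p].pi[None, None, :])
                    downs.append(d)
                    ls_const += float(self.data.weights[p] @ (wls + dls))
                    W_arr.append(W)
                    W_ls.append(wls)
                if edges is None or id(c) in edges:
                    c.length, val = self._optimize_edge(piW, downs, ls_const, c.length)
                    last_val[0] = val
                if not c.is_leaf:
                    # outside partial of c with the updated edge length
                    child_out, child_ls = [], []
                    for p in range(nparts):
                        P = self._eig[p].transition(self._cat[p] * c.length)
                        # out[c](y) = sum_x P(t_c)[y,x] W(x)
                        o = W_arr[p] @ P.transpose(0, 2, 1)
                        mx = o.max(axis=(0, 2))
                        mx = np.where(mx > 0, mx, 1.0)
                        child_out.append(o / mx[None, :, None])
                        child_ls.append(W_ls[p] + np.log(mx))
                    visit(c, child_out, child_ls)
                    for p in range(nparts):
                        self._combine_down(p, c)  # refresh after subtree edits

        visit(self.tree.root, ones, zero)
        for p in range(nparts):
            self._combine_down(p, self.tree.root)  # root partial reflects new lengths
        return last_val[0]

    # -------------------------------------------------------- model inference
    def empirical_frequencies(self, p: int, pseudocount: float = 1.0) -> np.ndarray:
        pat = self.data.patterns[p]
        w = self.data.weights[p]
        counts = np.full(4, pseudocount)
        for s in range(4):
            counts[s] += ((pat == s) * w[None, :]).sum()
        return counts / counts.sum()

    def optimize_model(self, optimize_multipliers: bool = True,
                       rounds: int = 2) -> PartitionedModel:
        """Coordinate ascent over per-partition exchangeabilities, gamma
        shape and rate multiplier (empirical base frequencies); lnL never
        decreases."""
        for _ in range(rounds):
            for i, (pdef, model) in enumerate(self.pm.parts):
                pat = self.data.patterns[i]
                n_states = sum((pat == s).any(axis=0).astype(int) for s in range(4))
                variable = n_states > 1
                if pat.shape[1] <= 1 or not variable.any():
                    warnings.warn(
                        f"partition {pdef.name}: no variable patterns; "
                        f"alpha pinned at {ALPHA_MAX}, defaults kept")
                    self.set_partition_model(i, replace(
                        model, pi=model.pi, rates=model.rates, alpha=ALPHA_MAX))
                    continue
                pi = self.empirical_frequencies(i)
                base = np.concatenate([
                    np.log(model.rates[:5]),
                    [np.log(model.alpha)],
                    [np.log(model.rate_multiplier)] if optimize_multipliers else [],
                ])
                lo = np.concatenate([
                    np.full(5, np.log(RATE_MIN)), [np.log(ALPHA_MIN)],
                    [np.log(MULT_MIN)] if optimize_multipliers else []])
                hi = np.concatenate([
                    np.full(5, np.log(RATE_MAX)), [np.log(ALPHA_MAX)],
                    [np.log(MULT_MAX)] if optimize_multipliers else []])

                def unpack(x):
                    rates = np.concatenate([np.exp(x[:5]), [1.0]])
                    alpha = float(np.exp(x[5]))
                    mult = float(np.exp(x[6])) if optimize_multipliers else model.rate_multiplier
                    return GTRGammaModel(pi=pi, rates=rates, alpha=alpha,
                                         n_categories=model.n_categories,
                                         rate_multiplier=mult)

                def neg(x):
                    self.set_partition_model(i, unpack(x))
                    return -self._partition_lnl(i)

                start_lnl = -neg(base)
                res = minimize(neg, base, method="L-BFGS-B",
                               bounds=list(zip(lo, hi)),
                               options={"maxiter": 200, "ftol": 1e-8})
                if -res.fun >= start_lnl:
                    self.set_partition_model(i, unpack(res.x))
                else:  # pragma: no cover - LBFGS should not end worse
                    self.set_partition_model(i, unpack(base))
        if optimize_multipliers:
            self.pm.normalize_multipliers(self.tree)
            self._refresh_models()
        self._lnl = None
        return self.pm


# ------------------------------------------------------------------ functions

def tree_log_likelihood(tree: Tree, matrix: Supermatrix | PatternData,
                        pm: PartitionedModel) -> tuple[float, np.ndarray]:
    """Total log-likelihood and the per-site log-likelihood vector."""
    eng = LikelihoodEngine(tree, matrix, pm)
    site = eng.site_log_likelihoods()
    return float(site.sum()), site


def optimize_branch_lengths(tree: Tree, matrix: Supermatrix | PatternData,
                            pm: PartitionedModel, tol: float = 0.01) -> tuple[Tree, float]:
    eng = LikelihoodEngine(tree, matrix, pm)
    lnl = eng.optimize_branch_lengths(tol=tol)
    return tree, lnl


# ------------------------------------------------------------------ parsimony

def _pattern_masks(data: PatternData, p: int) -> np.ndarray:
    return _FITCH_MASK[data.patterns[p]]


def fitch_score(tree: Tree, column: Sequence[int] | np.ndarray,
                taxa: Optional[Sequence[str]] = None) -> int:
    """Minimum number of unordered state changes for one matrix column
    (codes as in formats.STATE_CODES; missing states are wildcards)."""
    column = np.asarray(column, dtype=np.uint8)
    if taxa is None:
        taxa = tree.leaf_labels()
    lookup = dict(zip(taxa, _FITCH_MASK[column]))
    score = 0
    sets: dict[int, int] = {}
    for n in tree.postorder():
        if n.is_leaf:
            sets[id(n)] = int(lookup[n.label])
            continue
        cur = None
        for c in n.children:
            s = sets.pop(id(c))
            if cur is None:
                cur = s
            else:
                inter = cur & s
                if inter:
                    cur = inter
                else:
                    cur = cur | s
                    score += 1
        sets[id(n)] = cur
    return score


def _fitch_total(tree: Tree, masks: list[np.ndarray], weights: list[np.ndarray],
                 rows: dict[str, int]) -> float:
    total = 0.0
    for pm_, w in zip(masks, weights):
        score = np.zeros(pm_.shape[1])
        sets: dict[int, np.ndarray] = {}
        for n in tree.postorder():
            if n.is_leaf:
                sets[id(n)] = pm_[rows[n.label]]
                continue
            cur = None
            for c in n.children:
                s = sets.pop(id(c))
                if cur is None:
                    cur = s.copy()
                else:
                    inter = cur & s
                    empty = inter == 0
                    score += empty
                    cur = np.where(empty, cur | s, inter)
            sets[id(n)] = cur
        total += float((score * w).sum())
    return total


def stepwise_addition_tree(matrix: Supermatrix | PatternData, seed: int) -> Tree:
    """Random-addition-order parsimony starting tree: each taxon joins the
    edge minimizing total Fitch length, ties to the first edge in preorder."""
    data = matrix if isinstance(matrix, PatternData) else PatternData.from_matrix(matrix)
    if len(data.taxa) < 3:
        raise TreeError("need at least 3 taxa for a starting tree")
    rng = np.random.default_rng(seed)
    order = [data.taxa[i] for i in rng.permutation(len(data.taxa))]
    rows = {t: i for i, t in enumerate(data.taxa)}
    masks = [_pattern_masks(data, p) for p in range(len(data.partitions))]
    weights = data.weights

    root = Node()
    for lab in order[:3]:
        root.add(Node(lab, 0.05))
    tree = Tree(root)

    for lab in order[3:]:
        down_sets, down_scores = [], []
        up_sets, up_scores = [], []
        for pm_, w in zip(masks, weights):
            dsets: dict[int, np.ndarray] = {}
            dscore: dict[int, np.ndarray] = {}
            for n in tree.postorder():
                if n.is_leaf:
                    dsets[id(n)] = pm_[rows[n.label]]
                    dscore[id(n)] = np.zeros(pm_.shape[1])
                    continue
                cur, sc = None, np.zeros(pm_.shape[1])
                for c in n.children:
                    s = dsets[id(c)]
                    sc = sc + dscore[id(c)]
                    if cur is None:
                        cur = s.copy()
                    else:
                        inter = cur & s
                        empty = inter == 0
                        sc += empty
                        cur = np.where(empty, cur | s, inter)
                dsets[id(n)] = cur
                dscore[id(n)] = sc
            usets: dict[int, np.ndarray] = {id(tree.root): np.full(pm_.shape[1], 15, dtype=np.uint8)}
            uscore: dict[int, np.ndarray] = {id(tree.root): np.zeros(pm_.shape[1])}
            for n in tree.preorder():
                if n.is_leaf:
                    continue
                for c in n.children:
                    cur = usets[id(n)].copy()
                    sc = uscore[id(n)].copy()
                    for s in n.children:
                        if s is c:
                            continue
                        ss = dsets[id(s)]
                        sc = sc + dscore[id(s)]
                        inter = cur & ss
                        empty = inter == 0
                        sc += empty
                        cur = np.where(empty, cur | ss, inter)
                    usets[id(c)] = cur
                    uscore[id(c)] = sc
            down_sets.append(dsets), down_scores.append(dscore)
            up_sets.append(usets), up_scores.append(uscore)

        best_edge, best_cost = None, np.inf
        candidates = [n for n in tree.preorder() if n is not tree.root]
        for cand in candidates:
            cost = 0.0
            for p, (pm_, w) in enumerate(zip(masks, weights)):
                d = down_sets[p][id(cand)]
                u = up_sets[p][id(cand)]
                sc = down_scores[p][id(cand)] + up_scores[p][id(cand)]
                leaf = pm_[rows[lab]]
                inter = d & u
                empty = inter == 0
                sc = sc + empty
                joined = np.where(empty, d | u, inter)
                inter2 = joined & leaf
                sc = sc + (inter2 == 0)
                cost += float((sc * w).sum())
            if cost < best_cost - 1e-9:
                best_cost, best_edge = cost, cand
        # attach on best edge: new internal node above best_edge
        p = best_edge.parent
        idx = p.children.index(best_edge)
        newint = Node(None, best_edge.length / 2.0)
        best_edge.length = best_edge.length / 2.0
        p.children[idx] = newint
        newint.parent = p
        newint.add(best_edge)
        newint.add(Node(lab, 0.05))
    for n in tree.postorder():
        if n is not tree.root:
            n.length = max(n.length, 0.05)
    return tree


# ------------------------------------------------------------------ NNI moves

def copy_with_map(tree: Tree) -> tuple[Tree, dict[int, Node]]:
    mapping: dict[int, Node] = {}

    def rec(n: Node) -> Node:
        m = Node(n.label, n.length)
        m.support = n.support
        mapping[id(n)] = m
        for c in n.children:
            m.add(rec(c))
        return m

    return Tree(rec(tree.root)), mapping


def nni_neighbors(tree: Tree, edge_child: Node
                  ) -> list[tuple[Tree, set, dict[int, Node]]]:
    """The two NNI rearrangements across an internal edge.  Returns
    (tree, local_edges, seedable) triples: local_edges are ids of the edges
    around the swapped edge in the new tree (for local re-optimization) and
    seedable maps original node ids to new nodes whose subtrees are
    unchanged (so cached partials may be reused)."""
    v = edge_child
    u = v.parent
    if u is None or v.is_leaf:
        raise TreeError("NNI requires an internal, non-root edge child")
    out = []
    if u is tree.root and len(u.children) == 2:
        w = [c for c in u.children if c is not v][0]
        if w.is_leaf:
            raise TreeError("edge is terminal in the unrooted tree")
        swaps = [(v.children[0], w.children[0]), (v.children[0], w.children[1])]
    else:
        sib = [c for c in u.children if c is not v][0]
        swaps = [(sib, v.children[0]), (sib, v.children[1])]
    for x, y in swaps:
        t2, m = copy_with_map(tree)
        x2, y2 = m[id(x)], m[id(y)]
        px, py = x2.parent, y2.parent
        ix, iy = px.children.index(x2), py.children.index(y2)
        px.children[ix], py.children[iy] = y2, x2
        x2.parent, y2.parent = py, px
        v2, u2 = m[id(v)], m[id(u)]
        local = {id(v2)} | {id(c) for c in v2.children}
        local |= {id(c) for c in u2.children if c is not v2}
        if u2 is not t2.root:
            local.add(id(u2))
        if u2 is t2.root and len(u2.children) == 2:
            w2 = [c for c in u2.children if c is not v2][0]
            local |= {id(c) for c in w2.children}
        dirty = set()
        for moved in (x2, y2):
            a = moved.parent
            while a is not None:
                dirty.add(id(a))
                a = a.parent
        seedable = {old: new for old, new in m.items()
                    if new.children and id(new) not in dirty}
        out.append((t2, local, seedable))
    return out


def nni_search(tree: Tree, matrix: Supermatrix | PatternData, pm: PartitionedModel,
               tol: float = 1e-3, max_rounds: int = 30) -> tuple[Tree, float]:
    """Hill-climb over NNI rearrangements.  Each candidate is scored after
    local (5-edge) branch re-optimization; the best strict improvement at an
    edge is accepted; terminates when no edge improves.  Ends with a full
    branch-length re-optimization."""
    data = matrix if isinstance(matrix, PatternData) else PatternData.from_matrix(matrix)
    eng = LikelihoodEngine(tree, data, pm)
    best_lnl = eng.optimize_branch_lengths(tol=0.05, max_sweeps=8, warn=False)
    accepts, stale = 0, False
    while accepts < max_rounds * len(tree.leaf_labels()):
        edges = list(tree.internal_edges())
        improved = False
        for v in edges:
            cand_best = None
            for t2, local, seedable in nni_neighbors(tree, v):
                e2 = LikelihoodEngine(t2, data, pm)
                e2.seed_down(eng, seedable)
                lnl2 = e2.optimize_branch_lengths(tol=0.5, max_sweeps=1,
                                                  edges=local, warn=False)
                if lnl2 > best_lnl + tol and (cand_best is None or lnl2 > cand_best[2]):
                    cand_best = (t2, e2, lnl2)
            if cand_best is not None:
                tree, eng, _ = cand_best
                best_lnl = eng.optimize_branch_lengths(tol=0.05, max_sweeps=2, warn=False)
                improved, stale = True, True
                accepts += 1
                break  # edge list refers to the old tree; rescan
        if not improved:
            if stale:
                # re-polish lengths once and give the scan a final chance
                best_lnl = eng.optimize_branch_lengths(tol=0.01, max_sweeps=10, warn=False)
                stale = False
                continue
            break
    eng = LikelihoodEngine(tree, data, pm)
    best_lnl = eng.optimize_branch_lengths(tol=0.01, max_sweeps=20)
    return tree, best_lnl


def ml_search(matrix: Supermatrix | PatternData, pm: PartitionedModel,
              n_starts: int = 11, seed: int = 0,
              optimize_model_first: bool = True) -> tuple[Tree, float]:
    """The published search protocol: `n_starts` seeded stepwise-addition
    parsimony trees, each NNI-optimized; best final lnL wins (ties to the
    first seed)."""
    data = matrix if isinstance(matrix, PatternData) else PatternData.from_matrix(matrix)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_starts)]
    best: tuple[Optional[Tree], float] = (None, -np.inf)
    for i, s in enumerate(child_seeds):
        start = stepwise_addition_tree(data, s)
        start.deroot()
        if optimize_model_first and i == 0:
            eng = LikelihoodEngine(start, data, pm)
            eng.optimize_branch_lengths(tol=0.1, max_sweeps=5)
            eng.optimize_model(rounds=1)
        t, lnl = nni_search(start, data, pm)
        if lnl > best[1] + 1e-9:
            best = (t, lnl)
    return best  # type: ignore[return-value]
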