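"""Conditional-inference tree for a categorical response.

A deliberately compact recursive-partitioning scheme in the conditional-
inference tradition: at each node every covariate's association with the
response is tested by a Monte-Carlo permutation test on a linear statistic
(per-class sums of the covariate), the resulting p-values are Bonferroni-
adjusted across covariates, and partitioning stops when the smallest adjusted
p-value is not below ``alpha`` or the node is too small. The selected
covariate is split at the cut-point maximizing the two-sample (left/right)
Pearson chi-square of the class distribution, searching all midpoints between
consecutive distinct values, ties broken toward the smaller threshold.

Separating variable selection (permutation test) from cut-point search keeps
the selection unbiased toward covariates with many candidate splits, which is
the point of conditional-inference partitioning over exhaustive-search CART.
This implementation targets the statistical idea, not bit-compatibility with
any existing partitioning package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CtreeNode", "ctree_fit"]


@dataclass
class CtreeNode:
    """One node of a fitted tree; terminal nodes carry the class distribution."""

    n: int
    class_counts: dict[str, int]
    depth: int
    split_var: str | None = None
    threshold: float | None = None
    p_adjusted: float | None = None
    left: "CtreeNode | None" = None
    right: "CtreeNode | None" = None
    node_p_values: dict[str, float] = field(default_factory=dict)

    @property
    def is_terminal(self) -> bool:
        return self.split_var is None

    def majority_class(self) -> str:
        return max(sorted(self.class_counts), key=lambda k: self.class_counts[k])

    def depth_below(self) -> int:
        if self.is_terminal:
            return 0
        return 1 + max(self.left.depth_below(), self.right.depth_below())

    def render(self) -> str:
        lines: list[str] = []

        def rec(node: CtreeNode, prefix: str, tag: str) -> None:
            counts = ", ".join(f"{k}:{v}" for k, v in sorted(node.class_counts.items()))
            if node.is_terminal:
                lines.append(f"{prefix}{tag}* n={node.n} [{counts}]")
            else:
                lines.append(
                    f"{prefix}{tag}{node.split_var} <= {node.threshold:.4g} "
                    f"(p_adj={node.p_adjusted:.4g}, n={node.n})"
                )
                rec(node.left, prefix + "  ", "yes: ")
                rec(node.right, prefix + "  ", "no:  ")

        rec(self, "", "")
        return "\n".join(lines)


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (y[:, None] == classes[None, :]).astype(float)


def _perm_p_value(x: np.ndarray, Y: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    """Monte-Carlo permutation p for association of covariate x with one-hot Y.

    Test statistic: max over classes of the absolute standardized linear
    statistic sum_i x_i 1(y_i = k); standardization moments are estimated from
    the permutation sample itself.
    """
    n = len(x)
    t_obs = x @ Y  # (k,)
    perms = np.empty((n_perm, n), dtype=x.dtype)
    for r in range(n_perm):
        perms[r] = x[rng.permutation(n)]
    t_perm = perms @ Y  # (n_perm, k)
    mu = t_perm.mean(axis=0)
    sd = t_perm.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    s_obs = np.max(np.abs(t_obs - mu) / sd)
    s_perm = np.max(np.abs(t_perm - mu) / sd, axis=1)
    return float((1 + np.sum(s_perm >= s_obs - 1e-12)) / (n_perm + 1))


def _best_cut(x: np.ndarray, Y: np.ndarray, min_leaf: int) -> tuple[float, float] | None:
    """Cut-point of x maximizing the left/right Pearson chi-square on classes.

    Returns (threshold, statistic) or None when no admissible cut leaves at
    least ``min_leaf`` observations on each side. Ties go to the smaller
    threshold.
    """
    order = np.argsort(x, kind="stable")
    xs, Ys = x[order], Y[order]
    n, k = Ys.shape
    totals = Ys.sum(axis=0)
    cum = np.cumsum(Ys, axis=0)
    best: tuple[float, float] | None = None
    for i in range(min_leaf - 1, n - min_leaf):
        if xs[i] == xs[i + 1]:
            continue
        n_l = i + 1
        n_r = n - n_l
        left = cum[i]
        exp_l = totals * (n_l / n)
        exp_r = totals * (n_r / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi = np.nansum(
                np.where(exp_l > 0, (left - exp_l) ** 2 / exp_l, 0.0)
                + np.where(exp_r > 0, ((totals - left) - exp_r) ** 2 / exp_r, 0.0)
            )
        thr = 0.5 * (xs[i] + xs[i + 1])
        if best is None or chi > best[1] + 1e-12:
            best = (float(thr), float(chi))
    return best


def ctree_fit(
    X,
    y,
    alpha: float = 0.05,
    n_perm: int = 9999,
    min_node: int = 10,
    min_leaf: int = 5,
    max_depth: int | None = None,
    seed: int | np.random.Generator = 0,
) -> CtreeNode:
    """Fit a conditional-inference tree.

    Parameters
    ----------
    X : DataFrame of numeric covariates (no missing / non-finite values).
    y : categorical response labels, one per row of X.
    alpha : stop when the smallest Bonferroni-adjusted permutation p is >= alpha.
    n_perm : Monte-Carlo permutations per covariate test.
    min_node : smallest node that may be tested for a split.
    min_leaf : smallest admissible child.
    max_depth : optional depth cap (None = unlimited).
    seed : seed or Generator for the permutation stream; fits are
        deterministic given the seed.
    """
    X = pd.DataFrame(X)
    Xv = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("covariates must be finite")
    y = np.asarray(y)
    if len(y) != len(X):
        raise ValueError("X and y lengths differ")
    classes = np.unique(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = list(X.columns)

    def grow(idx: np.ndarray, depth: int) -> CtreeNode:
        yk = y[idx]
        counts = {str(c): int(np.sum(yk == c)) for c in classes}
        node = CtreeNode(n=len(idx), class_counts=counts, depth=depth)
        if len(idx) < min_node or len(np.unique(yk)) < 2:
            return node
        if max_depth is not None and depth >= max_depth:
            return node
        Y = _one_hot(yk, classes)
        pvals = {}
        for j, c in enumerate(cols):
            xj = Xv[idx, j]
            if np.all(xj == xj[0]):
                pvals[c] = 1.0
            else:
                pvals[c] = min(1.0, _perm_p_value(xj, Y, n_perm, rng) * len(cols))
        node.node_p_values = pvals
        best_var = min(cols, key=lambda c: (pvals[c], cols.index(c)))
        if pvals[best_var] >= alpha:
            return node
        cut = _best_cut(Xv[idx, cols.index(best_var)], Y, min_leaf)
        if cut is None:
            return node
        thr, _ = cut
        mask = Xv[idx, cols.index(best_var)] <= thr
        node.split_var = best_var
        node.threshold = thr
        node.p_adjusted = pvals[best_var]
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    return grow(np.arange(len(y)), 0)
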