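"""CHAID decision trees with bootstrap complexity selection and k-fold CV.

Chi-square Automatic Interaction Detection grows a tree over categorical
features by, at each node and for each feature, iteratively merging the pair
of category groups whose class distributions are most alike (largest
pairwise chi-square p-value) until every pairwise p is below the merge
threshold or only two groups remain; the node then splits on the feature
with the smallest Bonferroni-adjusted chi-square p-value, provided it clears
the split threshold, respects the minimum child size and the depth cap.

The Bonferroni multiplier for a nominal feature is the number of ways its
``c`` observed categories can collapse into the ``r`` merged groups — the
Stirling number of the second kind S(c, r).

Complexity (depth / node size) is chosen by out-of-bag misclassification
over bootstrap resamples, with ties resolved toward simpler trees, and
operating characteristics (sensitivity, specificity, PPV, NPV with exact
Clopper–Pearson 95% intervals) are estimated by stratified k-fold
cross-validation pooling the out-of-fold predictions into one confusion
matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChaidParams",
    "ChaidNode",
    "ChaidTree",
    "ValidityReport",
    "fit_chaid",
    "bootstrap_select",
    "cross_validate",
    "validity_metrics",
    "stirling2",
    "tree_to_expression",
]


@dataclass(frozen=True)
class ChaidParams:
    alpha_merge: float = 0.05
    alpha_split: float = 0.05
    min_node_size: int = 30
    max_depth: int = 3
    bonferroni: bool = True

    def __post_init__(self):
        if not (0 < self.alpha_merge < 1 and 0 < self.alpha_split < 1):
            raise ValueError("alpha values must lie in (0, 1)")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")


@dataclass
class ChaidNode:
    n: int
    n_positive: int
    depth: int
    feature: str | None = None          # None at leaves
    groups: list[tuple] = field(default_factory=list)
    children: list["ChaidNode"] = field(default_factory=list)
    chi2: float = 0.0
    p_adjusted: float = 1.0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def p_positive(self) -> float:
        return self.n_positive / self.n if self.n else 0.0

    @property
    def predicted(self) -> bool:
        return self.n_positive * 2 > self.n

    def to_dict(self) -> dict:
        d = {"n": self.n, "n_positive": self.n_positive, "depth": self.depth,
             "p_positive": self.p_positive}
        if not self.is_leaf:
            d.update({"feature": self.feature,
                      "groups": [list(g) for g in self.groups],
                      "chi2": self.chi2, "p_adjusted": self.p_adjusted,
                      "children": [c.to_dict() for c in self.children]})
        return d


@dataclass
class ChaidTree:
    root: ChaidNode
    params: ChaidParams
    features: list[str]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(X), dtype=bool)
        cols = {f: X[f].to_numpy() for f in self.features if f in X.columns}
        for i in range(len(X)):
            node = self.root
            while not node.is_leaf:
                value = cols[node.feature][i]
                child = None
                for g, c in zip(node.groups, node.children):
                    if value in g:
                        child = c
                        break
                if child is None:       # unseen category: stop at this node
                    break
                node = child
            out[i] = node.predicted
        return out

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(X), dtype=float)
        cols = {f: X[f].to_numpy() for f in self.features if f in X.columns}
        for i in range(len(X)):
            node = self.root
            while not node.is_leaf:
                value = cols[node.feature][i]
                child = next((c for g, c in zip(node.groups, node.children)
                              if value in g), None)
                if child is None:
                    break
                node = child
            out[i] = node.p_positive
        return out

    def depth(self) -> int:
        def walk(node):
            if node.is_leaf:
                return 0
            return 1 + max(walk(c) for c in node.children)
        return walk(self.root)

    def to_dict(self) -> dict:
        return {"params": self.params.__dict__, "features": self.features,
                "tree": self.root.to_dict()}


# ---------------------------------------------------------------------------
# chi-square machinery


def _chi2_groups(y_counts: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square of an r×2 (group × class) count table.

    Zero-margin rows/columns are dropped; degenerate tables give (0, 1).
    """
    t = y_counts[y_counts.sum(axis=1) > 0]
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0, 1.0
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


@lru_cache(maxsize=None)
def stirling2(c: int, r: int) -> int:
    """Number of partitions of c labelled categories into r non-empty groups."""
    if r < 0 or r > c:
        return 0
    if c == r or r == 1:
        return 1 if r >= 1 or c == 0 else 0
    if r == 0:
        return 1 if c == 0 else 0
    return r * stirling2(c - 1, r) + stirling2(c - 1, r - 1)


def _merge_categories(counts: dict, alpha_merge: float) -> list[tuple]:
    """CHAID merge step: greedy pairwise merging of most-alike groups.

    ``counts`` maps category -> (n_negative, n_positive).  Returns merged
    groups (tuples of original categories) in deterministic order.
    """
    groups = [(cat,) for cat in sorted(counts, key=str)]
    tallies = {g: np.array(counts[g[0]], dtype=float) for g in groups}
    while len(groups) > 2:
        best_p, best_pair = -1.0, None
        for a, b in itertools.combinations(range(len(groups)), 2):
            _, p = _chi2_groups(np.vstack([tallies[groups[a]], tallies[groups[b]]]))
            if p > best_p:
                best_p, best_pair = p, (a, b)
        if best_p < alpha_merge:
            break
        a, b = best_pair
        merged = tuple(sorted(groups[a] + groups[b], key=str))
        tallies[merged] = tallies.pop(groups[a]) + tallies.pop(groups[b])
        groups = [g for i, g in enumerate(groups) if i not in (a, b)]
        groups.append(merged)
        groups.sort(key=str)
    return groups


def _evaluate_feature(values: np.ndarray, y: np.ndarray, params: ChaidParams):
    """Merge categories then score the split; None if unsplittable."""
    cats = pd.unique(values)
    if len(cats) < 2:
        return None
    counts = {}
    for cat in cats:
        mask = values == cat
        pos = int(y[mask].sum())
        counts[cat] = (int(mask.sum()) - pos, pos)
    groups = _merge_categories(counts, params.alpha_merge)
    if len(groups) < 2:
        return None
    table = np.array([np.sum([counts[c] for c in g], axis=0) for g in groups],
                     dtype=float)
    chi2, p = _chi2_groups(table)
    if params.bonferroni:
        p = min(1.0, p * stirling2(len(cats), len(groups)))
    sizes = table.sum(axis=1)
    if (sizes < params.min_node_size).any():
        return None
    return {"groups": groups, "chi2": chi2, "p_adjusted": p}


def fit_chaid(X: pd.DataFrame, y, params: ChaidParams | None = None) -> ChaidTree:
    """Grow a CHAID tree on categorical features and a binary outcome."""
    if params is None:
        params = ChaidParams()
    y = np.asarray(y, dtype=bool)
    if len(X) < 2 or X.shape[1] < 1:
        raise ValueError("need at least 2 rows and 1 feature")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    for col in X.columns:
        if pd.api.types.is_float_dtype(X[col]):
            raise TypeError(f"feature {col!r} is continuous; CHAID needs categoricals")

    features = list(X.columns)
    arrays = {f: X[f].to_numpy() for f in features}

    def grow(idx: np.ndarray, depth: int) -> ChaidNode:
        node = ChaidNode(n=len(idx), n_positive=int(y[idx].sum()), depth=depth)
        if depth >= params.max_depth or node.n_positive in (0, node.n):
            return node
        best_name, best = None, None
        for f in features:
            cand = _evaluate_feature(arrays[f][idx], y[idx], params)
            if cand is None or cand["p_adjusted"] > params.alpha_split:
                continue
            if best is None or cand["p_adjusted"] < best["p_adjusted"]:
                best_name, best = f, cand
        if best is None:
            return node
        node.feature = best_name
        node.groups = best["groups"]
        node.chi2 = best["chi2"]
        node.p_adjusted = best["p_adjusted"]
        vals = arrays[best_name][idx]
        for g in best["groups"]:
            sub = idx[np.isin(vals, np.array(list(g), dtype=vals.dtype))]
            node.children.append(grow(sub, depth + 1))
        return node

    root = grow(np.arange(len(y)), 0)
    return ChaidTree(root=root, params=params, features=features)


# ---------------------------------------------------------------------------
# complexity selection and validation


def bootstrap_select(X: pd.DataFrame, y, params_grid, n_boot: int = 25,
                     seed: int = 0) -> ChaidParams:
    """Pick the grid candidate minimizing out-of-bag misclassification.

    Ties break toward smaller ``max_depth`` then larger ``min_node_size``
    (simpler trees).
    """
    grid = list(params_grid)
    if not grid:
        raise ValueError("params_grid is empty")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    y = np.asarray(y, dtype=bool)
    rng = np.random.default_rng(seed)
    n = len(y)
    # shared resamples across candidates for a paired comparison
    resamples = [rng.integers(0, n, size=n) for _ in range(n_boot)]
    scores = []
    for params in grid:
        errs = []
        for boot in resamples:
            oob = np.setdiff1d(np.arange(n), boot)
            if len(oob) == 0:
                continue
            tree = fit_chaid(X.iloc[boot].reset_index(drop=True), y[boot], params)
            pred = tree.predict(X.iloc[oob].reset_index(drop=True))
            errs.append(float(np.mean(pred != y[oob])))
        scores.append(float(np.mean(errs)) if errs else 1.0)
    order = sorted(range(len(grid)),
                   key=lambda i: (round(scores[i], 12), grid[i].max_depth,
                                  -grid[i].min_node_size))
    return grid[order[0]]


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold id per row; classes distributed round-robin after a seeded shuffle."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def cross_validate(X: pd.DataFrame, y, params: ChaidParams | None = None,
                   k: int = 10, seed: int = 0) -> "ValidityReport":
    """Stratified k-fold CV; out-of-fold predictions pool into one matrix."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y, dtype=bool)
    folds = _stratified_folds(y, k, seed)
    pred = np.empty(len(y), dtype=bool)
    for f in range(k):
        test = folds == f
        train = ~test
        if not test.any():
            continue
        if y[train].all() or not y[train].any():
            warnings.warn(f"fold {f}: training labels are constant")
        tree = fit_chaid(X[train].reset_index(drop=True), y[train], params)
        pred[test] = tree.predict(X[test].reset_index(drop=True))
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    return validity_metrics(tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# validity metrics


@dataclass(frozen=True)
class MetricEstimate:
    point: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ValidityReport:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate | None
    npv: MetricEstimate | None
    tp: int
    fp: int
    tn: int
    fn: int


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles."""
    alpha = 1.0 - conf
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def _estimate(x: int, n: int) -> MetricEstimate:
    lo, hi = clopper_pearson(x, n)
    return MetricEstimate(point=x / n, ci_low=lo, ci_high=hi)


def validity_metrics(tp: int, fp: int, tn: int, fn: int) -> ValidityReport:
    """Sensitivity, specificity, PPV, NPV with exact 95% intervals."""
    for v in (tp, fp, tn, fn):
        if v < 0:
            raise ValueError("confusion-matrix cells must be nonnegative")
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("need at least one positive and one negative truth")
    ppv = npv = None
    if tp + fp == 0:
        warnings.warn("no positive predictions; PPV undefined")
    else:
        ppv = _estimate(tp, tp + fp)
    if tn + fn == 0:
        warnings.warn("no negative predictions; NPV undefined")
    else:
        npv = _estimate(tn, tn + fn)
    return ValidityReport(
        sensitivity=_estimate(tp, tp + fn),
        specificity=_estimate(tn, tn + fp),
        ppv=ppv, npv=npv, tp=tp, fp=fp, tn=tn, fn=fn,
    )


# ---------------------------------------------------------------------------
# tree -> boolean rule conversion (binary presence features only)


def tree_to_expression(tree: ChaidTree):
    """Convert a tree over binary presence atoms into an OR-of-paths rule.

    Leaves predicted positive become AND-paths of their branch conditions;
    a group containing both values imposes no condition on that feature.
    Returns a nested ["or"/"and"/"not", ...] expression, or False/True when
    no or every leaf predicts positive.
    """
    paths = []

    def walk(node: ChaidNode, conds: list):
        if node.is_leaf:
            if node.predicted:
                paths.append(list(conds))
            return
        for g, child in zip(node.groups, node.children):
            vals = set(bool(v) for v in g)
            if vals == {True}:
                walk(child, conds + [node.feature])
            elif vals == {False}:
                walk(child, conds + [["not", node.feature]])
            else:
                walk(child, conds)

    walk(tree.root, [])
    if not paths:
        return False
    terms = [p[0] if len(p) == 1 else ["and", *p] for p in paths if p]
    if len(paths) != len(terms):     # an empty path: the root itself predicts positive
        return True
    return terms[0] if len(terms) == 1 else ["or", *terms]
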