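"""All-relevant feature selection against shadow features.

A Boruta-style wrapper around a random forest: in every iteration each
feature gets a freshly permuted *shadow* copy, a forest of bagged
decision trees is trained on the widened table, and each feature is
scored by out-of-bag (OOB) permutation importance — the drop in OOB
classification accuracy when the feature's values are permuted.  A
feature scores a *hit* when its importance exceeds the maximum shadow
importance of that iteration; across iterations a two-sided binomial
test on the hit count decides ``confirmed`` / ``rejected`` (``tentative``
otherwise).

Because single selection runs are noisy on small samples, the pipeline
works with *selection frequencies*: the number of runs (out of ``R``)
in which each variable was confirmed.  These counts are the importance
scale on which the error-control threshold operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree._criterion import Gini
from sklearn.tree._splitter import BestSplitter
from sklearn.tree._tree import DepthFirstTreeBuilder, Tree
from sklearn.utils.validation import check_random_state

from .dataset import TabularDataset, ValidationError

CONFIRMED = "confirmed"
TENTATIVE = "tentative"
REJECTED = "rejected"

#: random-forest defaults: 500 trees, sqrt(J) features per split
DEFAULT_TREES = 500
DEFAULT_MAX_ITER = 100
DEFAULT_ALPHA = 0.01

_NO_DEPTH_LIMIT = np.iinfo(np.int32).max


def _fit_tree(
    X32: np.ndarray,
    y2d: np.ndarray,
    n_classes: np.ndarray,
    max_features: int,
    seed: int,
    sample_weight: np.ndarray,
) -> Tree:
    """Grow one fully-developed Gini classification tree.

    Drives scikit-learn's tree primitives directly; the repeated-run
    selection fits tens of thousands of trees on tiny tables, where the
    estimator wrapper's per-fit overhead dominates the actual build.
    Produces trees identical to
    ``DecisionTreeClassifier(max_features=max_features,
    random_state=seed)`` fitted with the same sample weights (asserted
    in the test suite).
    """
    criterion = Gini(1, n_classes)
    splitter = BestSplitter(criterion, max_features, 1, 0.0, check_random_state(seed), None)
    tree = Tree(X32.shape[1], n_classes, 1)
    DepthFirstTreeBuilder(splitter, 2, 1, 0.0, _NO_DEPTH_LIMIT, 0.0).build(
        tree, X32, y2d, sample_weight, None
    )
    return tree


def _forest_oob_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """OOB permutation importance of every column of ``X``.

    Fits a random forest (sqrt-features splits, bootstrap per tree).
    For each tree, baseline accuracy on its out-of-bag rows is compared
    with the accuracy after permuting one column at a time (one shared
    permutation per column per call); the importance of a column is the
    mean accuracy drop across trees.  Returns (importances, mean
    baseline OOB accuracy).
    """
    n, F = X.shape
    classes, y_enc = np.unique(y, return_inverse=True)
    n_classes = np.array([len(classes)], dtype=np.intp)
    y2d = np.ascontiguousarray(y_enc, dtype=np.float64).reshape(-1, 1)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    max_features = max(1, int(np.sqrt(F)))
    perms = np.stack([rng.permutation(n) for _ in range(F)])
    # stacked evaluation matrix: block 0 unpermuted, block j+1 has
    # column j permuted; a single predict per tree covers all columns
    big = np.tile(X32, (F + 1, 1))
    rows = np.arange(n)
    for j in range(F):
        big[(j + 1) * n + rows, j] = X32[perms[j], j]

    imp = np.zeros(F)
    base = 0.0
    used = 0
    tree_seeds = rng.integers(0, 2**31 - 1, size=n_trees)
    for t in range(n_trees):
        trng = np.random.default_rng(int(tree_seeds[t]))
        idx = trng.integers(0, n, n)
        weight = np.bincount(idx, minlength=n).astype(np.float64)
        oob = weight == 0
        if not oob.any():
            continue
        tree = _fit_tree(X32, y2d, n_classes, max_features, int(tree_seeds[t] >> 1), weight)
        # leaf class-count values -> predicted class per row
        pred = tree.predict(big).reshape(F + 1, n, -1).argmax(axis=-1)
        correct = (pred == y_enc[None, :])[:, oob]
        acc0 = correct[0].mean()
        acc_perm = correct[1:].mean(axis=1)
        imp += acc0 - acc_perm
        base += acc0
        used += 1
    if used == 0:
        raise RuntimeError("no tree retained out-of-bag rows")
    return imp / used, base / used


@dataclass
class BorutaResult:
    """Outcome of a single selection run."""

    feature_names: list[str]
    decisions: dict[str, str]
    importances: dict[str, float]
    hits: dict[str, int]
    iterations: int
    shadow_max: float  # mean over iterations of the per-iteration max shadow importance

    def confirmed(self) -> list[str]:
        return [f for f in self.feature_names if self.decisions[f] == CONFIRMED]


def boruta_select(
    data: TabularDataset,
    max_iter: int = DEFAULT_MAX_ITER,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    n_trees: int = DEFAULT_TREES,
) -> BorutaResult:
    """One run of shadow-feature selection on ``data``.

    Shadows are internal: only the dataset's own features (original and
    engineered alike) appear in the returned decisions.
    """
    data.validate()
    data.require_classes(2)
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    X = data.values
    n, J = X.shape
    y = data.labels

    hits = np.zeros(J, dtype=int)
    imp_sum = np.zeros(J)
    shadow_max_sum = 0.0
    for _ in range(max_iter):
        shadow = np.empty_like(X)
        for j in range(J):
            shadow[:, j] = X[rng.permutation(n), j]
        imp, _ = _forest_oob_importance(np.hstack([X, shadow]), y, n_trees, rng)
        shadow_max = imp[J:].max()
        hits += imp[:J] > shadow_max
        imp_sum += imp[:J]
        shadow_max_sum += shadow_max

    decisions: dict[str, str] = {}
    for j, name in enumerate(data.feature_names):
        p = stats.binomtest(int(hits[j]), max_iter, 0.5).pvalue
        if p < alpha and hits[j] > max_iter / 2:
            decisions[name] = CONFIRMED
        elif p < alpha and hits[j] < max_iter / 2:
            decisions[name] = REJECTED
        else:
            decisions[name] = TENTATIVE
    return BorutaResult(
        feature_names=list(data.feature_names),
        decisions=decisions,
        importances={f: float(imp_sum[j] / max_iter) for j, f in enumerate(data.feature_names)},
        hits={f: int(hits[j]) for j, f in enumerate(data.feature_names)},
        iterations=max_iter,
        shadow_max=float(shadow_max_sum / max_iter),
    )


@dataclass
class SelectionProfile:
    """Aggregate of ``runs`` repeated selection runs."""

    feature_names: list[str]
    provenance: np.ndarray
    importance: dict[str, float]  # mean raw importance across runs
    decision: dict[str, str]  # modal decision across runs
    selection_count: dict[str, int]  # runs with decision == confirmed
    runs: int
    shadow_max_trace: list[float] = field(default_factory=list)

    def counts_for(self, names: list[str]) -> np.ndarray:
        return np.array([self.selection_count[f] for f in names], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "provenance": list(self.provenance),
                "importance": [self.importance[f] for f in self.feature_names],
                "decision": [self.decision[f] for f in self.feature_names],
                "count": [self.selection_count[f] for f in self.feature_names],
            }
        )


def selection_frequencies(
    data: TabularDataset,
    runs: int = 100,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    alpha: float = DEFAULT_ALPHA,
    n_trees: int = DEFAULT_TREES,
) -> SelectionProfile:
    """Repeat :func:`boruta_select` ``runs`` times with derived seeds
    and aggregate confirmed-selection counts and mean importances."""
    if runs < 1:
        raise ValueError("runs must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(runs) % (2**31)
    counts = {f: 0 for f in data.feature_names}
    imp = {f: 0.0 for f in data.feature_names}
    decision_votes = {f: {CONFIRMED: 0, TENTATIVE: 0, REJECTED: 0} for f in data.feature_names}
    shadow_trace: list[float] = []
    for r in range(runs):
        result = boruta_select(
            data, max_iter=max_iter, alpha=alpha, seed=int(child_seeds[r]), n_trees=n_trees
        )
        for f in data.feature_names:
            imp[f] += result.importances[f]
            decision_votes[f][result.decisions[f]] += 1
            if result.decisions[f] == CONFIRMED:
                counts[f] += 1
        shadow_trace.append(result.shadow_max)
    modal = {
        f: max((CONFIRMED, TENTATIVE, REJECTED), key=lambda d: votes[d])
        for f, votes in decision_votes.items()
    }
    return SelectionProfile(
        feature_names=list(data.feature_names),
        provenance=data.provenance.copy(),
        importance={f: imp[f] / runs for f in data.feature_names},
        decision=modal,
        selection_count=counts,
        runs=runs,
        shadow_max_trace=shadow_trace,
    )


def delta_importance(profile: SelectionProfile, counterpart_map: dict[str, str]) -> dict[str, float]:
    """Importance difference of each original variable over its
    engineered counterpart, on the selection-count scale:
    ``delta[j] = count(X_j) - count(X_j_perm)``."""
    if not counterpart_map:
        raise ValidationError("counterpart_map is empty; engineer controls first")
    delta: dict[str, float] = {}
    for orig, perm in counterpart_map.items():
        if orig not in profile.selection_count or perm not in profile.selection_count:
            raise ValidationError(f"profile is missing '{orig}' or its counterpart '{perm}'")
        delta[orig] = float(profile.selection_count[orig] - profile.selection_count[perm])
    return delta
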