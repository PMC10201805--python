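"""Random-forest out-of-bag permutation importance and recursive elimination.

The importance of feature j is the mean, over K bootstrap-trained trees,
of the drop in that tree's out-of-bag (OOB) accuracy when column j is
permuted within the OOB rows:

    P_j = (1/K) * sum_k (L_k^OOB - L_{k,j}^OOB)

This per-tree accuracy-drop statistic is computed here explicitly — it is
not the impurity-based importance that forest libraries report.  The
recursive selector recomputes P_j on the surviving feature set each round
and drops the single least important feature until k features remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .io import FeatureMatrix


@dataclass
class ImportanceRanking:
    """Per-feature permutation importances plus per-tree bookkeeping."""

    scores: Dict[str, float]
    n_trees: int
    per_tree_deltas: Optional[np.ndarray] = None  # K x n_features
    n_empty_oob: int = 0

    def ordered(self) -> List[Tuple[str, float]]:
        """(name, P_j) pairs, most important first; ties broken by name."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class EliminationTrace:
    """Audit trail of the recursive elimination, one entry per round."""

    rounds: List[Tuple[str, float, int]] = field(default_factory=list)

    def record(self, name: str, score: float, surviving: int) -> None:
        self.rounds.append((name, score, surviving))

    @property
    def eliminated(self) -> List[str]:
        return [name for name, _, _ in self.rounds]


def _tree_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def _perm_rng(seed: int, k: int, j: int) -> np.random.Generator:
    # permutation seeded deterministically from (seed, tree, feature)
    return np.random.default_rng(np.random.SeedSequence([seed, k, 7919 + j]))


def oob_importance(
    fm: FeatureMatrix, n_trees: int = 200, seed: int = 0
) -> ImportanceRanking:
    """Permutation importance from K bootstrap-trained CART trees.

    Each tree is grown (Gini criterion, unlimited depth) on a bootstrap
    sample of n rows; its OOB rows give the baseline accuracy, and each
    feature's accuracy is re-measured after permuting that column within
    the OOB rows.  A tree whose OOB set is empty contributes zero deltas
    (counted in ``n_empty_oob``).
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X, y = fm.values, np.asarray(fm.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to fit the forest")
    n, p = X.shape
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB00]))
    deltas = np.zeros((n_trees, p))
    n_empty = 0
    for k in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[boot] = False
        if not oob_mask.any():
            n_empty += 1
            continue
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features="sqrt",
            random_state=_tree_seed(seed, k),
        )
        tree.fit(X[boot], y[boot])
        X_oob, y_oob = X[oob_mask], y[oob_mask]
        baseline = float(np.mean(tree.predict(X_oob) == y_oob))
        for j in range(p):
            perm = _perm_rng(seed, k, j).permutation(X_oob.shape[0])
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            permuted = float(np.mean(tree.predict(X_perm) == y_oob))
            deltas[k, j] = baseline - permuted
    scores = {name: float(deltas[:, j].mean()) for j, name in enumerate(fm.feature_names)}
    return ImportanceRanking(scores, n_trees, per_tree_deltas=deltas, n_empty_oob=n_empty)


def recursive_select(
    fm: FeatureMatrix, k_final: int = 10, n_trees: int = 200, seed: int = 0
) -> Tuple[List[str], EliminationTrace]:
    """Backward elimination: re-rank each round, drop the least important.

    Ties on the minimum score are broken by taking the lexicographically
    last name (recorded in the trace like any other elimination).  Returns
    the survivors ordered by final-round importance, plus the trace.
    """
    if k_final < 1:
        raise ValueError("k_final must be >= 1")
    if k_final > len(fm.feature_names):
        raise ValueError(
            f"k_final={k_final} exceeds the {len(fm.feature_names)} available features"
        )
    current = fm
    trace = EliminationTrace()
    ranking = oob_importance(current, n_trees=n_trees, seed=seed)
    while len(current.feature_names) > k_final:
        min_score = min(ranking.scores.values())
        worst = max(n for n, s in ranking.scores.items() if s == min_score)
        trace.record(worst, ranking.scores[worst], len(current.feature_names) - 1)
        survivors = [n for n in current.feature_names if n != worst]
        current = current.restrict(survivors)
        ranking = oob_importance(current, n_trees=n_trees, seed=seed)
    selected = [name for name, _ in ranking.ordered()]
    return selected, trace
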