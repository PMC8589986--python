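"""Balanced random-forest classifier with out-of-bag evaluation.

Each tree is trained on an equal number of samples per class drawn
*without replacement* (explicit per-tree sampler, not class weights), so
unbalanced datasets do not bias the vote.  OOB predictions are majority
votes over the trees for which a sample was out-of-bag; ties resolve to
the first class in sorted order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_COLUMNS

__all__ = [
    "ForestConfig",
    "ConfusionSummary",
    "BalancedRandomForest",
    "fit_balanced_forest",
    "sensitivity_grid",
    "classification_summary",
    "proximity_mds",
]


@dataclass(frozen=True)
class ForestConfig:
    """mtry defaults to floor(sqrt(n_features)); sampsize to half the
    smallest class."""

    mtry: int | None = None
    sampsize: int | None = None
    ntree: int = 10_000
    seed: int | None = None


@dataclass
class ConfusionSummary:
    class_names: list[str]
    counts: np.ndarray  # a-priori rows x predicted columns
    class_rates_pct: dict[str, float]
    class_ci_pct: dict[str, tuple[float, float]]
    class_p: dict[str, float]
    overall_rate_pct: float
    overall_ci_pct: tuple[float, float]
    overall_p: float

    def to_dict(self) -> dict:
        return {
            "classes": self.class_names,
            "counts": self.counts.tolist(),
            "class_rates_pct": self.class_rates_pct,
            "class_ci_pct": {k: list(v) for k, v in self.class_ci_pct.items()},
            "class_p": self.class_p,
            "overall_rate_pct": self.overall_rate_pct,
            "overall_ci_pct": list(self.overall_ci_pct),
            "overall_p": self.overall_p,
        }


def _exact_ci_pct(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    ci = binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return (100.0 * ci.low, 100.0 * ci.high)


def classification_summary(counts: np.ndarray, class_names: list[str]) -> ConfusionSummary:
    """Rates, exact (Clopper-Pearson) 95% CIs, and one-sided binomial
    p-values against a 0.5 chance rate, from a confusion-count matrix."""
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("counts must be a square matrix")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    rates, cis, ps = {}, {}, {}
    for i, name in enumerate(class_names):
        n = int(counts[i].sum())
        k = int(counts[i, i])
        if n == 0:
            rates[name], cis[name], ps[name] = float("nan"), (float("nan"), float("nan")), float("nan")
            continue
        rates[name] = 100.0 * k / n
        cis[name] = _exact_ci_pct(k, n)
        ps[name] = binomtest(k, n, 0.5, alternative="greater").pvalue
    n_tot = int(counts.sum())
    k_tot = int(np.trace(counts))
    return ConfusionSummary(
        class_names=list(class_names),
        counts=counts,
        class_rates_pct=rates,
        class_ci_pct=cis,
        class_p=ps,
        overall_rate_pct=100.0 * k_tot / n_tot if n_tot else float("nan"),
        overall_ci_pct=_exact_ci_pct(k_tot, n_tot) if n_tot else (float("nan"), float("nan")),
        overall_p=binomtest(k_tot, n_tot, 0.5, alternative="greater").pvalue if n_tot else float("nan"),
    )


class BalancedRandomForest:
    """Forest of CART trees over balanced, without-replacement draws."""

    def __init__(self, config: ForestConfig = ForestConfig()):
        self.config = config
        self.trees_: list[DecisionTreeClassifier] = []
        self.inbag_: list[np.ndarray] = []
        self.classes_: np.ndarray | None = None
        self.oob_votes_: np.ndarray | None = None
        self.oob_trace_: list[tuple[int, float]] = []
        self._X: np.ndarray | None = None

    # -- fitting -----------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, trace_points: int = 50) -> "BalancedRandomForest":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        k = self.classes_.size
        if k < 2:
            raise ValueError("need at least two classes")
        y_codes = np.searchsorted(self.classes_, y)
        class_idx = [np.flatnonzero(y_codes == c) for c in range(k)]
        smallest = min(idx.size for idx in class_idx)
        sampsize = self.config.sampsize if self.config.sampsize is not None else max(1, smallest // 2)
        if sampsize > smallest:
            raise ValueError(f"sampsize {sampsize} exceeds smallest class size {smallest}")
        n_feat = X.shape[1]
        mtry = self.config.mtry if self.config.mtry is not None else max(1, int(np.sqrt(n_feat)))
        if not 1 <= mtry <= n_feat:
            raise ValueError(f"mtry {mtry} outside [1, {n_feat}]")
        rng = np.random.default_rng(self.config.seed)
        n = X.shape[0]
        votes = np.zeros((n, k), dtype=np.int32)
        oob_mask = np.ones(n, dtype=bool)
        trace_every = max(1, self.config.ntree // max(trace_points, 1))
        self.trees_, self.inbag_, self.oob_trace_ = [], [], []
        for t in range(self.config.ntree):
            inbag = np.concatenate([rng.choice(idx, size=sampsize, replace=False) for idx in class_idx])
            tree = DecisionTreeClassifier(
                max_features=mtry,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[inbag], y_codes[inbag])
            oob_mask[:] = True
            oob_mask[inbag] = False
            pred = tree.predict(X[oob_mask]).astype(int)
            votes[np.flatnonzero(oob_mask), pred] += 1
            self.trees_.append(tree)
            self.inbag_.append(inbag)
            if (t + 1) % trace_every == 0 or t + 1 == self.config.ntree:
                self.oob_trace_.append((t + 1, self._oob_error(votes, y_codes)))
        self.oob_votes_ = votes
        self._y_codes = y_codes
        self._X = X
        self._sampsize = sampsize
        self._mtry = mtry
        return self

    @staticmethod
    def _oob_error(votes: np.ndarray, y_codes: np.ndarray) -> float:
        seen = votes.sum(axis=1) > 0
        if not seen.any():
            return float("nan")
        pred = votes[seen].argmax(axis=1)
        return float(np.mean(pred != y_codes[seen]))

    # -- OOB results -------------------------------------------------
    def oob_predictions(self) -> np.ndarray:
        """Majority-vote OOB class label per sample (ties -> first class)."""
        assert self.oob_votes_ is not None
        return self.classes_[self.oob_votes_.argmax(axis=1)]

    def oob_confusion(self) -> np.ndarray:
        pred_codes = self.oob_votes_.argmax(axis=1)
        k = self.classes_.size
        counts = np.zeros((k, k), dtype=int)
        np.add.at(counts, (self._y_codes, pred_codes), 1)
        return counts

    def oob_summary(self) -> ConfusionSummary:
        return classification_summary(self.oob_confusion(), [str(c) for c in self.classes_])

    def oob_vote_fractions(self) -> np.ndarray:
        """Per-sample OOB vote distribution over classes.

        Samples never out-of-bag get the neutral uniform distribution.
        """
        votes = self.oob_votes_.astype(float)
        tot = votes.sum(axis=1, keepdims=True)
        k = self.classes_.size
        out = np.full_like(votes, 1.0 / k)
        seen = tot[:, 0] > 0
        out[seen] = votes[seen] / tot[seen]
        return out

    # -- prediction --------------------------------------------------
    def predict_votes(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting for each class (rows sum to 1)."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        k = self.classes_.size
        votes = np.zeros((X.shape[0], k))
        for tree in self.trees_:
            pred = tree.predict(X).astype(int)
            votes[np.arange(X.shape[0]), pred] += 1
        return votes / len(self.trees_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_votes(X).argmax(axis=1)]

    # -- proximity ---------------------------------------------------
    def proximity(self, X: np.ndarray | None = None) -> np.ndarray:
        """Fraction of trees in which two samples share a terminal node."""
        X = self._X if X is None else np.ascontiguousarray(X, dtype=np.float64)
        n = X.shape[0]
        prox = np.zeros((n, n))
        for tree in self.trees_:
            leaves = tree.apply(X)
            prox += leaves[:, None] == leaves[None, :]
        return prox / len(self.trees_)

    # -- importance --------------------------------------------------
    def permutation_importance(
        self, rng: np.random.Generator | None = None, max_trees: int | None = None
    ) -> np.ndarray:
        """Mean decrease in OOB accuracy under per-tree feature permutation."""
        rng = rng if rng is not None else np.random.default_rng(self.config.seed)
        X, y = self._X, self._y_codes
        n_feat = X.shape[1]
        tree_idx = np.arange(len(self.trees_))
        if max_trees is not None and max_trees < tree_idx.size:
            tree_idx = rng.choice(tree_idx, size=max_trees, replace=False)
        drops = np.zeros(n_feat)
        used = 0
        for ti in tree_idx:
            tree, inbag = self.trees_[ti], self.inbag_[ti]
            oob = np.setdiff1d(np.arange(X.shape[0]), inbag)
            if oob.size == 0:
                continue
            base = np.mean(tree.predict(X[oob]).astype(int) == y[oob])
            X_oob = X[oob].copy()
            for f in range(n_feat):
                saved = X_oob[:, f].copy()
                X_oob[:, f] = saved[rng.permutation(oob.size)]
                acc = np.mean(tree.predict(X_oob).astype(int) == y[oob])
                drops[f] += base - acc
                X_oob[:, f] = saved
            used += 1
        return drops / max(used, 1)

    def gini_importance(self) -> np.ndarray:
        return np.mean([t.feature_importances_ for t in self.trees_], axis=0)


def fit_balanced_forest(
    table: pd.DataFrame,
    config: ForestConfig = ForestConfig(),
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS,
    label_column: str = "species",
    compute_importance: bool = True,
    importance_max_trees: int | None = 500,
):
    """Fit the event classifier on a feature table.

    Returns ``(model, ConfusionSummary, importance DataFrame, OOB trace
    DataFrame)``.
    """
    X = table[list(feature_columns)].to_numpy(dtype=float)
    y = table[label_column].to_numpy()
    model = BalancedRandomForest(config).fit(X, y)
    summary = model.oob_summary()
    if compute_importance:
        imp = model.permutation_importance(max_trees=importance_max_trees)
        importance = (
            pd.DataFrame(
                {
                    "feature": feature_columns,
                    "mean_decrease_accuracy": imp,
                    "gini_importance": model.gini_importance(),
                }
            )
            .sort_values("mean_decrease_accuracy", ascending=False)
            .reset_index(drop=True)
        )
    else:
        importance = pd.DataFrame(columns=["feature", "mean_decrease_accuracy", "gini_importance"])
    trace = pd.DataFrame(model.oob_trace_, columns=["ntree", "oob_error"])
    return model, summary, importance, trace


def sensitivity_grid(
    table: pd.DataFrame,
    mtry_range: range = range(2, 20),
    sampsize_range: range = range(2, 19),
    ntree: int = 500,
    seed: int | None = None,
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS,
    label_column: str = "species",
) -> pd.DataFrame:
    """OOB overall accuracy (%) for every (mtry, sampsize) combination.

    Rows are mtry values, columns sampsize values.
    """
    X = table[list(feature_columns)].to_numpy(dtype=float)
    y = table[label_column].to_numpy()
    rng = np.random.default_rng(seed)
    grid = np.empty((len(mtry_range), len(sampsize_range)))
    for i, mtry in enumerate(mtry_range):
        for j, sampsize in enumerate(sampsize_range):
            cfg = ForestConfig(mtry=mtry, sampsize=sampsize, ntree=ntree,
                               seed=int(rng.integers(0, 2**31 - 1)))
            model = BalancedRandomForest(cfg).fit(X, y)
            counts = model.oob_confusion()
            grid[i, j] = 100.0 * np.trace(counts) / counts.sum()
    return pd.DataFrame(grid, index=list(mtry_range), columns=list(sampsize_range))


def proximity_mds(model: BalancedRandomForest, X: np.ndarray | None = None, n_dims: int = 2):
    """Classical MDS of ``1 - proximity``.

    Returns ``(coordinates, explained_variation_pct)`` where the
    percentages are the positive-eigenvalue shares for each dimension.
    """
    prox = model.proximity(X)
    d = 1.0 - prox
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-12
    total = vals[pos].sum()
    coords = vecs[:, :n_dims] * np.sqrt(np.maximum(vals[:n_dims], 0.0))
    explained = 100.0 * np.maximum(vals[:n_dims], 0.0) / total if total > 0 else np.zeros(n_dims)
    return coords, explained
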