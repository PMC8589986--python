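"""Two-stage event classification.

Stage 1 ("call" stage) fits one balanced random forest per detector code
on click-level parameters; its out-of-bag assignment probabilities and
the per-event detector proportions, plus the event ICI mode, become the
predictors for the stage-2 ("event") forest.  Also implements the
encounter-pair similarity validation.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import ici_mode
from .features import FEATURE_COLUMNS
from .forest import BalancedRandomForest, ConfusionSummary, ForestConfig, classification_summary

__all__ = [
    "BanterConfig",
    "StageOneModel",
    "BanterModel",
    "fit_call_stage",
    "fit_event_stage",
    "fit_banter",
    "predict_events",
    "encounter_similarity",
]

#: Probability filled in for detectors with no clicks in an event.
NEUTRAL_PROBABILITY = 0.5


@dataclass(frozen=True)
class BanterConfig:
    stage1_sampsize: int = 50
    stage1_ntree: int = 20_000
    stage2_sampsize: int = 9
    stage2_ntree: int = 20_000
    mtry: int | None = None  # None -> floor(sqrt(n_features)) per stage
    #: when set, detectors below ``stage1_sampsize`` are kept with a
    #: reduced per-detector draw (half the smallest class, at least this
    #: floor) instead of being dropped; used by the small encounter-pair
    #: training models
    stage1_min_sampsize: int | None = None
    seed: int | None = None


@dataclass
class StageOneModel:
    detector_code: int
    forest: BalancedRandomForest
    summary: ConfusionSummary
    n_clicks: dict[str, int] = field(default_factory=dict)


@dataclass
class BanterModel:
    stage1: dict[int, StageOneModel]
    stage2: BalancedRandomForest
    stage2_summary: ConfusionSummary
    stage2_features: pd.DataFrame
    feature_columns: list[str]
    classes: list[str]

    @property
    def retained_detectors(self) -> list[int]:
        return sorted(self.stage1)


def _click_matrix(click_table: pd.DataFrame) -> np.ndarray:
    X = click_table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    # first clicks of a train have no backward ICI; trees need finite input
    ici_col = list(FEATURE_COLUMNS).index("ici")
    X[np.isnan(X[:, ici_col]), ici_col] = 0.0
    return np.nan_to_num(X, nan=0.0)


def _stage2_feature_columns(detectors: list[int], classes: list[str]) -> list[str]:
    cols: list[str] = []
    for d in detectors:
        for sp in classes:
            cols.append(f"det{d}_p_{sp}")
        cols.append(f"det{d}_prop")
    cols.append("ici")
    return cols


def _assemble_event_features(
    click_table: pd.DataFrame,
    detectors: list[int],
    classes: list[str],
    click_probs: np.ndarray,
) -> pd.DataFrame:
    """Event rows of stage-2 predictors from per-click class probabilities.

    ``click_probs`` is aligned with ``click_table`` rows and has one
    column per class.  Detector proportions are over clicks that fall in
    retained detectors; absent detectors get proportion 0 and the
    neutral probability.
    """
    cols = _stage2_feature_columns(detectors, classes)
    rows = []
    for event_id, grp in click_table.groupby("event_id", sort=True):
        idx = grp.index.to_numpy()
        det = grp["detector_code"].to_numpy()
        retained_mask = np.isin(det, detectors)
        n_retained = int(retained_mask.sum())
        row: dict[str, float] = {}
        for d in detectors:
            m = det == d
            if m.any():
                probs = click_probs[idx[m]]
                for ci, sp in enumerate(classes):
                    row[f"det{d}_p_{sp}"] = float(probs[:, ci].mean())
                row[f"det{d}_prop"] = float(m.sum()) / n_retained if n_retained else 0.0
            else:
                for sp in classes:
                    row[f"det{d}_p_{sp}"] = NEUTRAL_PROBABILITY
                row[f"det{d}_prop"] = 0.0
        row["ici"] = ici_mode(grp["time_s"].to_numpy())
        row["event_id"] = event_id
        row["n_retained_clicks"] = n_retained
        rows.append(row)
    out = pd.DataFrame(rows, columns=cols + ["event_id", "n_retained_clicks"])
    out["ici"] = out["ici"].fillna(0.0)
    return out


def fit_call_stage(
    click_table: pd.DataFrame, config: BanterConfig = BanterConfig()
) -> tuple[dict[int, StageOneModel], pd.DataFrame]:
    """Fit per-detector click classifiers and build stage-2 event features.

    Detectors with fewer than ``stage1_sampsize`` clicks in either
    species are dropped.  Requires at least two retained detectors.
    """
    click_table = click_table.reset_index(drop=True)
    classes = sorted(click_table["species"].unique())
    rng = np.random.default_rng(config.seed)
    stage1: dict[int, StageOneModel] = {}
    click_probs = np.full((len(click_table), len(classes)), NEUTRAL_PROBABILITY)
    for code in sorted(click_table["detector_code"].unique()):
        if code == 0:
            continue  # unclassified clicks feed no call classifier
        sub = click_table[click_table["detector_code"] == code]
        counts = sub["species"].value_counts()
        if len(counts) < len(classes):
            continue
        if counts.min() >= config.stage1_sampsize:
            sampsize = config.stage1_sampsize
        elif config.stage1_min_sampsize is not None and counts.min() >= config.stage1_min_sampsize:
            # keep OOB coverage: draw half the smallest class per tree
            sampsize = max(config.stage1_min_sampsize, int(counts.min()) // 2)
        else:
            continue
        X = _click_matrix(sub)
        y = sub["species"].to_numpy()
        cfg = ForestConfig(
            mtry=config.mtry,
            sampsize=sampsize,
            ntree=config.stage1_ntree,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        forest = BalancedRandomForest(cfg).fit(X, y)
        click_probs[sub.index.to_numpy()] = forest.oob_vote_fractions()
        stage1[int(code)] = StageOneModel(
            detector_code=int(code),
            forest=forest,
            summary=forest.oob_summary(),
            n_clicks={sp: int(counts.get(sp, 0)) for sp in classes},
        )
    if len(stage1) < 2:
        raise ValueError(f"need >= 2 retained detectors, got {sorted(stage1)}")
    detectors = sorted(stage1)
    features = _assemble_event_features(click_table, detectors, classes, click_probs)
    return stage1, features


def fit_event_stage(
    event_features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    config: BanterConfig = BanterConfig(),
    feature_columns: list[str] | None = None,
):
    """Fit the stage-2 event forest on stage-1 derived predictors.

    Returns ``(forest, ConfusionSummary, importance DataFrame)``.
    """
    if feature_columns is None:
        feature_columns = [c for c in event_features.columns if c not in ("event_id", "n_retained_clicks")]
    X = event_features[feature_columns].to_numpy(dtype=float)
    y = np.asarray(labels)
    cfg = ForestConfig(
        mtry=config.mtry,
        sampsize=config.stage2_sampsize,
        ntree=config.stage2_ntree,
        seed=config.seed,
    )
    forest = BalancedRandomForest(cfg).fit(X, y)
    imp = forest.permutation_importance(max_trees=500)
    importance = (
        pd.DataFrame({"feature": feature_columns, "mean_decrease_accuracy": imp})
        .sort_values("mean_decrease_accuracy", ascending=False)
        .reset_index(drop=True)
    )
    return forest, forest.oob_summary(), importance


def fit_banter(click_table: pd.DataFrame, config: BanterConfig = BanterConfig()) -> BanterModel:
    """Fit both stages from a labelled click-level table.

    The table needs the 20 feature columns plus ``time_s``, ``event_id``,
    ``species`` and ``detector_code``.
    """
    stage1, features = fit_call_stage(click_table, config)
    labels = (
        click_table.groupby("event_id", sort=True)["species"].first().reindex(features["event_id"]).to_numpy()
    )
    cols = _stage2_feature_columns(sorted(stage1), sorted(click_table["species"].unique()))
    stage2, summary, _ = fit_event_stage(features, labels, config, feature_columns=cols)
    return BanterModel(
        stage1=stage1,
        stage2=stage2,
        stage2_summary=summary,
        stage2_features=features,
        feature_columns=cols,
        classes=sorted(click_table["species"].unique()),
    )


def predict_events(model: BanterModel, click_table: pd.DataFrame) -> pd.DataFrame:
    """Predict species for new events from their clicks.

    Events with no clicks in any retained detector are flagged
    ``classifiable=False`` rather than silently dropped.
    """
    click_table = click_table.reset_index(drop=True)
    probs = np.full((len(click_table), len(model.classes)), NEUTRAL_PROBABILITY)
    for code, s1 in model.stage1.items():
        mask = (click_table["detector_code"] == code).to_numpy()
        if mask.any():
            X = _click_matrix(click_table[mask])
            probs[np.flatnonzero(mask)] = s1.forest.predict_votes(X)
    features = _assemble_event_features(click_table, model.retained_detectors, model.classes, probs)
    X2 = features[model.feature_columns].to_numpy(dtype=float)
    votes = model.stage2.predict_votes(X2)
    out = features[["event_id", "n_retained_clicks"]].copy()
    out["classifiable"] = features["n_retained_clicks"] > 0
    for ci, sp in enumerate(model.classes):
        out[f"vote_{sp}"] = votes[:, ci]
    pred = np.array(model.classes)[votes.argmax(axis=1)].astype(object)
    pred[~out["classifiable"].to_numpy()] = None
    out["predicted"] = pred
    return out


def _rates_vector(counts: np.ndarray, how: str) -> np.ndarray:
    row_sums = counts.sum(axis=1, keepdims=True)
    norm = np.divide(counts, row_sums, out=np.zeros_like(counts, dtype=float), where=row_sums > 0)
    if how == "cells":
        return norm.ravel()
    return np.diag(norm)  # per-class correct rates


def _confusion(labels: np.ndarray, preds: np.ndarray, classes: list[str]) -> np.ndarray:
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    lut = {c: i for i, c in enumerate(classes)}
    for a, p in zip(labels, preds):
        if p is not None:
            counts[lut[a], lut[p]] += 1
    return counts


def encounter_similarity(
    click_table: pd.DataFrame,
    config: BanterConfig | None = None,
    pair_ntree: int = 10_000,
    statistic: str = "pearson-cells",
    min_stage1_sampsize: int = 5,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Cross-encounter validation of the two-stage classifier.

    For every (species-A encounter, species-B encounter) pair, a model is
    trained on that pair's events (stage-2 sampsize = half the smallest
    class) and used to predict all held-out events.  The similarity
    statistic correlates the training (OOB) and validation confusion
    matrices; ``statistic`` is ``'pearson-cells'`` (default, Pearson over
    row-normalised cells), ``'spearman-cells'`` or ``'pearson-rates'``.
    """
    config = config if config is not None else BanterConfig()
    classes = sorted(click_table["species"].unique())
    if len(classes) != 2:
        raise ValueError("encounter similarity expects exactly two species")
    enc_by_sp = {sp: sorted(click_table.loc[click_table["species"] == sp, "encounter"].unique()) for sp in classes}
    rng = np.random.default_rng(config.seed)
    rows = []
    for enc_a, enc_b in itertools.product(enc_by_sp[classes[0]], enc_by_sp[classes[1]]):
        train = click_table[click_table["encounter"].isin([enc_a, enc_b])]
        test = click_table[~click_table["encounter"].isin([enc_a, enc_b])]
        ev_counts = train.groupby("species")["event_id"].nunique()
        if ev_counts.min() < 2 or test.empty:
            rows.append({"encounter_a": enc_a, "encounter_b": enc_b, "correlation": float("nan"), "similar": False, "note": "insufficient events"})
            continue
        pair_cfg = replace(
            config,
            stage1_min_sampsize=min_stage1_sampsize,
            stage1_ntree=pair_ntree,
            stage2_ntree=pair_ntree,
            stage2_sampsize=max(1, int(ev_counts.min()) // 2),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            model = fit_banter(train, pair_cfg)
        except ValueError as exc:
            rows.append({"encounter_a": enc_a, "encounter_b": enc_b, "correlation": float("nan"), "similar": False, "note": str(exc)})
            continue
        preds = predict_events(model, test)
        truth = test.groupby("event_id", sort=True)["species"].first().reindex(preds["event_id"]).to_numpy()
        val_counts = _confusion(truth, preds["predicted"].to_numpy(), classes)
        how = "rates" if statistic.endswith("rates") else "cells"
        v_train = _rates_vector(model.stage2_summary.counts, how)
        v_val = _rates_vector(val_counts, how)
        if statistic.startswith("spearman"):
            from scipy.stats import spearmanr

            corr = float(spearmanr(v_train, v_val).statistic)
        else:
            with np.errstate(invalid="ignore"):
                corr = float(np.corrcoef(v_train, v_val)[0, 1])
        rows.append(
            {
                "encounter_a": enc_a,
                "encounter_b": enc_b,
                "correlation": corr,
                "similar": bool(corr > threshold),
                "note": "",
            }
        )
    return pd.DataFrame(rows)
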