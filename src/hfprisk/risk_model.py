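"""Random-forest modelling of risk transitions from footprint and covariates.

The feature table carries the two footprint predictors (extent of range
above the chosen threshold in the later epoch, and its change between
epochs) alongside pressure, life-history and environmental covariates.
Species range size is deliberately not a predictor, to avoid circularity
with how risk categories are assigned.

Performance is estimated by stratified k-fold cross-validation; variable
importance is reported both as permutation importance (decrease in
accuracy) and as impurity-based (Gini) importance averaged over trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

from .risk_transitions import HIGH_RISK, LOW_RISK, NOT_UPLISTED, UPLISTED

CONTINUOUS_PREDICTORS = (
    "high_hfp_extent",
    "high_hfp_change",
    "popdensity",
    "pop_growth",
    "travel_time",
    "gestation_length",
    "weaning_age",
    "body_mass",
    "ndvi",
    "tree_cover",
    "habitat_prevalence",
)
CATEGORICAL_PREDICTORS = ("taxon_order", "diet", "habitat_class")
PREDICTORS = (
    "high_hfp_extent",
    "high_hfp_change",
    "popdensity",
    "pop_growth",
    "travel_time",
    "taxon_order",
    "gestation_length",
    "weaning_age",
    "body_mass",
    "diet",
    "habitat_class",
    "ndvi",
    "tree_cover",
    "habitat_prevalence",
)

__all__ = [
    "FeatureTable",
    "ModelSettings",
    "ModelReport",
    "assemble_features",
    "encode_feature_frame",
    "fit_evaluate",
    "threshold_selection",
    "PREDICTORS",
]


@dataclass(frozen=True)
class ModelSettings:
    """Random-forest and cross-validation settings (all seeded)."""

    n_trees: int = 500
    max_features: str = "sqrt"
    n_folds: int = 10
    seed: int = 0
    n_permutations: int = 10  # permutation-importance repeats; 0 skips it


@dataclass
class FeatureTable:
    """One row per species: the 14 predictors plus a binary label."""

    frame: pd.DataFrame
    threshold: int
    positive_class: str = HIGH_RISK
    negative_class: str = LOW_RISK
    level_maps: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in PREDICTORS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature table missing predictors: {missing}")
        if "label" not in self.frame.columns:
            raise ValueError("feature table missing 'label' column")
        if self.frame["label"].isna().any():
            raise ValueError("feature table has missing labels")


@dataclass
class ModelReport:
    threshold: int
    accuracy: float
    sensitivity: float
    specificity: float
    tss: float
    confusion: dict[str, int]
    importance_accuracy: dict[str, float]
    importance_gini: dict[str, float]
    settings: ModelSettings
    level_maps: dict[str, dict[str, int]]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tss": self.tss,
            "confusion": self.confusion,
            "importance_accuracy": self.importance_accuracy,
            "importance_gini": self.importance_gini,
            "settings": {
                "n_trees": self.settings.n_trees,
                "max_features": self.settings.max_features,
                "n_folds": self.settings.n_folds,
                "seed": self.settings.seed,
            },
            "level_maps": self.level_maps,
        }


def true_skill_statistic(sensitivity: float, specificity: float) -> float:
    """TSS = sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def encode_feature_frame(frame: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Integer-encode categoricals and median-impute continuous predictors.

    Returns the encoded frame and the categorical level maps. Imputed
    columns get a companion ``<name>_imputed`` flag.
    """
    frame = frame.copy()
    level_maps: dict[str, dict[str, int]] = {}
    for col in CATEGORICAL_PREDICTORS:
        levels = sorted(frame[col].astype(str).unique())
        level_maps[col] = {lev: i for i, lev in enumerate(levels)}
        frame[col] = frame[col].astype(str).map(level_maps[col])
    for col in CONTINUOUS_PREDICTORS:
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            frame[f"{col}_imputed"] = vals.isna().astype(int)
            vals = vals.fillna(vals.median())
        frame[col] = vals
    return frame, level_maps


def assemble_features(
    overlaps: pd.DataFrame,
    covariates: pd.DataFrame,
    labels: pd.DataFrame,
    t: int,
    label_column: str = "risk_class",
) -> FeatureTable:
    """Join extents at threshold ``t``, covariates and labels into one table.

    Categorical covariates are integer-encoded with the level maps recorded
    for the report; missing continuous covariates are median-imputed with a
    companion ``<name>_imputed`` flag column.
    """
    if not (0 <= t <= 49):
        raise ValueError(f"threshold {t} outside [0, 49]")
    ext = overlaps[overlaps["t"] == t]
    if ext.empty:
        raise ValueError(f"no overlap rows at threshold {t}")
    if ext["species_id"].duplicated().any():
        dups = ext.loc[ext["species_id"].duplicated(), "species_id"].tolist()
        raise ValueError(f"duplicate species in overlaps: {dups}")
    if covariates["species_id"].duplicated().any():
        dups = covariates.loc[
            covariates["species_id"].duplicated(), "species_id"
        ].tolist()
        raise ValueError(f"duplicate species in covariates: {dups}")
    base = ext[["species_id", "extent09", "delta"]].rename(
        columns={"extent09": "high_hfp_extent", "delta": "high_hfp_change"}
    )
    lacking = sorted(set(base["species_id"]) - set(covariates["species_id"]))
    if lacking:
        raise ValueError(f"covariate table lacks species: {lacking}")
    frame = base.merge(covariates, on="species_id", how="left")
    frame = frame.merge(
        labels[["species_id", label_column]].rename(columns={label_column: "label"}),
        on="species_id",
        how="left",
    )
    if frame["label"].isna().any():
        missing = frame.loc[frame["label"].isna(), "species_id"].tolist()
        raise ValueError(f"label missing for species: {missing}")

    frame, level_maps = encode_feature_frame(frame)
    if label_column == "uplist_class":
        pos, neg = UPLISTED, NOT_UPLISTED
    else:
        pos, neg = HIGH_RISK, LOW_RISK
    return FeatureTable(
        frame=frame,
        threshold=int(t),
        positive_class=pos,
        negative_class=neg,
        level_maps=level_maps,
    )


def fit_evaluate(features: FeatureTable, settings: ModelSettings) -> ModelReport:
    """Cross-validated performance and importances; deterministic per seed."""
    frame = features.frame
    classes = set(frame["label"])
    expected = {features.positive_class, features.negative_class}
    if classes != expected:
        if len(classes) < 2:
            raise ValueError(f"need both classes, got {sorted(classes)}")
        raise ValueError(f"unexpected labels {sorted(classes - expected)}")
    y = (frame["label"] == features.positive_class).to_numpy(dtype=int)
    feature_cols = [c for c in frame.columns if c not in ("species_id", "label")]
    X = frame[feature_cols].to_numpy(dtype=float)
    if min((y == 1).sum(), (y == 0).sum()) < settings.n_folds:
        raise ValueError("fewer species in a class than cross-validation folds")

    pos_share = y.mean()
    if min(pos_share, 1 - pos_share) < 0.1:
        warnings.warn(
            "severe class imbalance: the minority class holds "
            f"{100 * min(pos_share, 1 - pos_share):.1f}% of species; "
            "expect biased classification toward the majority class",
            stacklevel=2,
        )

    skf = StratifiedKFold(
        n_splits=settings.n_folds, shuffle=True, random_state=settings.seed
    )
    y_pred = np.empty_like(y)
    perm_scores = np.zeros(len(feature_cols))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        rf = RandomForestClassifier(
            n_estimators=settings.n_trees,
            max_features=settings.max_features,
            random_state=settings.seed,
        )
        rf.fit(X[tr], y[tr])
        y_pred[te] = rf.predict(X[te])
        if settings.n_permutations > 0:
            perm = permutation_importance(
                rf,
                X[te],
                y[te],
                n_repeats=settings.n_permutations,
                random_state=settings.seed + fold,
                scoring="accuracy",
            )
            perm_scores += perm.importances_mean
    if settings.n_permutations > 0:
        perm_scores /= settings.n_folds
    else:
        perm_scores[:] = np.nan

    tp = int(((y == 1) & (y_pred == 1)).sum())
    tn = int(((y == 0) & (y_pred == 0)).sum())
    fp = int(((y == 0) & (y_pred == 1)).sum())
    fn = int(((y == 1) & (y_pred == 0)).sum())
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    accuracy = (tp + tn) / len(y)

    rf_full = RandomForestClassifier(
        n_estimators=settings.n_trees,
        max_features=settings.max_features,
        random_state=settings.seed,
    )
    rf_full.fit(X, y)
    gini = rf_full.feature_importances_

    return ModelReport(
        threshold=features.threshold,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        tss=true_skill_statistic(sensitivity, specificity),
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        importance_accuracy=dict(zip(feature_cols, perm_scores.tolist())),
        importance_gini=dict(zip(feature_cols, gini.tolist())),
        settings=settings,
        level_maps=features.level_maps,
    )


def threshold_selection(
    overlaps: pd.DataFrame,
    covariates: pd.DataFrame,
    labels: pd.DataFrame,
    t_grid,
    settings: ModelSettings,
    label_column: str = "risk_class",
) -> tuple[int, pd.DataFrame, dict[int, ModelReport]]:
    """Fit the model at every threshold in ``t_grid``; pick the TSS maximum.

    Returns the best threshold (ties break toward the lowest t), a per-t
    performance table and the full per-t reports.
    """
    t_grid = sorted(int(t) for t in t_grid)
    if len(t_grid) < 2:
        raise ValueError("need at least two thresholds to select among")
    reports: dict[int, ModelReport] = {}
    rows = []
    for t in t_grid:
        feats = assemble_features(overlaps, covariates, labels, t, label_column)
        rep = fit_evaluate(feats, settings)
        reports[t] = rep
        rows.append(
            {
                "t": t,
                "accuracy": rep.accuracy,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "tss": rep.tss,
                "perm_importance_extent": rep.importance_accuracy["high_hfp_extent"],
                "perm_importance_change": rep.importance_accuracy["high_hfp_change"],
                "gini_importance_extent": rep.importance_gini["high_hfp_extent"],
                "gini_importance_change": rep.importance_gini["high_hfp_change"],
            }
        )
    curve = pd.DataFrame(rows)
    best_idx = curve["tss"].to_numpy().argmax()  # argmax takes first maximum
    best_t = int(curve.loc[best_idx, "t"])
    return best_t, curve, reports
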