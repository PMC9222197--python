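"""Marker-trained SVM compartment assignment with per-class FDR thresholds.

The classifier is a multi-class RBF-kernel support vector machine trained on
curated marker proteins, with the kernel parameterized as
``k(x, y) = exp(-sigma * ||x - y||^2)`` so that ``sigma`` is the inverse
kernel width.  Hyperparameters are tuned by repeated stratified
cross-validation scored with macro-F1; class-probability scores are then
thresholded per class so that the empirical fraction of wrong assignments
among accepted out-of-fold marker predictions stays below the requested FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from .exceptions import ConfigError
from .spatial_data import UNKNOWN_LABEL, MarkerMap, SpatialProfileMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SVMConfig:
    """Grid, cross-validation and FDR settings for the classifier."""

    sigma_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    cost_grid: tuple[float, ...] = (4.0, 16.0, 64.0)
    cv_rounds: int = 100
    folds: int = 5
    fdr: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if not (0.0 < self.fdr < 1.0):
            raise ConfigError("fdr must lie in (0, 1)")
        if any(s <= 0 for s in self.sigma_grid) or any(c <= 0 for c in self.cost_grid):
            raise ConfigError("sigma and cost grids must be positive")
        if self.cv_rounds < 1:
            raise ConfigError("cv_rounds must be >= 1")


@dataclass
class ClassificationResult:
    """Per-protein predictions plus the thresholds and tuning record behind them.

    ``assignments`` columns: protein_id, predicted_class, score, final_label,
    is_marker, true_class (markers only, else NA).
    """

    assignments: pd.DataFrame
    thresholds: dict[str, float]
    sigma: float
    cost: float
    tuning_record: pd.DataFrame = field(default_factory=pd.DataFrame)

    def label_of(self) -> dict[str, str]:
        return dict(zip(self.assignments["protein_id"], self.assignments["final_label"]))


def macro_f1(confusion: np.ndarray | pd.DataFrame) -> float:
    """Unweighted mean per-class F1 from a (true x predicted) count table.

    A class whose precision + recall is zero contributes 0 to the mean.
    """
    table = np.asarray(confusion, dtype=float)
    if table.size == 0 or table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("confusion table must be a non-empty square matrix")
    diag = np.diag(table)
    pred_totals = table.sum(axis=0)
    true_totals = table.sum(axis=1)
    f1s = np.zeros(table.shape[0])
    denom = pred_totals + true_totals  # 2PR/(P+R) == 2*diag / (pred+true)
    ok = denom > 0
    f1s[ok] = 2.0 * diag[ok] / denom[ok]
    return float(f1s.mean())


def _marker_design(
    profiles: SpatialProfileMatrix, markers: MarkerMap
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    present = [p for p in profiles.protein_ids if p in markers.entries]
    missing = len(markers) - len(present)
    if missing:
        logger.info("%d marker(s) absent from the profile matrix; ignored", missing)
    if not present:
        raise ConfigError("no marker overlaps the profile matrix")
    idx = {p: i for i, p in enumerate(profiles.protein_ids)}
    X = profiles.matrix[[idx[p] for p in present]]
    y = np.array([markers.entries[p] for p in present])
    return X, y, present


def _check_class_sizes(y: np.ndarray, folds: int) -> np.ndarray:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ConfigError("need markers from at least 2 classes")
    small = classes[counts < folds]
    if small.size:
        raise ConfigError(
            f"class {small[0]!r} has fewer markers ({int(counts[classes == small[0]][0])}) "
            f"than folds ({folds})"
        )
    return classes


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    pos = {c: i for i, c in enumerate(classes)}
    table = np.zeros((len(classes), len(classes)))
    for t, p in zip(y_true, y_pred):
        table[pos[t], pos[p]] += 1
    return table


def tune_hyperparameters(
    profiles: SpatialProfileMatrix,
    markers: MarkerMap,
    config: SVMConfig = SVMConfig(),
) -> tuple[float, float, pd.DataFrame]:
    """Grid-search (sigma, cost) by repeated stratified CV on markers only.

    Each grid point's score is the mean macro-F1 over ``cv_rounds`` rounds of
    ``folds``-fold stratified cross-validation; partitions are resampled each
    round from a round-indexed seed stream.  Ties are broken toward the
    smallest cost, then the smallest sigma.

    Returns ``(sigma, cost, record)`` where ``record`` has one row per grid
    point with its mean and std macro-F1.
    """
    X, y, _ = _marker_design(profiles, markers)
    classes = _check_class_sizes(y, config.folds)

    grid = [(s, c) for s in config.sigma_grid for c in config.cost_grid]
    scores: dict[tuple[float, float], list[float]] = {g: [] for g in grid}
    for rnd in range(config.cv_rounds):
        splitter = StratifiedKFold(
            n_splits=config.folds, shuffle=True, random_state=config.seed + 1000 * rnd
        )
        for train, test in splitter.split(X, y):
            for sigma, cost in grid:
                model = SVC(kernel="rbf", gamma=sigma, C=cost)
                model.fit(X[train], y[train])
                pred = model.predict(X[test])
                scores[(sigma, cost)].append(macro_f1(_confusion(y[test], pred, classes)))

    record = pd.DataFrame(
        [
            {
                "sigma": s,
                "cost": c,
                "mean_macro_f1": float(np.mean(scores[(s, c)])),
                "std_macro_f1": float(np.std(scores[(s, c)])),
            }
            for s, c in grid
        ]
    )
    best = record.sort_values(
        ["mean_macro_f1", "cost", "sigma"], ascending=[False, True, True]
    ).iloc[0]
    logger.info(
        "tuned sigma=%g cost=%g (mean macro-F1 %.3f)",
        best["sigma"], best["cost"], best["mean_macro_f1"],
    )
    return float(best["sigma"]), float(best["cost"]), record


def train_and_score(
    profiles: SpatialProfileMatrix,
    markers: MarkerMap,
    sigma: float,
    cost: float,
    seed: int = 0,
    folds: int = 5,
) -> pd.DataFrame:
    """Score every protein with a marker-trained probabilistic SVM.

    Markers are scored out-of-fold (stratified CV predictions) so their scores
    are honest for threshold derivation; non-markers are scored by the model
    trained on all markers.  ``score`` is the top pairwise-coupled class
    probability.

    Returns a frame with columns protein_id, predicted_class, score,
    is_marker, true_class.
    """
    X, y, marker_ids = _marker_design(profiles, markers)
    _check_class_sizes(y, folds)

    def make_model() -> SVC:
        return SVC(kernel="rbf", gamma=sigma, C=cost, probability=True, random_state=seed)

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        # SVC(probability=True) deprecation churn in scikit-learn >= 1.9
        warnings.simplefilter("ignore", FutureWarning)
        oof_proba = cross_val_predict(make_model(), X, y, cv=splitter, method="predict_proba")
        classes = np.unique(y)  # cross_val_predict orders columns by sorted class labels

        full = make_model()
        full.fit(X, y)
    marker_set = set(marker_ids)
    other_ids = [p for p in profiles.protein_ids if p not in marker_set]
    rows = []
    if other_ids:
        idx = {p: i for i, p in enumerate(profiles.protein_ids)}
        proba = full.predict_proba(profiles.matrix[[idx[p] for p in other_ids]])
        for pid, pr in zip(other_ids, proba):
            j = int(np.argmax(pr))
            rows.append((pid, full.classes_[j], float(pr[j]), False, pd.NA))
    for pid, true_cls, pr in zip(marker_ids, y, oof_proba):
        j = int(np.argmax(pr))
        rows.append((pid, classes[j], float(pr[j]), True, true_cls))

    frame = pd.DataFrame(
        rows, columns=["protein_id", "predicted_class", "score", "is_marker", "true_class"]
    )
    return frame.sort_values("protein_id", ignore_index=True)


def derive_fdr_thresholds(
    marker_oof: pd.DataFrame,
    fdr: float = 0.05,
    classes: tuple[str, ...] | None = None,
) -> dict[str, float]:
    """Per-class score cutoffs bounding the empirical false-discovery proportion.

    For each class ``c``, among out-of-fold marker predictions assigned to
    ``c``, the threshold is the lowest score ``s`` such that the fraction of
    wrong-class markers with score >= ``s`` is at most ``fdr``; if no score
    qualifies the threshold is ``+inf`` and the class is never assigned.
    """
    oof = marker_oof[marker_oof["is_marker"]] if "is_marker" in marker_oof else marker_oof
    if classes is None:
        classes = tuple(sorted(set(oof["true_class"].dropna())))
    thresholds: dict[str, float] = {}
    for cls in classes:
        sub = oof[oof["predicted_class"] == cls]
        if sub.empty:
            logger.warning("class %r: no out-of-fold marker predicted; threshold set to +inf", cls)
            thresholds[cls] = np.inf
            continue
        scores = sub["score"].to_numpy(dtype=float)
        wrong = (sub["true_class"] != cls).to_numpy()
        chosen = np.inf
        for s in np.unique(scores):  # ascending: first admissible s is the lowest
            accepted = scores >= s
            if wrong[accepted].mean() <= fdr:
                chosen = float(s)
                break
        if not np.isfinite(chosen):
            logger.warning("class %r: FDR %.2f unattainable; threshold set to +inf", cls, fdr)
        thresholds[cls] = chosen
    return thresholds


def classify(
    scored: pd.DataFrame,
    thresholds: dict[str, float],
    sigma: float = np.nan,
    cost: float = np.nan,
    tuning_record: pd.DataFrame | None = None,
) -> ClassificationResult:
    """Apply per-class thresholds: below-threshold proteins become "unknown"."""
    frame = scored.copy()
    cutoff = frame["predicted_class"].map(lambda c: thresholds.get(c, np.inf))
    frame["final_label"] = np.where(
        frame["score"] >= cutoff, frame["predicted_class"], UNKNOWN_LABEL
    )
    counts = frame["final_label"].value_counts().to_dict()
    logger.info("assignment counts: %s", dict(sorted(counts.items())))
    return ClassificationResult(
        assignments=frame,
        thresholds=dict(thresholds),
        sigma=sigma,
        cost=cost,
        tuning_record=tuning_record if tuning_record is not None else pd.DataFrame(),
    )


def classify_profiles(
    profiles: SpatialProfileMatrix,
    markers: MarkerMap,
    config: SVMConfig = SVMConfig(),
) -> ClassificationResult:
    """Convenience chain: tune -> train/score -> derive thresholds -> classify."""
    sigma, cost, record = tune_hyperparameters(profiles, markers, config)
    scored = train_and_score(profiles, markers, sigma, cost, seed=config.seed, folds=config.folds)
    oof = scored[scored["is_marker"]]
    thresholds = derive_fdr_thresholds(oof, config.fdr)
    return classify(scored, thresholds, sigma=sigma, cost=cost, tuning_record=record)
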