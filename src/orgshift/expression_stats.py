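"""Whole-lysate expression arm: QC filtering, normalization, PCA, testing.

Pipeline order is fixed: CV% filter on QC pool columns, median-log-ratio
normalization against a geometric-mean reference sample, Pareto scaling,
then PCA and per-protein Welch t-tests with Bonferroni correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, IntegrityError

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Bookkeeping from the QC coefficient-of-variation filter."""

    kept: list[str]
    removed: list[str]
    cv_percent: pd.Series
    threshold: float
    skipped: bool = False


def qc_cv_filter(
    table: pd.DataFrame,
    qc_columns: list[str],
    threshold: float = 25.0,
) -> tuple[pd.DataFrame, FilterReport]:
    """Retain proteins whose QC-sample CV%% is strictly below ``threshold``.

    CV%% = 100 * sd / mean over the QC columns (sample standard deviation).
    With fewer than two QC columns the filter is skipped with a warning.
    """
    if len(qc_columns) < 2:
        logger.warning("fewer than 2 QC columns; CV filter skipped")
        report = FilterReport(list(table.index), [], pd.Series(dtype=float), threshold, skipped=True)
        return table.copy(), report
    qc = table[qc_columns].astype(float)
    cv = 100.0 * qc.std(axis=1, ddof=1) / qc.mean(axis=1)
    keep = cv < threshold
    report = FilterReport(
        kept=list(table.index[keep]),
        removed=list(table.index[~keep]),
        cv_percent=cv,
        threshold=threshold,
    )
    logger.info("CV filter: kept %d / removed %d", len(report.kept), len(report.removed))
    return table.loc[keep].copy(), report


def mlr_normalize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-log-ratio normalization against a geometric-mean reference.

    Every sample is divided by the exponentiated median of its log-ratios to
    the across-sample geometric-mean pseudo-sample, so that after scaling the
    median log-ratio of each sample to the reference is zero.  Robust to a
    minority of differentially abundant proteins.

    Returns the normalized table and the per-sample scale factors applied
    (column was divided by its factor).
    """
    values = table.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or (values <= 0).any():
        raise IntegrityError("normalization needs strictly positive, finite abundances")
    log_values = np.log(values)
    reference = log_values.mean(axis=1)  # log of geometric-mean sample
    factors = np.exp(np.median(log_values - reference[:, None], axis=0))
    # dividing by these factors makes each sample's median log-ratio to the
    # input-derived reference exactly zero
    normalized = pd.DataFrame(values / factors[None, :], index=table.index, columns=table.columns)
    return normalized, pd.Series(factors, index=table.columns, name="scale_factor")


def pareto_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Feature-wise Pareto scaling: center, then divide by sqrt(sd).

    Constant features map to all-zero rows with a warning.  Intentionally
    non-idempotent (re-scaling changes values again).
    """
    values = matrix.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ConfigError("Pareto scaling needs at least 2 samples")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.warning("%d constant feature(s) mapped to zeros", int(constant.sum()))
    scale = np.where(sd > 0, np.sqrt(sd), 1.0)
    return pd.DataFrame((values - mean) / scale, index=matrix.index, columns=matrix.columns)


def pca_scores(matrix: np.ndarray | pd.DataFrame, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of an observations x features matrix via SVD of the centered data.

    Returns ``(scores, loadings, variance_explained_percent)`` with a fixed
    sign convention: each component's largest-magnitude loading is positive.
    ``scores`` is (n, k), ``loadings`` is (features, k).
    """
    X = np.asarray(matrix, dtype=float)
    n, m = X.shape
    if not 1 <= k <= min(n, m):
        raise ConfigError(f"k={k} must lie in [1, min(n, m)={min(n, m)}]")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| coordinate positive
    for j in range(len(s)):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    total_var = (s**2).sum()
    var_explained = 100.0 * (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return scores, loadings, var_explained


def ttest_bonferroni(
    table: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein two-sided Welch t-test with Bonferroni adjustment.

    ``p_adj = min(1, m * p_raw)`` with ``m`` the number of proteins tested;
    ``significant`` flags ``p_adj < alpha``.  Degenerate rows (zero variance
    in both groups, equal means) get p = 1 by convention.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ConfigError("each group needs at least 2 samples")
    a = table[group_a].to_numpy(dtype=float)
    b = table[group_b].to_numpy(dtype=float)
    with warnings.catch_warnings():
        # near-constant rows trigger scipy precision warnings; they are
        # handled below by the degenerate-row convention
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = np.isnan(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    m = len(table)
    p_adj = np.minimum(1.0, m * p)
    return pd.DataFrame(
        {
            "t": t,
            "p_raw": p,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        },
        index=table.index,
    )


def expression_pipeline(
    table: pd.DataFrame,
    groups: dict[str, list[str]],
    cv_threshold: float = 25.0,
    n_components: int = 2,
    test_on_scaled: bool = True,
) -> dict:
    """CV-filter -> MLR-normalize -> Pareto-scale -> PCA + Welch/Bonferroni.

    ``groups`` maps 'control'/'treated'/'qc' to column-name lists; 'qc' may be
    empty (the filter is then skipped).  Set ``test_on_scaled=False`` to run
    the t-test on normalized rather than Pareto-scaled values.
    """
    for key in ("control", "treated"):
        if key not in groups:
            raise ConfigError(f"groups must define {key!r} columns")
    qc_cols = groups.get("qc", [])
    filtered, report = qc_cv_filter(table, qc_cols, cv_threshold)
    normalized, factors = mlr_normalize(filtered)
    scaled = pareto_scale(normalized)

    sample_cols = groups["control"] + groups["treated"] + qc_cols
    scores, loadings, var_exp = pca_scores(scaled[sample_cols].T, n_components)
    test_table = scaled if test_on_scaled else normalized
    tests = ttest_bonferroni(test_table, groups["control"], groups["treated"])
    logger.info(
        "expression pipeline: %d proteins tested, %d significant",
        len(tests), int(tests["significant"].sum()),
    )
    return {
        "filter_report": report,
        "scale_factors": factors,
        "normalized": normalized,
        "scaled": scaled,
        "pca": {"scores": scores, "loadings": loadings, "variance_explained": var_exp,
                "samples": sample_cols},
        "tests": tests,
    }
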