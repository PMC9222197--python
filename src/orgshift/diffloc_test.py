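"""Bayesian non-parametric two-sample test for differential localization.

Each protein's sum-normalized fraction profiles are mapped to unconstrained
coordinates with the additive log-ratio (ALR) transform; the control and
treated replicate sets are then compared by a Gaussian-process two-sample
test.  The null model regresses the pooled observations on the ALR coordinate
index with a single zero-mean GP (squared-exponential covariance plus
Gaussian noise); the alternative fits one independent GP per condition.  The
log Bayes factor is the difference of the models' log marginal likelihoods,
each evaluated at hyperparameters maximizing the Gamma-prior-penalized
marginal likelihood (empirical-Bayes plug-in).  Bayes factors are converted
to posterior probabilities with a small prior on the independent model, and
proteins whose posterior saturates at 1 are called movers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .exceptions import ConfigError, NumericalError
from .spatial_data import SpatialProfileMatrix

logger = logging.getLogger(__name__)

_JITTER_START = 1e-8
_JITTER_MAX = 1e-4


# ---------------------------------------------------------------------------
# compositional transform


def alr_transform(composition: np.ndarray, ref: int | None = None, eps: float = 1e-6) -> np.ndarray:
    """Additive log-ratio transform of an F-part composition.

    ``ref`` is the 1-based index of the reference part (default: last).  The
    composition is floored at ``eps`` and renormalized first, so zeros cannot
    reach the logarithm.  Output coordinate order preserves part order with
    the reference removed.
    """
    p = np.asarray(composition, dtype=float)
    if p.ndim != 1:
        raise ValueError("composition must be a 1-D vector")
    F = p.size
    if ref is None:
        ref = F
    if not 1 <= ref <= F:
        raise ValueError(f"ref={ref} out of range for {F} parts")
    p = np.maximum(p, eps)
    p = p / p.sum()
    keep = np.arange(F) != (ref - 1)
    return np.log(p[keep] / p[ref - 1])


def inverse_alr(coords: np.ndarray, ref: int | None = None) -> np.ndarray:
    """Invert :func:`alr_transform` back to an F-part composition."""
    y = np.asarray(coords, dtype=float)
    F = y.size + 1
    if ref is None:
        ref = F
    if not 1 <= ref <= F:
        raise ValueError(f"ref={ref} out of range for {F} parts")
    parts = np.empty(F)
    keep = np.arange(F) != (ref - 1)
    parts[keep] = np.exp(y)
    parts[ref - 1] = 1.0
    return parts / parts.sum()


# ---------------------------------------------------------------------------
# GP machinery


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) prior on a positive hyperparameter."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ConfigError("Gamma prior needs positive shape and rate")

    def log_pdf(self, x: float) -> float:
        # normalizing constant omitted: MAP location is unaffected
        return (self.shape - 1.0) * np.log(x) - self.rate * x

    def dlog_pdf_dlogx(self, x: float) -> float:
        return (self.shape - 1.0) - self.rate * x

    @property
    def mean(self) -> float:
        return self.shape / self.rate


@dataclass(frozen=True)
class GPPriors:
    """Priors over (amplitude a^2, lengthscale l, noise variance s^2).

    These are stand-in defaults for the under-documented "default" priors of
    the reference implementation; adjust via configuration if needed.
    """

    amplitude: GammaPrior = GammaPrior(2.0, 1.0)
    lengthscale: GammaPrior = GammaPrior(3.0, 1.0)
    noise: GammaPrior = GammaPrior(2.0, 2.0)


@dataclass(frozen=True)
class GPHyperparams:
    """Squared-exponential GP hyperparameters (variances, not std devs)."""

    amplitude: float  # a^2
    lengthscale: float  # l
    noise: float  # sigma^2

    def __post_init__(self) -> None:
        if min(self.amplitude, self.lengthscale, self.noise) <= 0:
            raise ConfigError("GP hyperparameters must be positive")


def se_kernel(x: np.ndarray | float, xp: np.ndarray | float, hyper: GPHyperparams) -> np.ndarray | float:
    """Squared-exponential covariance a^2 * exp(-(x-x')^2 / (2 l^2))."""
    d = np.subtract(x, xp)
    return hyper.amplitude * np.exp(-(d**2) / (2.0 * hyper.lengthscale**2))


def _chol_with_jitter(K: np.ndarray, context: str = "") -> tuple[np.ndarray, float]:
    jitter = 0.0  # noise variance usually suffices; jitter only on failure
    while jitter <= _JITTER_MAX:
        try:
            L = linalg.cholesky(K + jitter * np.eye(K.shape[0]), lower=True)
            return L, jitter
        except linalg.LinAlgError:
            jitter = _JITTER_START if jitter == 0.0 else jitter * 10.0
    raise NumericalError(f"covariance not positive definite after max jitter {context}")


def gp_log_marginal(xs: np.ndarray, ys: np.ndarray, hyper: GPHyperparams) -> float:
    """Log marginal likelihood of ``ys`` under the zero-mean SE GP + noise.

    Repeated ``xs`` (replicate observations at the same coordinate) are
    allowed; the noise term keeps the covariance full rank.
    """
    x = np.asarray(xs, dtype=float).ravel()
    y = np.asarray(ys, dtype=float).ravel()
    if x.size != y.size or x.size == 0:
        raise ValueError("xs and ys must be equal-length, non-empty")
    n = x.size
    K = se_kernel(x[:, None], x[None, :], hyper) + hyper.noise * np.eye(n)
    L, _ = _chol_with_jitter(K)
    alpha = linalg.cho_solve((L, True), y)
    return float(
        -0.5 * y @ alpha - np.log(np.diag(L)).sum() - 0.5 * n * np.log(2.0 * np.pi)
    )


def _neg_map_objective(
    theta: np.ndarray, d2: np.ndarray, y: np.ndarray, priors: GPPriors
) -> tuple[float, np.ndarray]:
    """Negative (log ML + log priors) and its gradient in log-parameters.

    ``d2`` is the precomputed squared-distance matrix of the inputs.
    """
    a2, ell, s2 = np.exp(theta)
    n = y.size
    E = np.exp(-d2 / (2.0 * ell**2))
    K = a2 * E + (s2 + _JITTER_START) * np.eye(n)
    try:
        L = linalg.cholesky(K, lower=True)
    except linalg.LinAlgError:
        return 1e10, np.zeros(3)
    alpha = linalg.cho_solve((L, True), y)
    log_ml = -0.5 * y @ alpha - np.log(np.diag(L)).sum() - 0.5 * n * np.log(2.0 * np.pi)

    value = log_ml
    value += priors.amplitude.log_pdf(a2)
    value += priors.lengthscale.log_pdf(ell)
    value += priors.noise.log_pdf(s2)

    # gradient of log ML: 0.5 * tr((aa^T - K^-1) dK/dtheta)
    Kinv = linalg.cho_solve((L, True), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv
    dK_da2 = a2 * E  # d/d log a2
    dK_dell = a2 * E * (d2 / ell**2)  # d/d log l
    grad = np.array(
        [
            0.5 * np.sum(A * dK_da2) + priors.amplitude.dlog_pdf_dlogx(a2),
            0.5 * np.sum(A * dK_dell) + priors.lengthscale.dlog_pdf_dlogx(ell),
            0.5 * np.trace(A) * s2 + priors.noise.dlog_pdf_dlogx(s2),
        ]
    )
    return -value, -grad


def map_hyperparameters(
    xs: np.ndarray,
    ys: np.ndarray,
    priors: GPPriors = GPPriors(),
    n_restarts: int = 5,
    seed: int = 0,
) -> GPHyperparams:
    """Prior-penalized MAP estimate of the GP hyperparameters.

    L-BFGS-B in log-parameter space with analytic gradients; the first start
    is data-informed (variance split between signal and noise), the rest are
    drawn from the priors using a seeded generator.  The best of all converged
    restarts is returned.
    """
    x = np.asarray(xs, dtype=float).ravel()
    y = np.asarray(ys, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 observations to fit hyperparameters")
    d2 = (x[:, None] - x[None, :]) ** 2

    rng = np.random.default_rng(seed)
    var = max(float(np.var(y)), 1e-4)
    span = max(float(np.ptp(x)), 1.0)
    starts = [np.log([0.5 * var, 0.3 * span, 0.5 * var])]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            np.log(
                [
                    max(rng.gamma(priors.amplitude.shape, 1.0 / priors.amplitude.rate), 1e-3),
                    max(rng.gamma(priors.lengthscale.shape, 1.0 / priors.lengthscale.rate), 1e-3),
                    max(rng.gamma(priors.noise.shape, 1.0 / priors.noise.rate), 1e-3),
                ]
            )
        )

    bounds = [(-12.0, 8.0)] * 3
    best: optimize.OptimizeResult | None = None
    for theta0 in starts:
        res = optimize.minimize(
            _neg_map_objective,
            theta0,
            args=(d2, y, priors),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise NumericalError("all hyperparameter restarts failed")
    a2, ell, s2 = np.exp(best.x)
    return GPHyperparams(amplitude=float(a2), lengthscale=float(ell), noise=float(s2))


# ---------------------------------------------------------------------------
# two-sample test


def _stack_observations(profiles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(R, D) ALR replicate matrix -> flat (x, y) with x = coordinate index 1..D."""
    arr = np.atleast_2d(np.asarray(profiles, dtype=float))
    R, D = arr.shape
    xs = np.tile(np.arange(1, D + 1, dtype=float), R)
    return xs, arr.ravel()


def log_bayes_factor(
    ctrl: np.ndarray,
    trt: np.ndarray,
    priors: GPPriors = GPPriors(),
    n_restarts: int = 5,
    seed: int = 0,
) -> float:
    """Log Bayes factor of independent vs shared GP models for one protein.

    ``ctrl`` and ``trt`` are (R, D) arrays of per-replicate ALR coordinates
    (D = F - 1); replicates enter as repeated observations at the same
    coordinate index.  Positive values support a localization difference.
    """
    ctrl = np.atleast_2d(np.asarray(ctrl, dtype=float))
    trt = np.atleast_2d(np.asarray(trt, dtype=float))
    if ctrl.size == 0 or trt.size == 0:
        raise ValueError("each condition needs at least one replicate profile")

    xc, yc = _stack_observations(ctrl)
    xt, yt = _stack_observations(trt)
    xp, yp = np.concatenate([xc, xt]), np.concatenate([yc, yt])

    parts = []
    for xs, ys in ((xc, yc), (xt, yt), (xp, yp)):
        hyper = map_hyperparameters(xs, ys, priors, n_restarts=n_restarts, seed=seed)
        parts.append(gp_log_marginal(xs, ys, hyper))
    return float(parts[0] + parts[1] - parts[2])


def bf_to_posterior(log_bf: float, prior_independent: float = 0.01) -> float:
    """Posterior probability of the independent (difference) model.

    Computed stably on either side of zero; returns exactly the prior when
    the Bayes factor is 1.
    """
    pi = prior_independent
    if not 0.0 < pi < 1.0:
        raise ConfigError("prior probability must lie in (0, 1)")
    if np.isnan(log_bf):
        return float("nan")
    if log_bf >= 0:
        if np.isinf(log_bf):
            return 1.0
        return float(1.0 / (1.0 + ((1.0 - pi) / pi) * np.exp(-log_bf)))
    if np.isinf(log_bf):
        return 0.0
    num = pi * np.exp(log_bf)
    return float(num / (num + (1.0 - pi)))


@dataclass(frozen=True)
class DiffLocConfig:
    """Settings for the per-protein differential-localization scan."""

    alr_ref: int | None = None  # 1-based reference fraction; None = last
    alr_eps: float = 1e-6
    priors: GPPriors = GPPriors()
    n_restarts: int = 3
    prior_independent: float = 0.01
    mover_threshold: float = 1.0 - 1e-6
    seed: int = 0


def protein_alr_profiles(
    matrix: SpatialProfileMatrix, protein_id: str, config: DiffLocConfig = DiffLocConfig()
) -> np.ndarray:
    """(R, F-1) ALR coordinates for one protein's replicate compositions."""
    comps = matrix.profiles_of(protein_id)
    return np.vstack(
        [alr_transform(c, ref=config.alr_ref, eps=config.alr_eps) for c in comps]
    )


def diffloc_scan(
    control: SpatialProfileMatrix,
    treated: SpatialProfileMatrix,
    protein_ids: list[str] | None = None,
    config: DiffLocConfig = DiffLocConfig(),
) -> pd.DataFrame:
    """Run the GP two-sample test on every shared protein.

    Returns a frame sorted by descending posterior (ties: descending log
    Bayes factor, then protein id) with columns protein_id,
    log_bayes_factor, posterior, mover.
    """
    if protein_ids is None:
        protein_ids = sorted(set(control.protein_ids) & set(treated.protein_ids))
    rows = []
    for pid in sorted(protein_ids):
        ctrl = protein_alr_profiles(control, pid, config)
        trt = protein_alr_profiles(treated, pid, config)
        try:
            lbf = log_bayes_factor(
                ctrl, trt, config.priors, n_restarts=config.n_restarts, seed=config.seed
            )
        except NumericalError as exc:
            raise NumericalError(f"protein {pid}: {exc}") from exc
        post = bf_to_posterior(lbf, config.prior_independent)
        rows.append((pid, lbf, post, post >= config.mover_threshold))
    frame = pd.DataFrame(rows, columns=["protein_id", "log_bayes_factor", "posterior", "mover"])
    frame = frame.sort_values(
        ["posterior", "log_bayes_factor", "protein_id"],
        ascending=[False, False, True],
        ignore_index=True,
    )
    logger.info("differential-localization scan: %d/%d movers", int(frame["mover"].sum()), len(frame))
    return frame


def call_movers(results: pd.DataFrame, mover_threshold: float = 1.0 - 1e-6) -> pd.DataFrame:
    """Re-flag and re-rank an existing scan at a different posterior threshold."""
    frame = results.copy()
    frame["mover"] = frame["posterior"] >= mover_threshold
    return frame.sort_values(
        ["posterior", "log_bayes_factor", "protein_id"],
        ascending=[False, False, True],
        ignore_index=True,
    )
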