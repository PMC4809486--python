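"""Multiple imputation of the binary criterion via Bayesian logistic regression.

The missingness mechanism is MAR (the missing indicator depends only on
the observed selection variable), so the conditional distribution of Y
given the observed predictors is estimable from the selected cases.  The
imputation model is a logistic regression of Y on X (DRR) or on X and Z
(IRR) — the predictor set must include the cause of missingness for MAR
validity.  Because Y is the only incomplete variable, the
chained-equations cycle reduces to this single conditional model.

Each of the m imputations draws a coefficient vector from the
large-sample posterior (multivariate normal at the ridge-penalized
maximum likelihood estimate with inverse-information covariance), fills
each missing Y with a Bernoulli draw at its fitted probability, and
leaves observed values untouched.  Point estimates are pooled as the
arithmetic mean of the m per-dataset estimates; the completed-data
success proportion pooled this way is the method's estimate of the base
rate of success, which the classical corrections cannot provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlations import biserial, point_biserial, UndefinedCorrelationError
from .selection import RestrictedDataset

__all__ = [
    "LogisticFit",
    "PooledEstimates",
    "ConvergenceError",
    "augment_observations",
    "fit_bayes_logistic",
    "draw_beta",
    "impute_once",
    "multiple_impute",
    "pool_estimates",
    "mice_estimate",
]

_MAX_ITER = 25
_ETA_CAP = 30.0  # |linear predictor| beyond this saturates the logistic


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; the sample is excluded and logged upstream."""


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic imputation model with its approximate posterior."""

    beta_hat: np.ndarray  # intercept first
    cov_hat: np.ndarray
    converged: bool
    n_obs: int
    n_iter: int = 0


@dataclass(frozen=True)
class PooledEstimates:
    """Pooled MI point estimates: arithmetic means over m imputations."""

    r_pb: float
    br: float
    m: int
    r_b: float | None = None  # artificial kind only
    per_imputation: list[dict] = field(default_factory=list)


def _design(predictors: np.ndarray) -> np.ndarray:
    predictors = np.atleast_2d(np.asarray(predictors, dtype=float))
    if predictors.shape[0] == 1 and predictors.shape[1] > 1:
        predictors = predictors.T
    return np.column_stack([np.ones(predictors.shape[0]), predictors])


def augment_observations(
    predictors_all: np.ndarray, predictors_obs: np.ndarray, y_obs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Anti-separation data augmentation for the logistic imputation model.

    Appends, for each predictor, pseudo-observations at the full-sample
    mean +- 0.5 sd of that predictor (other predictors at their means),
    once with each criterion label, carrying total weight ``p + 1`` split
    evenly.  Pseudo values are clamped to the observed range.  Because the
    means and sds are taken over *all* applicants — not just the selected
    ones — the pseudo-points sit in the unselected predictor range and
    gently shrink extrapolated probabilities toward one half there, which
    both stabilizes the fit under (quasi-)separation and is part of the
    imputation engine's default behaviour that the accuracy results
    reflect.

    Returns the augmented ``(predictors, y, weights)`` for fitting; real
    observations carry weight 1.
    """
    X_all = np.atleast_2d(np.asarray(predictors_all, dtype=float))
    if X_all.shape[0] == 1 and X_all.shape[1] > 1:
        X_all = X_all.T
    X_obs = np.atleast_2d(np.asarray(predictors_obs, dtype=float))
    if X_obs.shape[0] == 1 and X_obs.shape[1] > 1:
        X_obs = X_obs.T
    y = np.asarray(y_obs, dtype=float)
    p = X_all.shape[1]
    k = 2  # criterion categories
    nr = 2 * p * k
    mean = X_all.mean(axis=0)
    sd = X_all.std(axis=0, ddof=1)
    lo, hi = X_all.min(axis=0), X_all.max(axis=0)
    pseudo = np.tile(mean, (nr, 1))
    offsets = np.tile([0.5, -0.5], k)
    labels = np.repeat([0.0, 1.0], 2)
    y_pseudo = np.empty(nr)
    for j in range(p):
        block = slice(j * 2 * k, (j + 1) * 2 * k)
        pseudo[block, j] = mean[j] + offsets * sd[j]
        y_pseudo[block] = labels
    pseudo = np.clip(pseudo, lo, hi)
    X_fit = np.vstack([X_obs, pseudo])
    y_fit = np.concatenate([y, y_pseudo])
    w_fit = np.concatenate([np.ones(y.size), np.full(nr, (p + 1) / nr)])
    return X_fit, y_fit, w_fit


def fit_bayes_logistic(
    predictors: np.ndarray,
    y_obs: np.ndarray,
    ridge: float = 1e-5,
    weights: np.ndarray | None = None,
) -> LogisticFit:
    """Ridge-penalized logistic fit by iteratively reweighted least squares.

    ``predictors`` is an (n, p) matrix of observed-row covariates (the
    intercept column is added internally); ``weights`` are optional prior
    case weights (used for augmented pseudo-observations).  The small
    ridge penalty guards against separation, likely at small selection
    ratios with a strong association and an extreme base rate.
    Convergence is judged on the relative deviance change, as in standard
    IRLS implementations.  ``cov_hat`` is the inverse of the penalized
    information at the optimum — the covariance of the normal posterior
    approximation.
    """
    X = _design(predictors)
    y = np.asarray(y_obs, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("predictor and response lengths differ")
    if y.min() == y.max():
        raise ValueError("y_obs is constant; logistic fit undefined")
    pw = np.ones(y.size) if weights is None else np.asarray(weights, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    penalty = ridge * np.eye(p)
    deviance = np.inf
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = np.clip(X @ beta, -_ETA_CAP, _ETA_CAP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = pw * mu * (1.0 - mu)
        # working response for the IRLS normal equations
        zvec = eta + (y - mu) / np.maximum(mu * (1.0 - mu), 1e-10)
        XtW = X.T * w
        info = XtW @ X + penalty
        try:
            beta = np.linalg.solve(info, XtW @ zvec)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        eta = np.clip(X @ beta, -_ETA_CAP, _ETA_CAP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        new_dev = -2.0 * float(
            np.sum(pw * y * np.log(np.maximum(mu, 1e-12)))
            + np.sum(pw * (1.0 - y) * np.log(np.maximum(1.0 - mu, 1e-12)))
        )
        if abs(new_dev - deviance) / (abs(new_dev) + 0.1) < 1e-8:
            deviance = new_dev
            converged = True
            break
        deviance = new_dev
    eta = np.clip(X @ beta, -_ETA_CAP, _ETA_CAP)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = pw * mu * (1.0 - mu)
    info = (X.T * w) @ X + penalty
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("singular information at optimum") from exc
    return LogisticFit(
        beta_hat=beta, cov_hat=cov, converged=converged, n_obs=n, n_iter=it
    )


def draw_beta(fit: LogisticFit, rng: np.random.Generator) -> np.ndarray:
    """One draw from the normal posterior approximation N(beta_hat, cov_hat).

    Non-positive-semidefinite covariances (numerically possible) are
    repaired by flooring eigenvalues at zero.
    """
    cov = fit.cov_hat
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        vals = np.maximum(vals, 0.0)
        chol = vecs * np.sqrt(vals)
    return fit.beta_hat + chol @ rng.standard_normal(fit.beta_hat.size)


def _predictor_matrix(restricted: RestrictedDataset, scenario: str) -> np.ndarray:
    if scenario == "drr":
        return restricted.x[:, None]
    if restricted.z is None:
        raise ValueError("IRR imputation requires z")
    return np.column_stack([restricted.x, restricted.z])


def impute_once(
    restricted: RestrictedDataset,
    beta_star: np.ndarray,
    rng: np.random.Generator,
    scenario: str | None = None,
) -> np.ndarray:
    """Complete the criterion once: Bernoulli draws at fitted probabilities.

    Observed values are kept identical; each missing row gets
    ``Y ~ Bernoulli(expit(eta))`` under the drawn coefficients.
    """
    scenario = scenario or restricted.scenario
    X = _design(_predictor_matrix(restricted, scenario))
    if beta_star.size != X.shape[1]:
        raise ValueError("beta dimension does not match the predictor set")
    y = restricted.y_obs.copy()
    miss = ~restricted.selected
    eta = np.clip(X[miss] @ beta_star, -_ETA_CAP, _ETA_CAP)
    p = 1.0 / (1.0 + np.exp(-eta))
    y[miss] = (rng.random(miss.sum()) < p).astype(float)
    return y.astype(np.int64)


def multiple_impute(
    restricted: RestrictedDataset,
    m: int = 20,
    scenario: str | None = None,
    rng: np.random.Generator | None = None,
    ridge: float = 1e-5,
    augment: bool = True,
) -> list[np.ndarray]:
    """Generate m completed criterion vectors.

    The imputation model is fitted once on the observed rows — by default
    with the :func:`augment_observations` pseudo-data, the imputation
    engine's standard guard against separation; each imputation uses an
    independent posterior draw of the coefficients, so the
    between-imputation spread reflects parameter uncertainty.  With no
    missing values the input criterion is returned m times unchanged.
    """
    scenario = scenario or restricted.scenario
    if rng is None:
        rng = np.random.default_rng()
    if restricted.selected.all():
        y = restricted.y_obs.astype(np.int64)
        return [y.copy() for _ in range(m)]
    X_all = _predictor_matrix(restricted, scenario)
    X_obs = X_all[restricted.selected]
    y_obs = restricted.observed_y()
    if augment:
        X_fit, y_fit, w_fit = augment_observations(X_all, X_obs, y_obs)
        fit = fit_bayes_logistic(X_fit, y_fit, ridge=ridge, weights=w_fit)
    else:
        fit = fit_bayes_logistic(X_obs, y_obs, ridge=ridge)
    if not fit.converged:
        raise ConvergenceError(
            f"logistic fit did not converge in {fit.n_iter} iterations"
        )
    return [
        impute_once(restricted, draw_beta(fit, rng), rng, scenario)
        for _ in range(m)
    ]


def pool_estimates(
    x: np.ndarray, completed: list[np.ndarray], kind: str
) -> PooledEstimates:
    """Pool per-imputation estimates into MI point estimates.

    Per completed dataset: the point-biserial r(x, y), the success
    proportion, and — for an artificial dichotomy — the biserial computed
    with that dataset's own completed proportion (this is how the approach
    corrects the base-rate bias).  Pooled values are arithmetic means; an
    imputation with a constant completed criterion has no defined
    correlation and is dropped from the correlation pool.
    """
    if not completed:
        raise ValueError("no completed datasets to pool")
    rows: list[dict] = []
    for y in completed:
        br_i = float(np.mean(y))
        row = {"br": br_i, "r_pb": np.nan, "r_b": np.nan}
        try:
            est = point_biserial(x, y)
            row["r_pb"] = est.value
            if kind == "artificial":
                row["r_b"] = biserial(est.value, est.q).value
        except UndefinedCorrelationError:
            pass
        rows.append(row)
    r_pb_vals = np.array([r["r_pb"] for r in rows])
    if np.isnan(r_pb_vals).all():
        raise UndefinedCorrelationError(
            "criterion constant in every completed dataset"
        )

    def _mean(values: np.ndarray) -> float:
        # identical values (e.g. nothing was missing) pool to themselves
        # exactly, so the no-op contract holds bit-for-bit
        finite = values[~np.isnan(values)]
        if np.all(finite == finite[0]):
            return float(finite[0])
        return float(finite.mean())

    r_pb = _mean(r_pb_vals)
    br = _mean(np.array([r["br"] for r in rows]))
    r_b = None
    if kind == "artificial":
        r_b = _mean(np.array([r["r_b"] for r in rows]))
    return PooledEstimates(
        r_pb=r_pb, br=br, m=len(completed), r_b=r_b, per_imputation=rows
    )


def mice_estimate(
    restricted: RestrictedDataset,
    m: int = 20,
    kind: str | None = None,
    scenario: str | None = None,
    rng: np.random.Generator | None = None,
    ridge: float = 1e-5,
) -> PooledEstimates:
    """Impute m times and pool: the full MI correction of one sample."""
    kind = kind or restricted.kind
    completed = multiple_impute(restricted, m=m, scenario=scenario, rng=rng, ridge=ridge)
    return pool_estimates(restricted.x, completed, kind)
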