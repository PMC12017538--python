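"""Breeding-value prediction: similarity-matrix kriging and elastic net.

Kriging predicts a test family as a similarity-weighted combination of
training phenotypes, with weights omega = Sigma^{-1} rho where Sigma =
theta * S + (1 - theta) * I on the training block and rho is the (theta-
scaled) similarity vector between the test family and the training
families. The default form is centered best-linear-unbiased prediction,
y_hat = mu + rho' Sigma^{-1} (Y - mu); the literal uncentered weighted
average is available via ``raw_weights`` and coincides with the centered
form whenever the weights sum to one.

The elastic net minimizes (1/2n) sum (y_i - b0 - x_i'b)^2 +
lambda * (0.5 * (1 - alpha) ||b||^2 + alpha ||b||_1) by cyclic coordinate
descent over internally standardized features, with an unpenalized
intercept. Tuning follows a bootstrap grid search: 25 resamples of the
training families over alpha in 0.1..0.9 and lambda in {1, 0.1, 0.01,
0.001}, scored by out-of-bag RMSE; ties prefer the smaller lambda, then
the smaller alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.linalg import cho_factor, cho_solve

from .config import RunConfig
from .io import FamilyFeatureMatrix, PhenotypeTable, ValidationError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "KrigingModel",
    "ElasticNetModel",
    "PredictionResult",
    "kriging_fit",
    "kriging_predict",
    "kriging_predict_families",
    "elasticnet_fit",
    "elasticnet_objective",
    "tune_elasticnet",
    "elasticnet_predict_families",
    "combine_predictions",
]


# ---------------------------------------------------------------------------
# kriging
# ---------------------------------------------------------------------------

@dataclass
class KrigingModel:
    train_ids: list[str]
    y: np.ndarray
    sigma: np.ndarray
    theta: float
    mu: float
    raw_weights: bool = False
    _cho: tuple = field(default=None, repr=False)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return cho_solve(self._cho, rhs)


def kriging_fit(
    s: SimilarityMatrix,
    phen_train: PhenotypeTable,
    theta: float = 1.0,
    *,
    raw_weights: bool = False,
    ridge: float | str = "auto",
    jitter: float = 1e-6,
) -> KrigingModel:
    """Build the training-block composite matrix Sigma = theta S + (1-theta) I.

    A correlation similarity estimated from p features carries sampling
    noise of order 1/sqrt(p) per entry, which Sigma^{-1} amplifies badly
    when the feature count is comparable to the number of training
    families. ``ridge="auto"`` therefore adds 2/sqrt(p) to the diagonal
    (negligible for large p); pass ``ridge=0.0`` for the unregularized
    solve or any float for a fixed value.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValidationError("theta must be in [0, 1]")
    train_ids = list(phen_train.family_ids)
    missing = [f for f in train_ids if f not in set(s.family_ids)]
    if missing:
        raise ValidationError(f"similarity matrix missing training families: {missing[:5]}")
    if ridge == "auto":
        # floor of 0.2: redundant (correlated) features make the nominal
        # feature count overstate the effective one
        ridge = max(0.2, 2.0 / np.sqrt(max(1, s.n_features)))
    sigma = (
        theta * s.entries.loc[train_ids, train_ids].to_numpy()
        + (1.0 - theta
           + float(ridge)) * np.eye(len(train_ids))
    )
    y = phen_train.bv.loc[train_ids].to_numpy()
    try:
        cho = cho_factor(sigma)
    except np.linalg.LinAlgError:
        logger.warning("kriging_fit: Sigma not SPD, adding diagonal jitter %g", jitter)
        sigma = sigma + jitter * np.eye(len(train_ids))
        cho = cho_factor(sigma)  # raises if still singular
    return KrigingModel(
        train_ids=train_ids,
        y=y,
        sigma=sigma,
        theta=theta,
        mu=float(y.mean()),
        raw_weights=raw_weights,
        _cho=cho,
    )


def kriging_predict(model: KrigingModel, rho: np.ndarray) -> float:
    """Predict one test family from its similarity vector to the training set.

    ``rho`` is the raw similarity of the test family to each training
    family, in training order; it is scaled by theta internally (the
    identity component has no train-test cross terms).
    """
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (len(model.train_ids),):
        raise ValidationError("rho must align with the training family order")
    rho_s = model.theta * rho
    if model.raw_weights:
        omega = model.solve(rho_s)
        return float(omega @ model.y)
    return float(model.mu + rho_s @ model.solve(model.y - model.mu))


def kriging_predict_families(
    model: KrigingModel, s: SimilarityMatrix, test_ids
) -> "PredictionResult":
    test_ids = list(test_ids)
    block = s.entries.loc[test_ids, model.train_ids].to_numpy()
    preds = np.array([kriging_predict(model, block[i]) for i in range(len(test_ids))])
    return PredictionResult(
        predictions=pd.Series(preds, index=test_ids),
        model="kriging",
        datatype={"transcript_log2": "transcripts", "snp_dosage": "snps"}.get(
            s.source_feature_kind, s.source_feature_kind
        ),
        stage="",
    )


# ---------------------------------------------------------------------------
# elastic net
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cd_sweep(xs, r, beta, lam_l1, lam_l2):
    """One cyclic coordinate-descent sweep; returns max squared coef change."""
    n, p = xs.shape
    max_d2 = 0.0
    for j in range(p):
        bj = beta[j]
        rho = bj + np.dot(xs[:, j], r) / n
        # soft threshold
        if rho > lam_l1:
            bnew = (rho - lam_l1) / (1.0 + lam_l2)
        elif rho < -lam_l1:
            bnew = (rho + lam_l1) / (1.0 + lam_l2)
        else:
            bnew = 0.0
        d = bnew - bj
        if d != 0.0:
            r -= xs[:, j] * d
            beta[j] = bnew
            if d * d > max_d2:
                max_d2 = d * d
    return max_d2


@njit(cache=True)
def _cd_solve(xs, yc, beta, lam_l1, lam_l2, tol, max_sweeps):
    """Cyclic coordinate descent with active-set cycling.

    Convergence follows the standard relative criterion for this family of
    solvers: stop when the largest squared coefficient change in a sweep
    drops below tol * var(y). After each full sweep the nonzero (active)
    coefficients are cycled to convergence before the next full sweep.
    """
    n, p = xs.shape
    r = yc - xs @ beta
    thresh = tol * max(np.var(yc), 1e-12)
    sweeps = 0
    converged = False
    while sweeps < max_sweeps:
        sweeps += 1
        if _cd_sweep(xs, r, beta, lam_l1, lam_l2) < thresh:
            converged = True
            break
        active = np.nonzero(beta)[0]
        while sweeps < max_sweeps:
            sweeps += 1
            max_d2 = 0.0
            for k in range(active.size):
                j = active[k]
                bj = beta[j]
                rho = bj + np.dot(xs[:, j], r) / n
                if rho > lam_l1:
                    bnew = (rho - lam_l1) / (1.0 + lam_l2)
                elif rho < -lam_l1:
                    bnew = (rho + lam_l1) / (1.0 + lam_l2)
                else:
                    bnew = 0.0
                d = bnew - bj
                if d != 0.0:
                    r -= xs[:, j] * d
                    beta[j] = bnew
                    if d * d > max_d2:
                        max_d2 = d * d
            if max_d2 < thresh:
                break
    return sweeps, converged


@dataclass
class ElasticNetModel:
    intercept: float
    coef: pd.Series  # on the original feature scale
    alpha: float
    lam: float
    feature_means: pd.Series
    feature_scales: pd.Series
    n_sweeps: int = 0

    def predict(self, x: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.coef.index if c not in x.columns]
        if missing:
            raise ValidationError(f"features absent at predict time: {missing[:5]}")
        xm = x.loc[:, self.coef.index].to_numpy(dtype=float)
        return self.intercept + xm @ self.coef.to_numpy()


def elasticnet_objective(
    x: np.ndarray, y: np.ndarray, beta0: float, beta: np.ndarray, alpha: float, lam: float
) -> float:
    """(1/2n) RSS + lambda * (0.5 (1-alpha) ||b||^2 + alpha ||b||_1)."""
    n = y.size
    resid = y - beta0 - x @ beta
    return float(
        resid @ resid / (2 * n)
        + lam * (0.5 * (1 - alpha) * beta @ beta + alpha * np.abs(beta).sum())
    )


def _standardize(x: np.ndarray):
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    usable = scale > 0
    xs = np.zeros_like(x)
    xs[:, usable] = (x[:, usable] - mean[usable]) / scale[usable]
    return xs, mean, scale, usable


def elasticnet_fit(
    x: FamilyFeatureMatrix | pd.DataFrame,
    y: PhenotypeTable | pd.Series,
    alpha: float,
    lam: float,
    *,
    tol: float = 1e-7,
    max_sweeps: int = 100_000,
    warm_start: np.ndarray | None = None,
) -> ElasticNetModel:
    """Fit the elastic net by cyclic coordinate descent.

    Features are standardized internally; returned coefficients are on the
    original scale and the intercept is unpenalized. Raises on
    non-convergence.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must be in [0, 1]")
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    xdf = x.values if isinstance(x, FamilyFeatureMatrix) else x
    yser = y.bv if isinstance(y, PhenotypeTable) else y
    yser = yser.loc[xdf.index]
    xa = xdf.to_numpy(dtype=float)
    ya = yser.to_numpy(dtype=float)
    xs, mean, scale, usable = _standardize(xa)
    ybar = ya.mean()
    yc = ya - ybar

    beta_std = np.zeros(xa.shape[1]) if warm_start is None else warm_start.copy()
    beta_std[~usable] = 0.0
    sweeps, converged = _cd_solve(
        np.asfortranarray(xs), yc, beta_std, lam * alpha, lam * (1.0 - alpha), tol, max_sweeps
    )
    if not converged:
        raise ValidationError(
            f"elastic net did not converge in {max_sweeps} sweeps "
            f"(alpha={alpha}, lambda={lam}, p={xa.shape[1]})"
        )
    coef_orig = np.zeros_like(beta_std)
    coef_orig[usable] = beta_std[usable] / scale[usable]
    intercept = float(ybar - mean @ coef_orig)
    return ElasticNetModel(
        intercept=intercept,
        coef=pd.Series(coef_orig, index=xdf.columns),
        alpha=float(alpha),
        lam=float(lam),
        feature_means=pd.Series(mean, index=xdf.columns),
        feature_scales=pd.Series(scale, index=xdf.columns),
        n_sweeps=int(sweeps),
    )


def elasticnet_sweep_objectives(
    x: pd.DataFrame, y: pd.Series, alpha: float, lam: float, n_sweeps: int = 50
) -> list[float]:
    """Objective value after each coordinate-descent sweep (diagnostic)."""
    xa = x.to_numpy(dtype=float)
    ya = y.to_numpy(dtype=float)
    xs, mean, scale, usable = _standardize(xa)
    yc = ya - ya.mean()
    beta = np.zeros(xa.shape[1])
    r = yc - xs @ beta
    objs = []
    xs_f = np.asfortranarray(xs)
    for _ in range(n_sweeps):
        _cd_sweep(xs_f, r, beta, lam * alpha, lam * (1.0 - alpha))
        objs.append(elasticnet_objective(xs, yc, 0.0, beta, alpha, lam))
    return objs


def tune_elasticnet(
    x: FamilyFeatureMatrix | pd.DataFrame,
    y: PhenotypeTable | pd.Series,
    cfg: RunConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Bootstrap grid search for (alpha, lambda) scored by out-of-bag RMSE.

    For each of ``cfg.n_bootstrap`` resamples of the training families the
    whole grid is fitted on the resample and scored on the out-of-bag
    families; a resample whose out-of-bag set is empty is redrawn. Returns
    the grid point with minimal mean RMSE, ties going to the smaller
    lambda then the smaller alpha.
    """
    cfg = cfg or RunConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    xdf = x.values if isinstance(x, FamilyFeatureMatrix) else x
    yser = (y.bv if isinstance(y, PhenotypeTable) else y).loc[xdf.index]
    n = xdf.shape[0]
    grid = [(a, l) for a in cfg.alphas for l in cfg.lambdas]
    sse = {g: 0.0 for g in grid}
    cnt = {g: 0 for g in grid}
    lam_desc = sorted(set(cfg.lambdas), reverse=True)
    for _ in range(cfg.n_bootstrap):
        while True:
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size > 0:
                break
            logger.info("tune_elasticnet: empty out-of-bag set, redrawing")
        xb = xdf.iloc[idx]
        # resampled families repeat; reset the index so rows stay distinct
        xb = xb.reset_index(drop=True)
        yb = pd.Series(yser.to_numpy()[idx])
        xo = xdf.iloc[oob].to_numpy(dtype=float)
        yo = yser.to_numpy()[oob]
        for a in cfg.alphas:
            warm = None
            for l in lam_desc:
                model = elasticnet_fit(xb, yb, a, l, warm_start=warm)
                scales = model.feature_scales.to_numpy()
                warm = model.coef.to_numpy() * np.where(scales > 0, scales, 1.0)
                pred = model.intercept + xo @ model.coef.to_numpy()
                sse[(a, l)] += float(((pred - yo) ** 2).sum())
                cnt[(a, l)] += oob.size
    rmse = {g: np.sqrt(sse[g] / cnt[g]) for g in grid}
    best_val = min(rmse.values())
    candidates = [g for g, v in rmse.items() if v <= best_val + 1e-12]
    # ties: smaller lambda, then smaller alpha
    best = sorted(candidates, key=lambda g: (g[1], g[0]))[0]
    return best


def elasticnet_predict_families(
    model: ElasticNetModel, x: FamilyFeatureMatrix, test_ids, datatype: str
) -> "PredictionResult":
    test_ids = list(test_ids)
    preds = model.predict(x.values.loc[test_ids])
    return PredictionResult(
        predictions=pd.Series(preds, index=test_ids),
        model="elasticnet",
        datatype=datatype,
        stage="",
    )


# ---------------------------------------------------------------------------
# combining data types
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    predictions: pd.Series
    model: str     # "kriging" | "elasticnet" | "combined"
    datatype: str  # "snps" | "transcripts" | "combined"
    stage: str     # "ALL" | "setA" | "setB" | "setC"

    def __post_init__(self) -> None:
        if not np.isfinite(self.predictions.to_numpy(dtype=float)).all():
            raise ValidationError("predictions must be finite")


def combine_predictions(a: PredictionResult, b: PredictionResult) -> PredictionResult:
    """Per-family arithmetic mean of two single-datatype predictions."""
    if set(a.predictions.index) != set(b.predictions.index):
        raise ValidationError("combine_predictions: family sets differ")
    if a.model != b.model:
        raise ValidationError("combine_predictions: model labels differ")
    ids = list(a.predictions.index)
    mean = (a.predictions.loc[ids] + b.predictions.loc[ids]) / 2.0
    return PredictionResult(mean, a.model, "combined", a.stage)
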