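"""L1-penalized logistic scoring of temperature-pair indicators.

Given the binary pair indicators Z ∈ {0,1}^(n×k) and class labels
y ∈ {0,1}^n, the model minimizes the lasso-logistic objective

    f(β₀, β) = (1/n) Σ_s [ log(1 + e^{η_s}) − y_s η_s ] + λ ‖β‖₁ ,
    η_s = β₀ + z_sᵀ β ,

with the intercept unpenalized.  λ is chosen by seeded, class-stratified
k-fold cross-validation of the held-out binomial deviance along a
log-spaced path from λ_max (the smallest λ with all coefficients zero)
down to 10⁻³·λ_max.  Pairs whose coefficient is exactly zero at the chosen
λ are dropped; the returned coefficients are the penalized solution itself
(no post-selection refit), so a sample's score

    score = β₀ + Σ_k β_k · 1[X_ti_k > X_tj_k]

is a single real number and the decision rule is its sign: score > 0 →
positive class, score ≤ 0 → negative class (ties broken toward the
lower-risk class).

The objective is solved through the positive/negative-part reformulation of
the L1 term as a bound-constrained smooth convex program (projected
quasi-Newton), with warm starts along the λ path.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import FitError, GridMismatchError, SplitError
from .io import NEGATIVE, POSITIVE, Cohort
from .preprocess import FeatureVector, GridSpec
from .tsp import PairFeature, PairMatrix, _as_binary_labels, _grid_index, indicator_matrix

logger = logging.getLogger(__name__)


def grid_hash(g: GridSpec) -> str:
    """Stable short hash identifying a GridSpec (guards model/feature mixups)."""
    payload = json.dumps(
        [g.t_min, g.t_max, g.dt, g.feature_lo, g.feature_hi, g.feature_step]
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FittedModel:
    """A fitted sparse logistic scorer over temperature-pair indicators."""

    pairs: list[PairFeature]
    intercept: float
    coefficients: np.ndarray
    penalty: float
    positive_label: str = POSITIVE
    negative_label: str = NEGATIVE
    cv_folds: int = 0
    seed: int = 0
    grid_id: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.pairs):
            raise FitError("one coefficient per pair required")
        if self.penalty < 0:
            raise FitError(f"penalty must be >= 0, got {self.penalty}")

    # -- persistence ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "pairs": [
                {
                    "ti": p.ti,
                    "tj": p.tj,
                    "score_primary": p.score_primary,
                    "score_secondary": p.score_secondary,
                }
                for p in self.pairs
            ],
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "penalty": self.penalty,
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "grid_id": self.grid_id,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedModel":
        doc = json.loads(Path(path).read_text())
        pairs = [
            PairFeature(p["ti"], p["tj"], p["score_primary"], p["score_secondary"])
            for p in doc["pairs"]
        ]
        return cls(
            pairs=pairs,
            intercept=doc["intercept"],
            coefficients=np.asarray(doc["coefficients"], dtype=float),
            penalty=doc["penalty"],
            positive_label=doc["positive_label"],
            negative_label=doc["negative_label"],
            cv_folds=doc["cv_folds"],
            seed=doc["seed"],
            grid_id=doc.get("grid_id", ""),
        )


# ---------------------------------------------------------------------------
# solver


def solve_lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    fit_intercept: bool = True,
    beta0: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 2000,
) -> tuple[float, np.ndarray]:
    """Minimize the lasso-logistic objective.

    Uses the standard positive/negative-part reformulation
    β = β⁺ − β⁻ with β⁺, β⁻ ≥ 0, which turns the non-smooth L1 term into a
    linear one, and solves the resulting bound-constrained smooth convex
    problem with projected quasi-Newton iterations (L-BFGS-B).  Coordinates
    at the bound are exactly zero.  Deterministic; ``beta0`` (intercept
    prepended when fitted) warm-starts the iteration.

    Returns ``(intercept, coefficients)``; with ``fit_intercept=False`` the
    intercept is fixed at 0.
    """
    from scipy.optimize import minimize

    n, k = X.shape
    if beta0 is None:
        b0, beta = 0.0, np.zeros(k)
    elif fit_intercept:
        b0, beta = float(beta0[0]), np.asarray(beta0[1:], dtype=float)
    else:
        b0, beta = 0.0, np.asarray(beta0, dtype=float)
    theta0 = np.concatenate(
        [[b0] if fit_intercept else [], np.maximum(beta, 0.0), np.maximum(-beta, 0.0)]
    )
    off = 1 if fit_intercept else 0

    def fg(theta):
        bp, bm = theta[off : off + k], theta[off + k :]
        eta = X @ (bp - bm)
        if fit_intercept:
            eta = eta + theta[0]
        loss = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
        g_eta = (1.0 / (1.0 + np.exp(-eta)) - y) / n
        xg = X.T @ g_eta
        grad = np.concatenate(
            [[g_eta.sum()] if fit_intercept else [], xg + lam, -xg + lam]
        )
        return loss + lam * (bp.sum() + bm.sum()), grad

    bounds = ([(None, None)] if fit_intercept else []) + [(0.0, None)] * (2 * k)
    res = minimize(
        fg,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
    )
    theta = res.x
    beta = theta[off : off + k] - theta[off + k :]
    beta[np.abs(beta) < 1e-8] = 0.0  # snap sub-tolerance coefficients
    return (float(theta[0]) if fit_intercept else 0.0), beta


def lambda_max(X: np.ndarray, y: np.ndarray, fit_intercept: bool = True) -> float:
    """Smallest λ at which every penalized coefficient is zero.

    With an unpenalized intercept the null model predicts the class
    prevalence p̄, and the KKT condition gives
    λ_max = max_j |x_jᵀ(y − p̄)| / n.
    """
    n = len(y)
    pbar = y.mean() if fit_intercept else 0.5
    return float(np.max(np.abs(X.T @ (y - pbar))) / n)


def default_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100,
                        ratio: float = 1e-3, fit_intercept: bool = True) -> np.ndarray:
    lmax = lambda_max(X, y, fit_intercept)
    if lmax <= 0:
        lmax = 1e-3
    return np.geomspace(lmax, ratio * lmax, n_lambda)


def _deviance(eta: np.ndarray, y: np.ndarray) -> float:
    """Total binomial deviance of linear predictors eta against labels y."""
    return float(2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta))


#: per-observation training deviance below which the fit is saturated and
#: the λ path is truncated (smaller λ only inflates coefficients)
SATURATION_DEVIANCE = 0.01


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    fit_intercept: bool = True,
    saturation_stop: bool = True,
) -> list[tuple[float, np.ndarray]]:
    """Warm-started solutions along a decreasing λ path.

    With ``saturation_stop`` the path is cut short once the training
    deviance per observation drops below :data:`SATURATION_DEVIANCE`
    (the model already fits the data essentially perfectly), so the
    returned list may be shorter than ``lambdas``.
    """
    sols = []
    warm = None
    n = len(y)
    for lam in lambdas:
        b0, b = solve_lasso_logistic(X, y, lam, fit_intercept, beta0=warm)
        warm = np.r_[b0, b] if fit_intercept else b
        sols.append((b0, b))
        if saturation_stop and _deviance(b0 + X @ b, y) / n < SATURATION_DEVIANCE:
            break
    return sols


def fit(
    pm: PairMatrix,
    labels,
    cv_folds: int | None = None,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
    lambda_rule: str = "min",
    fit_intercept: bool = True,
    grid_id: str = "",
) -> FittedModel:
    """Fit the lasso-logistic scorer with cross-validated λ.

    Parameters
    ----------
    pm
        Indicator matrix over candidate pairs.
    labels
        sample_id→label map or aligned label sequence (negative/positive or 0/1).
    cv_folds
        Number of stratified folds; ``None`` picks min(10, smallest class
        size); a value equal to n gives leave-one-out.
    seed
        Seeds the fold shuffle; fixed seed + inputs → identical model.
    lambda_grid
        Optional explicit λ path (decreasing); default is 100 log-spaced
        values from λ_max down to 10⁻³ λ_max.
    lambda_rule
        ``"min"`` (λ of minimal mean CV deviance) or ``"1se"`` (largest λ
        within one standard error of that minimum).

    Returns a model containing only the pairs with nonzero coefficients.
    """
    y = _as_binary_labels(labels, pm.sample_ids)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 == 0 or n1 == 0:
        raise FitError("both classes must be present to fit")
    if n0 < 2 or n1 < 2:
        raise FitError(f"need >= 2 samples per class, got {n0} and {n1}")
    if lambda_rule not in ("min", "1se"):
        raise FitError(f"unknown lambda_rule {lambda_rule!r}")

    X_full = pm.indicators.astype(float)
    keep = np.flatnonzero(X_full.std(axis=0) > 0)
    if len(keep) < X_full.shape[1]:
        dropped = [pm.pairs[i].label() for i in range(X_full.shape[1]) if i not in keep]
        logger.warning("dropping constant indicator columns: %s", dropped)
    if len(keep) == 0:
        # nothing informative left: intercept-only model at the prevalence
        logger.warning("all indicator columns constant; fitting intercept only")
        pbar = y.mean()
        return FittedModel(
            pairs=[],
            intercept=float(np.log(pbar / (1.0 - pbar))),
            coefficients=np.empty(0),
            penalty=0.0,
            cv_folds=0,
            seed=seed,
            grid_id=grid_id,
        )
    X = X_full[:, keep]
    pairs = [pm.pairs[i] for i in keep]

    if lambda_grid is None:
        lambdas = default_lambda_grid(X, y, fit_intercept=fit_intercept)
    else:
        lambdas = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    if cv_folds is None:
        cv_folds = min(10, n0, n1)
    cv_folds = int(cv_folds)
    if len(lambdas) > 1:
        if cv_folds < 2:
            raise FitError("cross-validation needs >= 2 folds")
        cv_folds_eff = min(cv_folds, n0, n1) if cv_folds < len(y) else len(y)
        if cv_folds_eff < cv_folds:
            logger.warning("reducing cv_folds to %d (smallest class)", cv_folds_eff)
        if cv_folds_eff == len(y):
            # leave-one-out: folds of size 1, no stratification possible
            folds = [(np.delete(np.arange(len(y)), i), np.array([i]))
                     for i in range(len(y))]
        else:
            skf = StratifiedKFold(n_splits=cv_folds_eff, shuffle=True, random_state=seed)
            folds = list(skf.split(X, y))
        dev = np.zeros((len(folds), len(lambdas)))
        for f, (tr, te) in enumerate(folds):
            sols = fit_path(X[tr], y[tr], lambdas, fit_intercept)
            for li, (b0, b) in enumerate(sols):
                dev[f, li] = _deviance(b0 + X[te] @ b, y[te])
            # a truncated (saturated) path repeats its last held-out deviance
            dev[f, len(sols):] = dev[f, len(sols) - 1]
        # mean held-out deviance per observation, averaged over folds
        sizes = np.array([len(te) for _, te in folds], dtype=float)
        mean_dev = (dev / sizes[:, None]).mean(axis=0)
        best = int(np.argmin(mean_dev))
        if lambda_rule == "1se":
            se = (dev / sizes[:, None]).std(axis=0, ddof=1) / np.sqrt(len(folds))
            cutoff = mean_dev[best] + se[best]
            best = int(np.flatnonzero(mean_dev <= cutoff)[0])  # largest λ first
        lam = float(lambdas[best])
    else:
        lam = float(lambdas[0])
        cv_folds_eff = 0

    # final warm-started fit on all data down the path to the chosen λ;
    # if the full-data fit saturates earlier, the achieved λ is reported
    path_to_lam = lambdas[: np.flatnonzero(np.isclose(lambdas, lam))[0] + 1] \
        if len(lambdas) > 1 else lambdas
    sols = fit_path(X, y, path_to_lam, fit_intercept)
    b0, b = sols[-1]
    lam = float(path_to_lam[len(sols) - 1])

    nz = np.flatnonzero(b != 0.0)
    return FittedModel(
        pairs=[pairs[i] for i in nz],
        intercept=b0,
        coefficients=b[nz],
        penalty=lam,
        cv_folds=cv_folds_eff if len(lambdas) > 1 else 0,
        seed=seed,
        grid_id=grid_id,
    )


# ---------------------------------------------------------------------------
# scoring


def _indicators_for(model: FittedModel, fv: FeatureVector) -> np.ndarray:
    vals = np.empty(len(model.pairs))
    for k, p in enumerate(model.pairs):
        i = _grid_index(fv.grid, p.ti)
        j = _grid_index(fv.grid, p.tj)
        vals[k] = 1.0 if fv.values[i] > fv.values[j] else 0.0
    return vals


def score(model: FittedModel, fv: FeatureVector) -> float:
    """Real-valued sample score: intercept + Σ coef·indicator."""
    try:
        ind = _indicators_for(model, fv)
    except GridMismatchError as e:
        raise GridMismatchError(
            f"sample {fv.sample_id!r}: {e} (model trained on another grid?)"
        ) from None
    return float(model.intercept + model.coefficients @ ind)


def classify(model: FittedModel, fv: FeatureVector) -> str:
    """Sign rule on the score; a score of exactly 0 maps to the negative class."""
    return model.positive_label if score(model, fv) > 0 else model.negative_label


def score_features(model: FittedModel, features: list[FeatureVector]):
    """Score and classify a list of feature vectors.

    Returns a list of ``(sample_id, score, predicted_label)`` tuples.
    """
    out = []
    for fv in features:
        s = score(model, fv)
        lab = model.positive_label if s > 0 else model.negative_label
        out.append((fv.sample_id, s, lab))
    return out


def train_validate_split(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Partition a cohort by diagnosis confidence.

    Training = samples with a confirmed diagnosis, validation = the rest;
    every sample must carry a confirmed flag.  An empty validation set is
    allowed (warned); an empty training set is an error.
    """
    missing = [s for s in cohort.sample_ids if s not in cohort.confirmed]
    if missing:
        raise SplitError(f"samples without confirmed flag: {missing}")
    train_ids = [s for s in cohort.sample_ids if cohort.confirmed[s]]
    val_ids = [s for s in cohort.sample_ids if not cohort.confirmed[s]]
    if not train_ids:
        raise SplitError("no confirmed samples to train on")
    if not val_ids:
        logger.warning("all samples confirmed; validation set is empty")
    return cohort.subset(train_ids), cohort.subset(val_ids)


__all__ = [
    "FittedModel",
    "fit",
    "fit_path",
    "score",
    "classify",
    "score_features",
    "train_validate_split",
    "solve_lasso_logistic",
    "lambda_max",
    "default_lambda_grid",
    "grid_hash",
    "indicator_matrix",
]
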