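"""Elastic-net passage clock: fitting, prediction, evaluation, and the
drug-deceleration readout.

The clock solves

    min_{w0, w}  (1/2n) * sum_i (p_i - w0 - x_i' w)^2
                 + lambda * ( alpha * ||w||_1 + (1 - alpha)/2 * ||w||_2^2 )

over samples i with passage p_i and screened CpG beta values x_i.
Predictors are standardised internally (mean 0, variance 1 over the
training samples); reported coefficients are mapped back to the
original beta scale. ``lambda`` is chosen by seeded k-fold
cross-validation (folds stratified by passage) minimising mean squared
prediction error, with an optional one-standard-error rule. The mixing
parameter defaults to alpha = 0.5.

Prediction is the affine map ``p_hat = w0 + sum_j w_j beta_j``; the
deceleration readout compares ``delta = p_hat - p`` between a treated
and a control cohort per passage level (negative effect = the treated
population ages more slowly).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path

from .exceptions import ConfigError, DesignError, LabelError, MissingProbeError
from .io import BetaMatrix, ClockModel, EvalMetrics, PredictionResult, SampleSheet

log = logging.getLogger(__name__)

__all__ = [
    "CvSpec",
    "CohortComparison",
    "fit_clock",
    "predict_passage",
    "evaluate",
    "compute_acceleration",
    "elastic_net_fit",
    "elastic_net_objective",
    "lambda_max",
]


@dataclass(frozen=True)
class CvSpec:
    """Cross-validation settings for the penalty parameter.

    The lambda grid is auto-generated unless given: ``n_lambda`` values
    log-spaced (descending) from ``lambda_max`` (smallest penalty
    zeroing every coefficient) down to ``lambda_min_ratio * lambda_max``.
    ``selection`` is ``"min"`` (CV-minimising lambda) or ``"1se"``
    (largest lambda within one standard error of the minimum).
    """

    n_folds: int = 10
    lambda_grid: tuple | None = None
    selection: str = "min"
    seed: int = 0
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4

    def __post_init__(self):
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.selection not in ("min", "1se"):
            raise ConfigError(f"unknown selection rule {self.selection!r}")
        if self.lambda_grid is not None:
            grid = tuple(float(g) for g in self.lambda_grid)
            if any(g <= 0 for g in grid):
                raise ConfigError("lambda grid must be positive")
            if list(grid) != sorted(grid, reverse=True) or len(set(grid)) != len(grid):
                raise ConfigError("lambda grid must be strictly descending")
            object.__setattr__(self, "lambda_grid", grid)


# ---------------------------------------------------------------------------
# elastic-net core (scikit-learn coordinate descent behind this surface)
# ---------------------------------------------------------------------------

def elastic_net_fit(X: np.ndarray, y: np.ndarray, alpha: float, lam: float,
                    tol: float = 1e-10, max_iter: int = 500_000):
    """Solve the elastic-net problem at a fixed penalty on ``X`` as
    given (no internal standardisation). Returns ``(intercept, coef)``."""
    if not (0.0 <= alpha <= 1.0):
        raise ConfigError(f"alpha {alpha} outside [0, 1]")
    if lam < 0:
        raise ConfigError("lambda must be >= 0")
    if lam == 0:
        # unpenalised limit: plain least squares
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        return float(y.mean() - X.mean(axis=0) @ coef), coef
    model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True,
                       tol=tol, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        model.fit(X, y)
    return float(model.intercept_), np.asarray(model.coef_, dtype=float)


def elastic_net_objective(X, y, intercept, coef, alpha, lam) -> float:
    """Value of the penalised objective at ``(intercept, coef)``."""
    r = y - intercept - X @ coef
    n = y.size
    return float((r @ r) / (2 * n)
                 + lam * (alpha * np.abs(coef).sum()
                          + 0.5 * (1 - alpha) * coef @ coef))


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty at which every coefficient is zero:
    ``max_j |x_j' (y - ybar)| / (n * alpha)`` with centred columns."""
    if alpha <= 0:
        raise ConfigError("lambda_max undefined for alpha <= 0 (no L1 term)")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return float(np.max(np.abs(Xc.T @ yc)) / (len(y) * alpha))


def _auto_grid(X, y, alpha, n_lambda, min_ratio):
    lmax = lambda_max(X, y, alpha)
    if lmax == 0:
        raise DesignError("response is orthogonal to every predictor")
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def _stratified_folds(passages: np.ndarray, n_folds: int, seed: int):
    """Assign samples to folds by dealing the (seed-shuffled) members of
    each passage level round-robin, so folds stay passage-balanced."""
    rng = np.random.default_rng(seed)
    fold_of = np.empty(passages.size, dtype=int)
    start = 0
    for level in np.unique(passages):
        members = np.flatnonzero(passages == level)
        rng.shuffle(members)
        for k, idx in enumerate(members):
            fold_of[idx] = (start + k) % n_folds
        start += members.size
    return fold_of


def _standardize(X):
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)  # ddof=0
    return (X - mu) / sigma, mu, sigma


def fit_clock(beta: BetaMatrix, sheet: SampleSheet, alpha: float = 0.5,
              cv: CvSpec | None = None,
              screening_threshold: float | None = None) -> ClockModel:
    """Fit the passage clock on a screened beta matrix.

    ``beta`` must be restricted to the screened candidate probes and be
    complete; every sample needs a passage in ``sheet``. Constant
    predictor columns are dropped with a warning. The returned model
    stores only probes with nonzero coefficients (original beta scale)
    plus full training provenance.
    """
    cv = cv or CvSpec()
    sample_ids = list(beta.sample_ids)
    n = len(sample_ids)
    if n < cv.n_folds:
        raise ConfigError(f"{n} samples < {cv.n_folds} CV folds")
    if beta.n_probes < 1:
        raise DesignError("no candidate probes to fit on")
    if np.isnan(beta.values).any():
        raise DesignError("beta matrix contains missing values")
    y = sheet.passages_for(sample_ids)
    X = beta.values.T.copy()  # samples x probes
    probes = list(beta.probe_ids)

    keep = X.std(axis=0) > 0
    if not keep.all():
        log.warning("dropping %d constant predictor columns", int((~keep).sum()))
        X = X[:, keep]
        probes = [p for p, k in zip(probes, keep) if k]
    if X.shape[1] == 0:
        raise DesignError("all predictor columns are constant")

    Xs, mu, sigma = _standardize(X)
    grid = np.asarray(cv.lambda_grid, dtype=float) if cv.lambda_grid is not None \
        else _auto_grid(Xs, y, alpha, cv.n_lambda, cv.lambda_min_ratio)

    fold_of = _stratified_folds(y, cv.n_folds, cv.seed)
    fold_mse = np.full((cv.n_folds, grid.size), np.nan)
    for k in range(cv.n_folds):
        val = fold_of == k
        if not val.any():
            continue
        Xtr, ytr = Xs[~val], y[~val]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        # whole descending-lambda path in one coordinate-descent sweep;
        # a loose tolerance is ample for comparing fold MSEs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            _, coefs, _ = enet_path(Xtr - xm, ytr - ym, l1_ratio=alpha,
                                    alphas=grid, tol=1e-4, max_iter=10_000)
        pred = (Xs[val] - xm) @ coefs + ym  # (n_val, n_lambda)
        fold_mse[k] = np.mean((pred - y[val, None]) ** 2, axis=0)
    used = ~np.isnan(fold_mse).all(axis=1)
    mean_mse = np.nanmean(fold_mse[used], axis=0)
    se_mse = np.nanstd(fold_mse[used], axis=0, ddof=1) / math.sqrt(used.sum())

    i_min = int(np.argmin(mean_mse))  # ties -> first, i.e. larger lambda
    if cv.selection == "1se":
        bound = mean_mse[i_min] + se_mse[i_min]
        i_sel = int(np.flatnonzero(mean_mse <= bound)[0])
    else:
        i_sel = i_min
    lam = float(grid[i_sel])

    w0_s, w_s = elastic_net_fit(Xs, y, alpha, lam, tol=1e-12)
    w_raw = w_s / sigma
    intercept = float(w0_s - float(mu @ w_raw))
    weights = {p: float(w) for p, w in zip(probes, w_raw) if w != 0.0}
    log.info("clock: lambda %g (%s rule), %d of %d probes selected",
             lam, cv.selection, len(weights), len(probes))

    meta = {
        "alpha": float(alpha),
        "lambda_": lam,
        "selection": cv.selection,
        "n_folds": int(cv.n_folds),
        "seed": int(cv.seed),
        "cv_mse_at_lambda": float(mean_mse[i_sel]),
        "screening_threshold": screening_threshold,
        "n_candidate_probes": len(probes),
        "n_training_samples": n,
        "passage_range": [int(y.min()), int(y.max())],
    }
    return ClockModel(intercept=intercept, weights=weights, training_meta=meta)


def predict_passage(model: ClockModel, beta: BetaMatrix,
                    sheet: SampleSheet | None = None) -> list:
    """Score samples with a clock: ``p_hat = w0 + sum_j w_j beta_j``.

    Every clock probe must be present and non-missing in ``beta`` for
    every sample — absent probes are a hard error, never imputed.
    """
    probes = list(model.weights)
    present = set(beta.probe_ids)
    absent = [p for p in probes if p not in present]
    if absent:
        raise MissingProbeError(absent)
    sub = beta.select_probes(probes)
    if np.isnan(sub.values).any():
        bad = {sub.probe_ids[i] for i in np.flatnonzero(np.isnan(sub.values).any(axis=1))}
        raise MissingProbeError(bad)
    w = np.array([model.weights[p] for p in probes])
    yhat = model.intercept + w @ sub.values
    actual = {}
    if sheet is not None:
        actual = dict(zip(sheet.frame["sample_id"], sheet.frame["passage"]))
    return [
        PredictionResult(s, float(yhat[j]),
                         int(actual[s]) if s in actual else None)
        for j, s in enumerate(beta.sample_ids)
    ]


def evaluate(predictions) -> EvalMetrics:
    """RMSE and Spearman rank correlation of predicted vs actual passage
    over predictions that carry an actual passage (needs >= 3)."""
    pairs = [(p.predicted_passage, p.actual_passage) for p in predictions
             if p.actual_passage is not None]
    if len(pairs) < 3:
        raise DesignError(f"need >= 3 predictions with actual passage, got {len(pairs)}")
    yhat = np.array([a for a, _ in pairs])
    y = np.array([b for _, b in pairs], dtype=float)
    rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
    if np.ptp(yhat) == 0 or np.ptp(y) == 0:
        return EvalMetrics(rmse, float("nan"), float("nan"), len(pairs),
                           spearman_defined=False)
    rho, pval = stats.spearmanr(yhat, y)
    pval = max(float(pval), 5e-324)  # keep p in (0, 1]
    return EvalMetrics(rmse, float(rho), pval, len(pairs))


@dataclass(frozen=True)
class CohortComparison:
    """Per-level deceleration readout comparing a treated and a control
    cohort. ``table`` has one row per shared level (passage or
    cumulative-PD bin) with cohort means of delta, counts and the
    effect (treated minus control); ``overall_effect`` averages the
    per-level effects, with ``overall_se`` from per-sample deltas.
    Negative effect = deceleration."""

    treatment_label: str
    control_label: str
    x_axis: str
    table: pd.DataFrame
    overall_effect: float
    overall_se: float


def compute_acceleration(predictions, sheet: SampleSheet, treatment_label: str,
                         control_label: str, x_axis: str = "passage",
                         n_bins: int = 5) -> CohortComparison:
    """Compare delta = predicted - actual passage between cohorts.

    Deltas are grouped by passage level (or, with
    ``x_axis="cumulative_pd"``, by equal-width cumulative-PD bins) and
    averaged per cohort; the effect at each level is the treated mean
    minus the control mean, reported only where both cohorts have at
    least one sample.
    """
    if x_axis not in ("passage", "cumulative_pd"):
        raise ConfigError(f"unknown x_axis {x_axis!r}")
    sf = sheet.frame
    for label in (treatment_label, control_label):
        if not (sf["treatment"] == label).any():
            raise LabelError(f"treatment label {label!r} absent from sample sheet")
    deltas = {p.sample_id: p.delta for p in predictions if p.delta is not None}
    rows = sf[sf["treatment"].isin([treatment_label, control_label])
              & sf["sample_id"].isin(deltas)].copy()
    if rows.empty:
        raise DesignError("no predictions with delta for the requested cohorts")
    rows["delta"] = rows["sample_id"].map(deltas)
    if x_axis == "passage":
        rows["level"] = rows["passage"]
    else:
        cpd = rows["cumulative_pd"]
        if cpd.isna().any():
            raise DesignError("cumulative_pd missing for some samples")
        edges = np.linspace(cpd.min(), cpd.max(), n_bins + 1)
        edges[-1] = np.nextafter(edges[-1], np.inf)
        idx = np.clip(np.digitize(cpd, edges) - 1, 0, n_bins - 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rows["level"] = centers[idx]

    records = []
    for level, grp in rows.groupby("level", sort=True):
        t = grp.loc[grp["treatment"] == treatment_label, "delta"]
        c = grp.loc[grp["treatment"] == control_label, "delta"]
        if len(t) == 0 or len(c) == 0:
            continue
        records.append({
            "level": level,
            "n_treatment": len(t), "n_control": len(c),
            "mean_delta_treatment": float(t.mean()),
            "mean_delta_control": float(c.mean()),
            "effect": float(t.mean() - c.mean()),
        })
    if not records:
        raise DesignError("no level has samples from both cohorts")
    table = pd.DataFrame.from_records(records)
    overall = float(table["effect"].mean())
    td = rows.loc[rows["treatment"] == treatment_label, "delta"].to_numpy()
    cd = rows.loc[rows["treatment"] == control_label, "delta"].to_numpy()
    se = float(np.sqrt(
        (td.var(ddof=1) / td.size if td.size > 1 else 0.0)
        + (cd.var(ddof=1) / cd.size if cd.size > 1 else 0.0)))
    return CohortComparison(treatment_label, control_label, x_axis, table,
                            overall, se)
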