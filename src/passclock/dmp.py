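"""Per-CpG screening of methylation drift against cell passage.

Each probe's beta values are regressed on passage with ordinary least
squares (``beta ~ a + b * passage``); the slope's two-sided t-test
(n - 2 degrees of freedom) provides the screening p-value. Probes
passing a stringent threshold (default 1e-11) become the candidate set
for the elastic-net clock. The threshold itself can be selected by
leave-one-out validation of downstream passage-prediction error.

The single-covariate t-test on the slope yields p-values identical to
the F-test of the one-covariate linear model used by standard
differential-methylation position finders.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DesignError, ConfigError
from .io import BetaMatrix, SampleSheet

log = logging.getLogger(__name__)

__all__ = [
    "DmpResult",
    "ScreenConfig",
    "fit_passage_regression",
    "screen_dmps",
    "select_threshold_loo",
    "ThresholdSelection",
]

#: Residual RMS (in beta units) below which a fit is treated as exact.
PERFECT_FIT_TOL = 1e-12


@dataclass(frozen=True)
class DmpResult:
    """OLS summary for one probe: slope (delta-beta per passage),
    intercept (beta at passage 0), t statistic, two-sided p-value and
    drift direction. Perfect (zero-residual) fits carry ``t_stat=inf``
    and ``p_value=0`` sentinels."""

    probe_id: str
    slope: float
    intercept: float
    t_stat: float
    p_value: float
    direction: str
    perfect_fit: bool = False

    def __post_init__(self):
        object.__setattr__(self, "direction", "hypo" if self.slope < 0 else "hyper")


@dataclass(frozen=True)
class ScreenConfig:
    """Screening parameters: significance threshold ``threshold`` (tau),
    the candidate grid used for leave-one-out selection (sorted
    descending), and the minimum sample count for the per-probe fit."""

    threshold: float = 1e-11
    candidate_grid: tuple = (1e-5, 1e-7, 1e-9, 1e-11, 1e-13)
    min_samples: int = 3

    def __post_init__(self):
        if not (0.0 < self.threshold <= 1.0):
            raise ConfigError(f"threshold {self.threshold} outside (0, 1]")
        grid = tuple(float(g) for g in self.candidate_grid)
        if list(grid) != sorted(grid, reverse=True):
            raise ConfigError("candidate_grid must be sorted descending")
        object.__setattr__(self, "candidate_grid", grid)
        if self.min_samples < 3:
            raise ConfigError("min_samples must be >= 3")


def _ols_stats(Y: np.ndarray, p: np.ndarray):
    """Vectorised OLS of each row of ``Y`` on ``p``.

    Returns (slope, intercept, t, pval, perfect) arrays. Closed-form
    normal equations; the t statistic uses n - 2 degrees of freedom.
    """
    n = p.size
    if n < 3:
        raise DesignError(f"need >= 3 samples, got {n}")
    pbar = p.mean()
    dev = p - pbar
    sxx = float(dev @ dev)
    if sxx == 0.0:
        raise DesignError("all passages identical: slope not identifiable")
    ybar = Y.mean(axis=1)
    sxy = Y @ dev
    slope = sxy / sxx
    intercept = ybar - slope * pbar
    resid = Y - intercept[:, None] - slope[:, None] * p[None, :]
    rss = np.einsum("ij,ij->i", resid, resid)
    exact = rss <= n * PERFECT_FIT_TOL**2
    flat = slope == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / (n - 2) / sxx)
        t = slope / se
    # exact nonzero-slope fit: t = +/-inf sentinel, p = 0;
    # constant probe (exact fit, zero slope): no drift evidence, t = 0, p = 1
    t = np.where(exact, np.where(flat, 0.0, np.inf * np.sign(slope + flat)), t)
    with np.errstate(invalid="ignore"):
        pval = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pval = np.where(exact, np.where(flat, 1.0, 0.0), pval)
    perfect = exact & ~flat
    return slope, intercept, t, pval, perfect


def fit_passage_regression(betas, passages) -> DmpResult:
    """OLS of one probe's beta values on passage; see module docstring."""
    y = np.asarray(betas, dtype=float)
    p = np.asarray(passages, dtype=float)
    if y.shape != p.shape:
        raise DesignError("betas and passages differ in length")
    slope, intercept, t, pval, perfect = _ols_stats(y[None, :], p)
    return DmpResult("", float(slope[0]), float(intercept[0]), float(t[0]),
                     float(pval[0]), "", bool(perfect[0]))


def screen_dmps(beta: BetaMatrix, sheet: SampleSheet,
                config: ScreenConfig = ScreenConfig()) -> list:
    """Regress every probe on passage and return those with
    ``p < threshold``, sorted by p-value then probe ID.

    Requires a complete matrix (no missing values) and a passage for
    every sample. The result is invariant to probe and sample order.
    """
    if np.isnan(beta.values).any():
        raise DesignError("beta matrix contains missing values; run "
                          "drop_incomplete_probes first")
    p = sheet.passages_for(beta.sample_ids)
    if p.size < config.min_samples:
        raise DesignError(f"need >= {config.min_samples} samples, got {p.size}")
    slope, intercept, t, pval, perfect = _ols_stats(beta.values, p)
    hits = np.flatnonzero(pval < config.threshold)
    results = [
        DmpResult(beta.probe_ids[i], float(slope[i]), float(intercept[i]),
                  float(t[i]), float(pval[i]), "", bool(perfect[i]))
        for i in hits
    ]
    results.sort(key=lambda r: (r.p_value, r.probe_id))
    n_hypo = sum(1 for r in results if r.direction == "hypo")
    log.info("screen: %d of %d probes pass p < %g (%d hypo / %d hyper)",
             len(results), beta.n_probes, config.threshold,
             n_hypo, len(results) - n_hypo)
    return results


@dataclass(frozen=True)
class ThresholdSelection:
    """Outcome of leave-one-out threshold selection: the chosen tau and
    the per-candidate LOO RMSE table (infeasible candidates are inf)."""

    threshold: float
    loo_rmse: dict


def select_threshold_loo(beta: BetaMatrix, sheet: SampleSheet, grid=None,
                         alpha: float = 0.5, cv=None) -> ThresholdSelection:
    """Choose the screening threshold by leave-one-out validation.

    For each candidate tau and each held-out sample, probes are screened
    and the clock refit on the remaining samples, then the held-out
    passage is predicted. The tau minimising LOO RMSE wins; ties break
    toward the most stringent (smallest) tau. A tau that yields zero
    screened probes in any fold is infeasible (RMSE = inf).
    """
    from .clock import CvSpec, fit_clock, predict_passage

    grid = tuple(ScreenConfig(candidate_grid=grid).candidate_grid) if grid \
        else ScreenConfig().candidate_grid
    cv = cv or CvSpec()
    sample_ids = list(beta.sample_ids)
    n = len(sample_ids)
    if n < 5:
        raise DesignError(f"leave-one-out selection needs >= 5 samples, got {n}")
    passages = sheet.passages_for(sample_ids)
    loo_rmse = {}
    for tau in grid:
        sq_errs = []
        feasible = True
        for i, held in enumerate(sample_ids):
            rest = [s for s in sample_ids if s != held]
            beta_tr = beta.select_samples(rest)
            hits = screen_dmps(beta_tr, sheet, ScreenConfig(threshold=tau))
            if not hits:
                feasible = False
                break
            probes = [r.probe_id for r in hits]
            folds = min(cv.n_folds, n - 1)
            model = fit_clock(beta_tr.select_probes(probes), sheet, alpha=alpha,
                              cv=CvSpec(n_folds=folds, lambda_grid=cv.lambda_grid,
                                        n_lambda=cv.n_lambda,
                                        lambda_min_ratio=cv.lambda_min_ratio,
                                        selection=cv.selection, seed=cv.seed))
            pred = predict_passage(model, beta.select_samples([held]))[0]
            sq_errs.append((pred.predicted_passage - passages[i]) ** 2)
        loo_rmse[tau] = math.sqrt(float(np.mean(sq_errs))) if feasible else math.inf
        log.info("LOO threshold %g: RMSE %s", tau, loo_rmse[tau])
    # smallest tau among minimisers (grid is descending, so scan reversed)
    best = min(reversed(grid), key=lambda tau: loo_rmse[tau])
    if math.isinf(loo_rmse[best]):
        raise DesignError("every candidate threshold was infeasible")
    return ThresholdSelection(best, loo_rmse)
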