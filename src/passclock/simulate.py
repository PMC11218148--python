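"""Seeded simulator of serially passaged methylome cohorts.

The generator emulates the study design used to build a
passage-prediction clock from cultured primary fibroblasts:

* a large static background of CpGs whose methylation fraction is drawn
  from a bimodal mixture (unmethylated mode near 0.1, methylated mode
  near 0.9) and does not change with passage;
* a small set of drifting CpGs whose mean moves linearly with passage —
  hypomethylating probes start in the methylated regime and drift down,
  hypermethylating probes start low and drift up — calibrated so the
  mean absolute change over ten passages equals ``drift_total``
  (default 0.2);
* beta-distributed observation noise with precision ``kappa``
  (``beta ~ Beta(mu*kappa, (1-mu)*kappa)``), which keeps draws inside
  [0, 1] without clipping artefacts; kappa = 200 gives an SD of about
  0.035 at beta = 0.5, comparable to array replicate noise;
* treatment cohorts whose epigenetic drift is *decelerated* via an
  effective-passage compression, and immortalisation cohorts whose
  drift continues at a reduced residual rate after a breakpoint.

Effective passage for a cohort with deceleration ``d`` from onset
``p0``:  ``p_eff = p0 + (p - p0) * (1 - d)`` for ``p >= p0``; an
immortalisation breakpoint ``m`` with residual drift ``r`` further maps
``p_eff -> m + (p_eff - m) * r`` beyond ``m``. Drifting probe means are
``clip(m_j + s_j * (p_eff - 10), 0.01, 0.99)``.

Identical config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import BetaMatrix, SampleSheet

log = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_immortalised",
    "default_config",
    "deceleration_config",
    "immortalised_config",
    "TRAIN_SCHEDULE",
    "TEST_SCHEDULE",
]

#: Training design: 39 samples, six at each of P10/12/14 and seven at
#: each of P16/18/20.
TRAIN_SCHEDULE = ((10, 6), (12, 6), (14, 6), (16, 7), (18, 7), (20, 7))

#: Held-out design: 26 samples spread over P9-P20, weighted toward the
#: late passages where drug effects are read out.
TEST_SCHEDULE = ((9, 1), (10, 2), (11, 2), (12, 1), (13, 2), (14, 2),
                 (15, 2), (16, 6), (18, 4), (20, 4))

#: Drug arms are profiled at the late passages only.
TREATMENT_SCHEDULE = ((16, 6), (18, 6), (20, 6))

#: Immortalised arm spans the full passage range.
IMMORTALISED_SCHEDULE = ((10, 3), (12, 3), (14, 3), (16, 3), (18, 3), (20, 3))


@dataclass(frozen=True)
class CohortSpec:
    """One cohort: label, sampling schedule ((passage, n), ...), and its
    ageing-trajectory modifiers."""

    label: str
    schedule: tuple = TRAIN_SCHEDULE
    deceleration: float = 0.0
    onset_passage: int = 9
    immortalisation_passage: int | None = None
    residual_drift: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "schedule",
                           tuple((int(p), int(n)) for p, n in self.schedule))
        if not (0.0 <= self.deceleration <= 1.0):
            raise ConfigError(f"deceleration {self.deceleration} outside [0, 1]")
        if not (0.0 <= self.residual_drift <= 1.0):
            raise ConfigError(f"residual_drift {self.residual_drift} outside [0, 1]")
        if self.immortalisation_passage is not None:
            passages = [p for p, _ in self.schedule]
            if not (min(passages) <= self.immortalisation_passage <= max(passages)):
                raise ConfigError("immortalisation passage outside schedule range")

    def effective_passage(self, p: float) -> float:
        pe = float(p)
        if self.deceleration > 0 and pe > self.onset_passage:
            pe = self.onset_passage + (pe - self.onset_passage) * (1 - self.deceleration)
        m = self.immortalisation_passage
        if m is not None and pe > m:
            pe = m + (pe - m) * self.residual_drift
        return pe


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults reproduce the study design (39
    training + 26 test samples, 10,000 probes, 60 drifting CpGs with
    mean |delta-beta| of 0.2 over ten passages, kappa = 200)."""

    n_probes: int = 10_000
    n_hypo: int = 23
    n_hyper: int = 19
    n_extra_drifters: int = 18
    drift_total: float = 0.2
    noise_precision: float = 200.0
    slope_jitter: float = 0.2
    background_low: tuple = (5.0, 45.0)    # Beta(a,b): mode near 0.1
    background_high: tuple = (45.0, 5.0)   # mode near 0.9
    background_weight_low: float = 0.5
    hypo_baseline_range: tuple = (0.60, 0.85)
    hyper_baseline_range: tuple = (0.15, 0.40)
    cohort_baseline_sd: float = 0.0        # donor/cell-type offsets, off by default
    pd_per_passage: float = 2.5            # fills cumulative_pd deterministically
    cohorts: tuple = (CohortSpec("train", TRAIN_SCHEDULE),
                      CohortSpec("test", TEST_SCHEDULE))
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "cohorts", tuple(self.cohorts))
        n_drift = self.n_hypo + self.n_hyper + self.n_extra_drifters
        if n_drift > self.n_probes:
            raise ConfigError("more drifting CpGs than probes")
        if self.drift_total < 0 or self.noise_precision <= 0:
            raise ConfigError("drift_total must be >= 0 and noise_precision > 0")
        labels = [c.label for c in self.cohorts]
        if len(set(labels)) != len(labels):
            raise ConfigError("cohort labels must be unique")

    @property
    def n_drifters(self) -> int:
        return self.n_hypo + self.n_hyper + self.n_extra_drifters


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated data set: the drifting probes with
    their slopes/directions, each cohort's trajectory modifiers, and
    the seed."""

    drifters: pd.DataFrame          # probe_id, slope, direction, baseline
    cohorts: dict                   # label -> CohortSpec
    seed: int

    @property
    def drifting_probe_ids(self) -> tuple:
        return tuple(self.drifters["probe_id"])

    def effective_passage(self, label: str, p: float) -> float:
        return self.cohorts[label].effective_passage(p)


def _probe_ids(n: int) -> tuple:
    return tuple(f"cg{i:08d}" for i in range(n))


def generate_cohort(config: SyntheticConfig):
    """Generate (BetaMatrix, SampleSheet, SyntheticTruth) for all
    cohorts in ``config``, sharing one probe panel and drift truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    probe_ids = _probe_ids(n)

    # background baselines from the bimodal mixture
    low = rng.beta(*config.background_low, size=n)
    high = rng.beta(*config.background_high, size=n)
    is_low = rng.random(n) < config.background_weight_low
    baseline = np.where(is_low, low, high)

    # drifting probes: positions, directions, baselines, slopes
    drift_idx = np.sort(rng.choice(n, size=config.n_drifters, replace=False))
    signs = np.concatenate([
        -np.ones(config.n_hypo),
        np.ones(config.n_hyper),
        rng.choice([-1.0, 1.0], size=config.n_extra_drifters),
    ])
    rng.shuffle(signs)
    hypo = signs < 0
    b = np.empty(config.n_drifters)
    b[hypo] = rng.uniform(*config.hypo_baseline_range, size=int(hypo.sum()))
    b[~hypo] = rng.uniform(*config.hyper_baseline_range, size=int((~hypo).sum()))
    baseline[drift_idx] = b
    unit = config.drift_total / 10.0
    jitter = rng.uniform(1 - config.slope_jitter, 1 + config.slope_jitter,
                         size=config.n_drifters)
    slopes_d = signs * unit * jitter
    slopes = np.zeros(n)
    slopes[drift_idx] = slopes_d

    # clipping sanity: drifter means pinned at the bounds for any
    # scheduled passage indicate an incompatible drift_total
    all_pe = sorted({c.effective_passage(p) for c in config.cohorts
                     for p, _ in c.schedule})
    if all_pe and config.n_drifters:
        mus = baseline[drift_idx, None] + slopes_d[:, None] * (
            np.asarray(all_pe)[None, :] - 10.0)
        pinned = ((mus <= 0.01) | (mus >= 0.99)).any(axis=1)
        if pinned.mean() > 0.10:
            log.warning("drift_total %g pins %.0f%% of drifting CpGs at the "
                        "[0.01, 0.99] bounds", config.drift_total,
                        100 * pinned.mean())

    kappa = config.noise_precision
    sample_ids, rows, cols = [], [], []
    for cohort in config.cohorts:
        offset = (rng.normal(0.0, config.cohort_baseline_sd, size=n)
                  if config.cohort_baseline_sd > 0 else 0.0)
        for p, count in cohort.schedule:
            pe = cohort.effective_passage(p)
            mu = np.clip(baseline + offset + slopes * (pe - 10.0), 0.01, 0.99)
            for k in range(count):
                sid = f"{cohort.label}_P{p:02d}_{k:02d}"
                sample_ids.append(sid)
                cols.append(rng.beta(mu * kappa, (1 - mu) * kappa))
                rows.append({
                    "sample_id": sid,
                    "passage": p,
                    "cell_type": "HMF",
                    "donor_id": f"donor_{cohort.label}",
                    "treatment": cohort.label,
                    "dose": "",
                    "cumulative_pd": config.pd_per_passage * (p - 8),
                })

    beta = BetaMatrix(probe_ids, tuple(sample_ids),
                      np.column_stack(cols) if cols else np.empty((n, 0)))
    sheet = SampleSheet(pd.DataFrame(rows))
    truth = SyntheticTruth(
        drifters=pd.DataFrame({
            "probe_id": [probe_ids[i] for i in drift_idx],
            "slope": slopes_d,
            "direction": np.where(hypo, "hypo", "hyper"),
            "baseline": b,
        }),
        cohorts={c.label: c for c in config.cohorts},
        seed=config.seed,
    )
    return beta, sheet, truth


def generate_immortalised(config: SyntheticConfig | None = None,
                          immortalisation_passage: int = 12,
                          residual_drift: float = 0.4,
                          label: str = "immortalised"):
    """Add an immortalised cohort (drift slowed to ``residual_drift``
    of its rate beyond the breakpoint passage) to ``config`` and
    generate. ``residual_drift=1`` reproduces a control trajectory;
    ``0`` freezes drift at the breakpoint."""
    cfg = config or default_config()
    arm = CohortSpec(label, IMMORTALISED_SCHEDULE,
                     immortalisation_passage=immortalisation_passage,
                     residual_drift=residual_drift)
    return generate_cohort(replace(cfg, cohorts=cfg.cohorts + (arm,)))


# ---------------------------------------------------------------------------
# scenario helpers
# ---------------------------------------------------------------------------

def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default two-cohort (train/test) study design."""
    return SyntheticConfig(seed=seed, **overrides)


def deceleration_config(deceleration: float = 0.3, onset_passage: int = 9,
                        seed: int = 0, label: str = "drug",
                        **overrides) -> SyntheticConfig:
    """Train + vehicle + treated arms; the treated arm's drift is
    compressed by ``deceleration`` from ``onset_passage`` onward."""
    cohorts = (
        CohortSpec("train", TRAIN_SCHEDULE),
        CohortSpec("vehicle", TREATMENT_SCHEDULE),
        CohortSpec(label, TREATMENT_SCHEDULE, deceleration=deceleration,
                   onset_passage=onset_passage),
    )
    return SyntheticConfig(seed=seed, cohorts=cohorts, **overrides)


def immortalised_config(immortalisation_passage: int = 12,
                        residual_drift: float = 0.4, seed: int = 0,
                        **overrides) -> SyntheticConfig:
    """Train cohort plus an immortalised arm."""
    cohorts = (
        CohortSpec("train", TRAIN_SCHEDULE),
        CohortSpec("immortalised", IMMORTALISED_SCHEDULE,
                   immortalisation_passage=immortalisation_passage,
                   residual_drift=residual_drift),
    )
    return SyntheticConfig(seed=seed, cohorts=cohorts, **overrides)
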