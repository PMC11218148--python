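"""End-to-end orchestration of the two workflows: clock building and
compound screening.

``run_build_clock`` chains preprocessing, (optional) leave-one-out
threshold selection, probe screening, elastic-net fitting and held-out
evaluation; ``run_screen_compound`` scores treated and control cohorts
with a trained clock, computes the per-passage deceleration readout,
optionally scores a senescence-marker panel with robust Z, and issues a
per-compound verdict.

Every run writes its resolved configuration (defaults applied) next to
the outputs so it can be reproduced exactly; a single global seed fans
out to per-stage seeds through counter-keyed seed sequences.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigError, LabelError
from .io import (BetaMatrix, ClockModel, EvalMetrics, SampleSheet,
                 predictions_to_frame, read_beta_matrix, read_clock_model,
                 read_sample_sheet, write_clock_model)
from .preprocess import (drop_incomplete_probes, filter_by_detection,
                         read_blocklist, read_detection_p, remove_blocklist)
from .dmp import ScreenConfig, screen_dmps, select_threshold_loo
from .clock import (CohortComparison, CvSpec, compute_acceleration, evaluate,
                    fit_clock, predict_passage)
from .metrics import DEFAULT_POLARITY, MarkerMeasurements, robust_z

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "BuildResult", "ScreenResult", "run_build_clock",
           "run_screen_compound", "derive_seed"]


def derive_seed(seed: int, stage: int) -> int:
    """Per-stage seed derived from the global seed by a counter key, so
    stages can be re-run in isolation (always < 2**31)."""
    return int(np.random.SeedSequence([int(seed), int(stage)])
               .generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Resolved pipeline configuration (all defaults applied)."""

    seed: int = 0
    out_dir: str = "passclock_run"
    log_level: str = "INFO"
    # input file paths; beta/sheet may instead come from `simulate`
    beta: str | None = None
    sheet: str | None = None
    detp: str | None = None
    blocklist: str | None = None
    clock_file: str | None = None
    panel: str | None = None
    # simulate: keyword overrides for simulate.default_config (or a
    # scenario name under key "scenario": default|deceleration|immortalised)
    simulate: dict | None = None
    # stage parameters
    detection_cutoff: float = 0.01
    detection_rule: str = "any-sample"
    threshold: float = 1e-11
    select_loo: bool = False
    loo_grid: tuple | None = None
    alpha: float = 0.5
    n_folds: int = 10
    selection: str = "min"
    train_label: str = "train"
    test_label: str | None = "test"
    treatment_labels: tuple = ()
    control_label: str = "vehicle"
    x_axis: str = "passage"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["passclock_version"] = __version__
        for key, val in doc.items():
            if isinstance(val, tuple):
                doc[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def _load_inputs(cfg: RunConfig):
    """Load or simulate the beta matrix and sample sheet."""
    if cfg.simulate is not None:
        from . import simulate as sim

        opts = dict(cfg.simulate)
        scenario = opts.pop("scenario", "default")
        opts.setdefault("seed", derive_seed(cfg.seed, 0))
        maker = {"default": sim.default_config,
                 "deceleration": sim.deceleration_config,
                 "immortalised": sim.immortalised_config}.get(scenario)
        if maker is None:
            raise ConfigError(f"unknown simulate scenario {scenario!r}")
        beta, sheet, truth = sim.generate_cohort(maker(**opts))
        return beta, sheet, truth
    if not cfg.beta or not cfg.sheet:
        raise ConfigError("config must provide beta+sheet paths or a "
                          "simulate block")
    for path in (cfg.beta, cfg.sheet, cfg.detp, cfg.blocklist,
                 cfg.clock_file, cfg.panel):
        if path and not os.path.exists(path):
            raise ConfigError(f"input file does not exist: {path}")
    return read_beta_matrix(cfg.beta), read_sample_sheet(cfg.sheet), None


def _preprocess(cfg: RunConfig, beta: BetaMatrix, report: list) -> BetaMatrix:
    n0 = beta.n_probes
    if cfg.detp:
        beta = filter_by_detection(beta, read_detection_p(cfg.detp),
                                   cfg.detection_cutoff, cfg.detection_rule)
        report.append(f"detection filter: {n0} -> {beta.n_probes} probes")
    if cfg.blocklist:
        n1 = beta.n_probes
        beta = remove_blocklist(beta, read_blocklist(cfg.blocklist))
        report.append(f"blocklist: {n1} -> {beta.n_probes} probes")
    n2 = beta.n_probes
    beta = drop_incomplete_probes(beta)
    if beta.n_probes != n2:
        report.append(f"missing-value filter: {n2} -> {beta.n_probes} probes")
    return beta


@dataclass
class BuildResult:
    model: ClockModel
    metrics: EvalMetrics | None
    threshold: float
    dmps: list
    report: str


def run_build_clock(cfg: RunConfig) -> BuildResult:
    """Preprocess -> (optional) LOO threshold selection -> screen ->
    fit -> held-out evaluation; writes clock.json, metrics.tsv,
    report.txt and the resolved config into ``cfg.out_dir``."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    report = [f"passclock {__version__} build-clock (seed {cfg.seed})"]
    beta, sheet, _truth = _load_inputs(cfg)
    beta = _preprocess(cfg, beta, report)

    train_ids = [s for s in beta.sample_ids
                 if sheet.treatment_of(s) == cfg.train_label]
    if not train_ids:
        raise LabelError(f"no samples with treatment {cfg.train_label!r}")
    beta_tr = beta.select_samples(train_ids)
    cv = CvSpec(n_folds=cfg.n_folds, selection=cfg.selection,
                seed=derive_seed(cfg.seed, 1))

    threshold = cfg.threshold
    if cfg.select_loo:
        sel = select_threshold_loo(beta_tr, sheet, grid=cfg.loo_grid,
                                   alpha=cfg.alpha, cv=cv)
        threshold = sel.threshold
        report.append("LOO threshold selection: "
                      + ", ".join(f"tau={t:g} RMSE={r:.3f}"
                                  for t, r in sel.loo_rmse.items()))
    dmps = screen_dmps(beta_tr, sheet, ScreenConfig(threshold=threshold))
    n_hypo = sum(1 for r in dmps if r.direction == "hypo")
    report.append(f"screen at tau={threshold:g}: {len(dmps)} CpGs "
                  f"({n_hypo} hypo / {len(dmps) - n_hypo} hyper)")
    if not dmps:
        raise ConfigError(f"no probes pass the screening threshold {threshold:g}")

    model = fit_clock(beta_tr.select_probes([r.probe_id for r in dmps]), sheet,
                      alpha=cfg.alpha, cv=cv, screening_threshold=threshold)
    report.append(f"clock: {len(model.weights)} CpGs, lambda "
                  f"{model.training_meta['lambda_']:g} "
                  f"({cfg.selection} rule, {cfg.n_folds} folds)")

    metrics = None
    if cfg.test_label:
        test_ids = [s for s in beta.sample_ids
                    if sheet.treatment_of(s) == cfg.test_label]
        if test_ids:
            preds = predict_passage(model, beta.select_samples(test_ids), sheet)
            metrics = evaluate(preds)
            report.append(f"held-out evaluation (n={metrics.n}): RMSE "
                          f"{metrics.rmse:.3f}, Spearman rho "
                          f"{metrics.spearman_rho:.3f}")
            predictions_to_frame(preds).to_csv(
                os.path.join(cfg.out_dir, "test_predictions.tsv"),
                sep="\t", index=False)

    write_clock_model(model, os.path.join(cfg.out_dir, "clock.json"))
    if metrics is not None:
        pd.DataFrame([dataclasses.asdict(metrics)]).to_csv(
            os.path.join(cfg.out_dir, "metrics.tsv"), sep="\t", index=False)
    cfg.to_yaml(os.path.join(cfg.out_dir, "resolved_config.yaml"))
    text = "\n".join(report) + "\n"
    with open(os.path.join(cfg.out_dir, "report.txt"), "w") as fh:
        fh.write(text)
    log.info("%s", text)
    return BuildResult(model, metrics, threshold, dmps, text)


@dataclass
class ScreenResult:
    comparisons: dict        # treatment label -> CohortComparison
    verdicts: dict           # treatment label -> str
    marker_calls: pd.DataFrame | None
    report: str


def _verdict(comp: CohortComparison) -> str:
    """Two-standard-error call on the overall effect: clearly negative
    = decelerated, clearly positive = accelerated, else no effect."""
    if comp.overall_se > 0 and comp.overall_effect < -2 * comp.overall_se:
        return "decelerated"
    if comp.overall_se > 0 and comp.overall_effect > 2 * comp.overall_se:
        return "accelerated"
    return "no effect"


def run_screen_compound(cfg: RunConfig, model: ClockModel | None = None) -> ScreenResult:
    """Score treated/control cohorts with a trained clock and report a
    per-compound verdict; optionally score a marker panel."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    report = [f"passclock {__version__} screen-compound (seed {cfg.seed})"]
    beta, sheet, _truth = _load_inputs(cfg)
    beta = _preprocess(cfg, beta, report)
    if model is None:
        if not cfg.clock_file:
            raise ConfigError("screen-compound requires a trained clock "
                              "(clock_file) or an in-memory model")
        model = read_clock_model(cfg.clock_file)

    present = set(sheet.frame["treatment"].dropna())
    labels = tuple(cfg.treatment_labels) or tuple(
        sorted(present - {cfg.control_label, cfg.train_label}))
    missing = [l for l in (*labels, cfg.control_label) if l not in present]
    if missing:
        raise LabelError(f"labels absent from sample sheet: {missing}")

    preds = predict_passage(model, beta, sheet)
    predictions_to_frame(preds).to_csv(
        os.path.join(cfg.out_dir, "predictions.tsv"), sep="\t", index=False)

    comparisons, verdicts = {}, {}
    for label in labels:
        comp = compute_acceleration(preds, sheet, label, cfg.control_label,
                                    x_axis=cfg.x_axis)
        comparisons[label] = comp
        verdicts[label] = _verdict(comp)
        per_level = "; ".join(f"{r.level:g}: {r.effect:+.2f}"
                              for r in comp.table.itertuples())
        report.append(f"{label} vs {cfg.control_label}: overall effect "
                      f"{comp.overall_effect:+.3f} (SE {comp.overall_se:.3f})"
                      f" -> {verdicts[label]} [{per_level}]")
        comp.table.assign(treatment=label).to_csv(
            os.path.join(cfg.out_dir, f"effect_{label}.tsv"),
            sep="\t", index=False)

    marker_calls = None
    if cfg.panel:
        panel = pd.read_csv(cfg.panel)
        calls = []
        for (marker, treat), grp in panel[panel["cohort"] != cfg.control_label] \
                .groupby(["marker", "cohort"], sort=True):
            ctrl = panel.loc[(panel["marker"] == marker)
                             & (panel["cohort"] == cfg.control_label), "value"]
            polarity = (grp["polarity"].iloc[0] if "polarity" in grp
                        else DEFAULT_POLARITY.get(marker))
            mm = MarkerMeasurements(marker, polarity, tuple(ctrl),
                                    tuple(grp["value"]))
            for res in robust_z(mm):
                calls.append({"marker": marker, "cohort": treat,
                              "value": res.value, "z": res.z, "call": res.call})
        marker_calls = pd.DataFrame(calls)
        marker_calls.to_csv(os.path.join(cfg.out_dir, "marker_calls.tsv"),
                            sep="\t", index=False)
        report.append(f"marker panel: {len(marker_calls)} calls "
                      f"({(marker_calls['call'] == 'proliferative').sum()} "
                      f"proliferative, {(marker_calls['call'] == 'senescent').sum()}"
                      " senescent)")

    cfg.to_yaml(os.path.join(cfg.out_dir, "resolved_config.yaml"))
    text = "\n".join(report) + "\n"
    with open(os.path.join(cfg.out_dir, "report.txt"), "w") as fh:
        fh.write(text)
    log.info("%s", text)
    return ScreenResult(comparisons, verdicts, marker_calls, text)
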