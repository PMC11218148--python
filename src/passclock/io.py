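"""Core containers and plain-text readers/writers.

The toolkit revolves around three portable artefacts:

* a **beta matrix** — CpG probes (rows) by samples (columns), holding
  methylation fractions ``beta`` in [0, 1], tab-separated on disk;
* a **sample sheet** — per-sample passage number and cohort labels,
  comma-separated on disk;
* a **clock model** — intercept plus a sparse map of CpG weights,
  stored as a versioned JSON document.

All writers format floats with 17 significant digits so that a
write/read cycle reproduces the exact IEEE-754 bit patterns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, RangeError

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "ClockModel",
    "PredictionResult",
    "EvalMetrics",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_clock_model",
    "write_clock_model",
    "predictions_to_frame",
]

CLOCK_SCHEMA_VERSION = 1

#: Float format that round-trips IEEE-754 doubles exactly.
_FLOAT_FMT = "%.17g"

_SHEET_COLUMNS = (
    "sample_id",
    "passage",
    "cell_type",
    "donor_id",
    "treatment",
    "dose",
    "cumulative_pd",
)


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set = set()
        dup = next(x for x in ids if x in seen or seen.add(x))
        raise FormatError(f"duplicate {what} ID: {dup!r}")


@dataclass(frozen=True)
class BetaMatrix:
    """Probe-by-sample matrix of methylation fractions.

    ``values`` has shape ``(len(probe_ids), len(sample_ids))``; missing
    measurements are ``NaN``. Non-missing entries must lie in [0, 1].
    """

    probe_ids: tuple
    sample_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "probe_ids", tuple(self.probe_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        if vals.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {vals.shape} does not match "
                f"({len(self.probe_ids)} probes, {len(self.sample_ids)} samples)"
            )
        with np.errstate(invalid="ignore"):
            bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise RangeError(
                f"beta value {vals[i, j]!r} outside [0, 1] at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    # -- convenience -------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.probe_ids),
                            columns=list(self.sample_ids))

    def select_probes(self, probes: Iterable[str]) -> "BetaMatrix":
        """Restrict to ``probes`` in the given order (all must exist)."""
        probes = list(probes)
        pos = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probes if p not in pos]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        idx = [pos[p] for p in probes]
        return BetaMatrix(tuple(probes), self.sample_ids, self.values[idx])

    def drop_probes(self, probes: Iterable[str]) -> "BetaMatrix":
        drop = set(probes)
        keep = [i for i, p in enumerate(self.probe_ids) if p not in drop]
        return BetaMatrix(tuple(self.probe_ids[i] for i in keep),
                          self.sample_ids, self.values[keep])

    def select_samples(self, samples: Iterable[str]) -> "BetaMatrix":
        samples = list(samples)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        idx = [pos[s] for s in samples]
        return BetaMatrix(self.probe_ids, tuple(samples), self.values[:, idx])

    def __eq__(self, other):
        if not isinstance(other, BetaMatrix):
            return NotImplemented
        return (self.probe_ids == other.probe_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.values, other.values, equal_nan=True))


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample annotations.

    Required per sample: unique ``sample_id`` and a non-negative integer
    ``passage``. Optional: ``cell_type``, ``donor_id``, ``treatment``,
    ``dose`` (free-form "number unit" string) and ``cumulative_pd``.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame.copy()
        for col in ("sample_id", "passage"):
            if col not in df.columns:
                raise FormatError(f"sample sheet lacks required column {col!r}")
        for col in _SHEET_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df.loc[:, list(_SHEET_COLUMNS)]
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(list(df["sample_id"]), "sample")
        passages = []
        for sid, raw in zip(df["sample_id"], df["passage"]):
            try:
                f = float(raw)
            except (TypeError, ValueError):
                raise FormatError(f"passage {raw!r} for sample {sid!r} is not an integer")
            if not math.isfinite(f) or f != int(f):
                raise FormatError(f"passage {raw!r} for sample {sid!r} is not an integer")
            if f < 0:
                raise RangeError(f"negative passage {raw!r} for sample {sid!r}")
            passages.append(int(f))
        df["passage"] = passages
        for col in ("cell_type", "donor_id", "treatment", "dose"):
            df[col] = df[col].map(
                lambda v: np.nan if (pd.isna(v) or v == "") else str(v))
        df["cumulative_pd"] = [
            np.nan if (pd.isna(v) or v == "") else float(v)
            for v in df["cumulative_pd"]]
        df = df.reset_index(drop=True)
        object.__setattr__(self, "frame", df)

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.frame["sample_id"])

    def passages_for(self, sample_ids: Iterable[str]) -> np.ndarray:
        m = dict(zip(self.frame["sample_id"], self.frame["passage"]))
        return np.array([m[s] for s in sample_ids], dtype=float)

    def treatment_of(self, sample_id: str):
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        return None if row.empty else row["treatment"].iloc[0]

    def subset_by_treatment(self, label: str) -> "SampleSheet":
        return SampleSheet(self.frame.loc[self.frame["treatment"] == label])

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other):
        if not isinstance(other, SampleSheet):
            return NotImplemented
        a, b = self.frame, other.frame
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            x, y = a[col], b[col]
            if x.dtype.kind == "f" or y.dtype.kind == "f":
                if not np.allclose(x.astype(float), y.astype(float), equal_nan=True,
                                   rtol=0, atol=0):
                    return False
            else:
                same = (x == y) | (x.isna() & y.isna())
                if not bool(same.all()):
                    return False
        return True


@dataclass(frozen=True)
class ClockModel:
    """A trained passage clock: intercept plus sparse CpG weights.

    Weights are on the original beta scale (passage units per unit
    beta); only CpGs with nonzero coefficients are stored.
    ``training_meta`` records the elastic-net mixing ``alpha``, the
    selected penalty ``lambda_``, screening threshold, CV fold count,
    seed, training sample count and passage range.
    """

    intercept: float
    weights: dict
    training_meta: dict = field(default_factory=dict)
    schema_version: int = CLOCK_SCHEMA_VERSION

    def __post_init__(self):
        for probe, w in self.weights.items():
            if w == 0.0:
                raise RangeError(f"zero-valued weight for probe {probe!r} "
                                 "(only selected CpGs may be stored)")
        alpha = self.training_meta.get("alpha")
        if alpha is not None and not (0.0 <= alpha <= 1.0):
            raise RangeError(f"alpha {alpha} outside [0, 1]")
        lam = self.training_meta.get("lambda_")
        if lam is not None and lam < 0:
            raise RangeError(f"lambda {lam} must be >= 0")

    @property
    def probes(self) -> tuple:
        return tuple(self.weights)

    def __eq__(self, other):
        if not isinstance(other, ClockModel):
            return NotImplemented
        return (self.schema_version == other.schema_version
                and self.intercept == other.intercept
                and self.weights == other.weights
                and self.training_meta == other.training_meta)


@dataclass(frozen=True)
class PredictionResult:
    """Predicted passage for one sample, with the deceleration readout
    ``delta = predicted - actual`` when the actual passage is known."""

    sample_id: str
    predicted_passage: float
    actual_passage: int | None = None
    delta: float | None = None

    def __post_init__(self):
        if self.actual_passage is not None:
            object.__setattr__(self, "delta",
                               float(self.predicted_passage - self.actual_passage))
        else:
            object.__setattr__(self, "delta", None)


@dataclass(frozen=True)
class EvalMetrics:
    """Prediction accuracy summary: RMSE in passage units, Spearman
    rank correlation with its asymptotic p-value, and sample count.
    ``spearman_defined`` is False when either vector is constant."""

    rmse: float
    spearman_rho: float
    spearman_p: float
    n: int
    spearman_defined: bool = True


# ---------------------------------------------------------------------------
# beta matrix I/O (TSV, probes as rows)
# ---------------------------------------------------------------------------

def read_beta_matrix(path) -> BetaMatrix:
    """Read a tab-separated beta matrix (first column probe IDs, header
    row sample IDs). Empty cells become missing; any other unparseable
    cell, out-of-range value, or duplicate ID raises."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 1:
        raise FormatError(f"{path}: empty header")
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample")
    # float_precision="round_trip" keeps the written 17-digit values
    # bit-exact; pd.to_numeric would not
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                     na_values=[""], skip_blank_lines=True,
                     float_precision="round_trip")
    probe_ids = [str(p) for p in df.index]
    _check_unique(probe_ids, "probe")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        s = df[col]
        if s.dtype.kind in "fiu":
            values[:, j] = s.to_numpy(dtype=float)
            continue
        # mixed column: the C parser left it as objects
        for i, v in enumerate(s.to_numpy()):
            if isinstance(v, float) and np.isnan(v):
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(v)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: unparseable value {v!r} at probe "
                    f"{probe_ids[i]!r}, sample {col!r}") from None
    try:
        return BetaMatrix(tuple(probe_ids), tuple(map(str, df.columns)), values)
    except RangeError as err:
        raise RangeError(f"{path}: {err}") from None


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    df = matrix.to_dataframe()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep="")


# ---------------------------------------------------------------------------
# sample sheet I/O (CSV)
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if "sample_id" not in df.columns or "passage" not in df.columns:
        raise FormatError(f"{path}: sample sheet requires columns "
                          "'sample_id' and 'passage'")
    try:
        return SampleSheet(df)
    except (FormatError, RangeError) as err:
        raise type(err)(f"{path}: {err}") from None


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    df = sheet.frame.copy()
    df["cumulative_pd"] = df["cumulative_pd"].map(
        lambda v: "" if pd.isna(v) else _FLOAT_FMT % v)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# clock model I/O (versioned JSON)
# ---------------------------------------------------------------------------

def write_clock_model(model: ClockModel, path) -> None:
    """Serialise a clock model as JSON. ``json`` emits ``repr``-style
    floats, so numeric fields survive a round trip bit-exactly."""
    doc = {
        "schema_version": model.schema_version,
        "intercept": model.intercept,
        "weights": dict(model.weights),
        "training_meta": model.training_meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_clock_model(path) -> ClockModel:
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != CLOCK_SCHEMA_VERSION:
        raise FormatError(f"{path}: unknown clock-model schema version {version!r}")
    return ClockModel(intercept=float(doc["intercept"]),
                      weights={str(k): float(v) for k, v in doc["weights"].items()},
                      training_meta=doc.get("training_meta", {}),
                      schema_version=version)


def predictions_to_frame(predictions: Sequence[PredictionResult]) -> pd.DataFrame:
    """Tabular view of prediction results (used by the CLI writers)."""
    return pd.DataFrame({
        "sample_id": [p.sample_id for p in predictions],
        "predicted_passage": [p.predicted_passage for p in predictions],
        "actual_passage": [p.actual_passage for p in predictions],
        "delta": [p.delta for p in predictions],
    })
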