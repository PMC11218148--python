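"""Probe-level quality filtering upstream of clock construction.

Inputs are assumed to be background-corrected (e.g. Noob-normalised)
beta values; this module implements only the probe gates applied before
screening: the detection p-value filter, removal of a user-supplied
cross-hybridising probe blocklist, and removal of probes with missing
measurements. Optionally, beta can be computed from raw
methylated/unmethylated intensity pairs with the platform-standard
offset.

All filters act on probes only; the sample set is never altered, and
each filter is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import CoverageError, RangeError, ConfigError
from .io import BetaMatrix

log = logging.getLogger(__name__)

__all__ = [
    "IntensityPairMatrix",
    "DetectionPMatrix",
    "compute_beta",
    "filter_by_detection",
    "remove_blocklist",
    "drop_incomplete_probes",
    "read_blocklist",
    "read_detection_p",
]


@dataclass(frozen=True)
class IntensityPairMatrix:
    """Methylated/unmethylated fluorescence intensities per probe and
    sample, in arbitrary (but shared) units."""

    probe_ids: tuple
    sample_ids: tuple
    methylated: np.ndarray
    unmethylated: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "probe_ids", tuple(self.probe_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        m = np.asarray(self.methylated, dtype=float)
        u = np.asarray(self.unmethylated, dtype=float)
        shape = (len(self.probe_ids), len(self.sample_ids))
        if m.shape != shape or u.shape != shape:
            raise RangeError(f"intensity matrices must both have shape {shape}")
        if (m < 0).any() or (u < 0).any():
            raise RangeError("negative fluorescence intensity")
        object.__setattr__(self, "methylated", m)
        object.__setattr__(self, "unmethylated", u)


@dataclass(frozen=True)
class DetectionPMatrix:
    """Per-probe, per-sample detection p-values (probability the signal
    is indistinguishable from background)."""

    probe_ids: tuple
    sample_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "probe_ids", tuple(self.probe_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise RangeError("detection-p matrix shape mismatch")
        if ((v < 0) | (v > 1)).any():
            raise RangeError("detection p-values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


def compute_beta(intensities: IntensityPairMatrix, offset: float = 100.0) -> BetaMatrix:
    """beta = M / (M + U + offset), the platform-standard stabilised
    methylation fraction; the offset keeps low-intensity probes away
    from 0/1 and guarantees outputs in [0, 1)."""
    if offset < 0:
        raise RangeError("offset must be >= 0")
    m, u = intensities.methylated, intensities.unmethylated
    denom = m + u + offset
    if (denom == 0).any():
        raise RangeError("zero total intensity with zero offset")
    return BetaMatrix(intensities.probe_ids, intensities.sample_ids, m / denom)


def filter_by_detection(beta: BetaMatrix, detp: DetectionPMatrix,
                        cutoff: float = 0.01, rule: str = "any-sample") -> BetaMatrix:
    """Drop probes that fail the detection filter.

    Under ``rule="any-sample"`` (default, strictest reading) a probe is
    removed when its detection p exceeds ``cutoff`` in at least one
    sample; under ``rule="mean"`` when its mean detection p across
    samples exceeds ``cutoff``.
    """
    if rule not in ("any-sample", "mean"):
        raise ConfigError(f"unknown detection rule {rule!r}")
    pos = {p: i for i, p in enumerate(detp.probe_ids)}
    missing = [p for p in beta.probe_ids if p not in pos]
    if missing:
        raise CoverageError(f"{len(missing)} probes absent from detection-p "
                            f"matrix, e.g. {missing[:5]}")
    spos = {s: i for i, s in enumerate(detp.sample_ids)}
    smissing = [s for s in beta.sample_ids if s not in spos]
    if smissing:
        raise CoverageError(f"samples absent from detection-p matrix: {smissing[:5]}")
    sub = detp.values[np.ix_([pos[p] for p in beta.probe_ids],
                             [spos[s] for s in beta.sample_ids])]
    if rule == "any-sample":
        fails = (sub > cutoff).any(axis=1)
    else:
        fails = sub.mean(axis=1) > cutoff
    dropped = [p for p, f in zip(beta.probe_ids, fails) if f]
    log.info("detection filter (%s, cutoff %g): dropped %d of %d probes",
             rule, cutoff, len(dropped), beta.n_probes)
    return beta.drop_probes(dropped)


def remove_blocklist(beta: BetaMatrix, blocklist) -> BetaMatrix:
    """Remove probes on a (cross-hybridising) blocklist; IDs not in the
    matrix are counted and ignored."""
    block = set(blocklist)
    present = block & set(beta.probe_ids)
    absent = len(block) - len(present)
    if absent:
        log.info("blocklist: %d IDs not found in matrix", absent)
    out = beta.drop_probes(present)
    log.info("blocklist: removed %d of %d probes", len(present), beta.n_probes)
    if out.n_probes == 0:
        log.warning("blocklist removed every probe")
    return out


def drop_incomplete_probes(beta: BetaMatrix) -> BetaMatrix:
    """Remove probes with any missing measurement (training and
    prediction require complete rows)."""
    incomplete = np.isnan(beta.values).any(axis=1)
    dropped = [p for p, f in zip(beta.probe_ids, incomplete) if f]
    if dropped:
        log.info("dropped %d probes with missing values", len(dropped))
    out = beta.drop_probes(dropped)
    if out.n_probes == 0 and beta.n_probes > 0:
        log.warning("every probe had at least one missing value")
    return out


def read_blocklist(path) -> set:
    """Read a probe blocklist: one probe ID per line, ``#`` comments
    and blank lines ignored."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                ids.add(entry)
    return ids


def read_detection_p(path) -> DetectionPMatrix:
    """Read a detection p-value matrix in the same TSV layout as a beta
    matrix (probes as rows)."""
    from .io import read_beta_matrix  # same dialect and [0,1] contract

    bm = read_beta_matrix(path)
    return DetectionPMatrix(bm.probe_ids, bm.sample_ids, bm.values)
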