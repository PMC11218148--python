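"""Non-clock screening statistics: robust Z scores for senescence-marker
panels and population-doubling arithmetic.

Robust Z of a treatment measurement ``t`` against control values ``x``:

    z = (t - median(x)) / MAD(x),   MAD(x) = median(|x - median(x)|)

with the MAD deliberately *unscaled* (no 1.4826 normal-consistency
factor). A call of "senescent" or "proliferative" is made when the
polarity-adjusted z crosses +/- cutoff (default 0.5).

Population doublings between seeding and harvest:

    PD = ln(final / (seeded / 2)) / 0.6931 - 1

with 0.6931 as a literal constant (use ``exact_ln2=True`` for ln 2);
cumulative PD is the running sum across passages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ConfigError, DegenerateSpreadError, RangeError

__all__ = [
    "MarkerMeasurements",
    "RobustZResult",
    "PdRecord",
    "DEFAULT_POLARITY",
    "robust_z",
    "classify_marker",
    "population_doubling",
    "cumulative_pd",
]

SENESCENCE_INCREASES = "senescence-increases"
SENESCENCE_DECREASES = "senescence-decreases"

#: Default polarities for the common senescence-marker panel: CDK
#: inhibitors, SA-beta-Gal, the SASP cytokine IL-6 and morphometry all
#: increase with senescence; nucleolar integrity (nucleolin signal)
#: decreases.
DEFAULT_POLARITY = {
    "p21": SENESCENCE_INCREASES,
    "p16": SENESCENCE_INCREASES,
    "SA-b-Gal": SENESCENCE_INCREASES,
    "IL-6": SENESCENCE_INCREASES,
    "nuclear_area": SENESCENCE_INCREASES,
    "cell_area": SENESCENCE_INCREASES,
    "nucleolin": SENESCENCE_DECREASES,
}


@dataclass(frozen=True)
class MarkerMeasurements:
    """One marker's control and treatment measurements (same assay
    units), plus the direction the marker moves with senescence."""

    marker: str
    polarity: str
    control_values: tuple
    treatment_values: tuple

    def __post_init__(self):
        if self.polarity not in (SENESCENCE_INCREASES, SENESCENCE_DECREASES):
            raise ConfigError(f"unknown polarity {self.polarity!r} "
                              f"for marker {self.marker!r}")
        ctrl = tuple(float(v) for v in self.control_values)
        if len(ctrl) < 3:
            raise ConfigError(f"marker {self.marker!r}: need >= 3 control "
                              f"values to estimate spread, got {len(ctrl)}")
        object.__setattr__(self, "control_values", ctrl)
        object.__setattr__(self, "treatment_values",
                           tuple(float(v) for v in self.treatment_values))


@dataclass(frozen=True)
class RobustZResult:
    """Robust Z for one treatment observation with its phenotype call."""

    marker: str
    value: float
    z: float
    call: str
    control_median: float
    mad: float


def classify_marker(z: float, polarity: str, cutoff: float = 0.5) -> str:
    """Map a robust Z to a phenotype call at the given cutoff.

    For a marker that increases with senescence, z >= +cutoff means
    "senescent" and z <= -cutoff "proliferative"; the mapping flips for
    markers that decrease with senescence. In between: "no-change".
    """
    if polarity not in (SENESCENCE_INCREASES, SENESCENCE_DECREASES):
        raise ConfigError(f"unknown polarity {polarity!r}")
    adj = z if polarity == SENESCENCE_INCREASES else -z
    if adj >= cutoff:
        return "senescent"
    if adj <= -cutoff:
        return "proliferative"
    return "no-change"


def robust_z(measurements: MarkerMeasurements, cutoff: float = 0.5) -> list:
    """Score each treatment value against the control median and MAD."""
    ctrl = np.asarray(measurements.control_values)
    med = float(np.median(ctrl))
    mad = float(np.median(np.abs(ctrl - med)))
    if mad == 0.0:
        raise DegenerateSpreadError(
            f"marker {measurements.marker!r}: control MAD is zero")
    out = []
    for t in measurements.treatment_values:
        z = (t - med) / mad
        out.append(RobustZResult(measurements.marker, t, z,
                                 classify_marker(z, measurements.polarity, cutoff),
                                 med, mad))
    return out


def population_doubling(seeded: float, final: float, exact_ln2: bool = False) -> float:
    """Doublings between seeding and harvest, assuming ~half the seeded
    cells attach (hence the ``seeded / 2`` reference and the -1)."""
    if seeded <= 0:
        raise RangeError(f"seeded count must be > 0, got {seeded}")
    if final <= 0:
        raise RangeError(f"final count must be > 0, got {final}")
    denom = math.log(2.0) if exact_ln2 else 0.6931
    return math.log(final / (seeded / 2.0)) / denom - 1.0


@dataclass(frozen=True)
class PdRecord:
    """One passage's cell counts and the resulting doublings."""

    seeded: float
    final: float
    pd: float = None  # computed when omitted

    def __post_init__(self):
        if self.pd is None:
            object.__setattr__(self, "pd",
                               population_doubling(self.seeded, self.final))


def cumulative_pd(series: Sequence) -> np.ndarray:
    """Running sum of per-passage population doublings.

    Accepts :class:`PdRecord` items or bare numbers, ordered by passage.
    """
    pds = [r.pd if isinstance(r, PdRecord) else float(r) for r in series]
    return np.cumsum(np.asarray(pds, dtype=float))
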