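"""Exception hierarchy for passclock.

All errors raised deliberately by the library derive from
:class:`PassclockError`, so callers (and the CLI) can distinguish
domain failures from programming errors.
"""


class PassclockError(Exception):
    """Base class for all passclock errors."""


class FormatError(PassclockError):
    """A file violates its expected tabular layout (duplicate IDs,
    missing required columns, unparseable cells, unknown schema)."""


class RangeError(PassclockError):
    """A numeric value is outside its admissible range (e.g. a beta
    value outside [0, 1] or a negative intensity)."""


class CoverageError(PassclockError):
    """An operation requires matched probe/sample coverage between two
    matrices and the coverage is incomplete."""


class DesignError(PassclockError):
    """A regression or fit cannot proceed: degenerate design (all
    covariate values identical) or too few samples."""


class MissingProbeError(PassclockError):
    """Probes required by a clock model are absent (or missing-valued)
    in the matrix being scored."""

    def __init__(self, probe_ids):
        self.probe_ids = sorted(probe_ids)
        shown = ", ".join(self.probe_ids[:10])
        more = "" if len(self.probe_ids) <= 10 else f" (+{len(self.probe_ids) - 10} more)"
        super().__init__(f"clock probes unavailable in matrix: {shown}{more}")


class DegenerateSpreadError(PassclockError):
    """The control measurements of a marker have zero MAD, so a robust
    Z score is undefined."""


class ConfigError(PassclockError):
    """An invalid configuration value or combination."""


class LabelError(PassclockError):
    """A requested cohort/treatment label is absent from the sample sheet."""
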