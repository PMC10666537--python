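"""Exception hierarchy shared across the pipeline."""


class ToxfingerError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ToxfingerError):
    """A table or config file does not match the expected dialect."""


class RowError(FormatError):
    """A single row failed to parse; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class ConfigError(ToxfingerError):
    """Invalid configuration value."""


class PreconditionError(ToxfingerError):
    """An operation was called with input violating its contract."""


class MappingError(ToxfingerError):
    """Endpoint→target map is inconsistent (e.g. endpoint in two targets)."""


class SplitError(ToxfingerError):
    """Train/test split impossible (a class has fewer than two members)."""


class AlignmentError(ToxfingerError):
    """Sample or bit identifiers of two matrices do not match."""


class MissingBitError(ToxfingerError):
    """A replicate fingerprint lacks a bit required by a trained model."""


class LeakageError(ToxfingerError):
    """Validation compounds overlap with training compounds."""

    def __init__(self, offenders):
        self.offenders = sorted(offenders)
        super().__init__(
            f"{len(self.offenders)} validation compound(s) present in training "
            f"data: {', '.join(self.offenders[:10])}"
            + ("..." if len(self.offenders) > 10 else "")
        )


class CalibrationError(ToxfingerError):
    """Synthetic label calibration could not reach the target fraction."""


class DegenerateAssayError(ToxfingerError):
    """Efficacy cutoff is non-positive; every series would be called active."""
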