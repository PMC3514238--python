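"""Exception hierarchy shared across the package."""


class PepGenomeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PepGenomeError):
    """A file does not conform to its declared dialect."""


class RowError(FormatError):
    """A single data row is malformed; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class NormalizationError(PepGenomeError):
    """A peptide string could not be reduced to plain amino-acid letters."""


class FrameError(PepGenomeError):
    """Raw CDS length is not a multiple of three."""


class LengthMismatchError(PepGenomeError):
    """CDS length disagrees with the protein length (neither 3L nor 3L+3)."""


class RangeError(PepGenomeError):
    """A protein position/length pair falls outside the coding region."""


class ConfigError(PepGenomeError):
    """Invalid run configuration (e.g. non-increasing tier thresholds)."""


class FixtureError(PepGenomeError):
    """Synthetic-fixture geometry is impossible for the requested sizes."""
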