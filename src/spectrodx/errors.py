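"""Exception hierarchy for spectrodx.

Exit-code mapping used by the CLI:
  1 — validation errors (bad configuration or arguments)
  2 — consistency / format errors (files disagree with each other)
  3 — degenerate statistics (a quantity is undefined on the given data)
"""


class SpectroDxError(Exception):
    """Base class for all spectrodx errors."""

    exit_code = 1


class InvalidConfigError(SpectroDxError, ValueError):
    """A configuration value violates its constraints."""

    exit_code = 1


class InvalidInputError(SpectroDxError, ValueError):
    """An operation received data it cannot process (too few points, bad window...)."""

    exit_code = 1


class FormatError(SpectroDxError, ValueError):
    """A file does not conform to the expected schema."""

    exit_code = 2


class ConsistencyError(SpectroDxError, ValueError):
    """Two inputs that must agree (e.g. spectra vs truth table) do not."""

    exit_code = 2


class IncompatibleGridError(SpectroDxError, ValueError):
    """Spectra or features are defined on different wavenumber grids."""

    exit_code = 2


class DegenerateInputError(SpectroDxError, ValueError):
    """The requested statistic is undefined on this input (single class, zero vector...)."""

    exit_code = 3


class UndefinedMetricError(SpectroDxError, ZeroDivisionError):
    """A metric's denominator is zero; the value is undefined, not silently 0."""

    exit_code = 3
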