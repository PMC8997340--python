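"""Exception hierarchy shared across the toolkit."""


class TaxodelimError(Exception):
    """Base class for all package errors."""


class InputError(TaxodelimError, ValueError):
    """Malformed or empty input where a value is required."""


class AlphabetError(InputError):
    """Sequence residues inconsistent with the declared/expected alphabet."""


class UndefinedMetricError(TaxodelimError):
    """A metric has no defined value (e.g. ANI with zero retained fragments).

    Distinct from a value of 0: the comparison carries no signal at all.
    """


class OrientationError(InputError):
    """rRNA anchors matched in mutually inconsistent orientations."""


class ParseError(TaxodelimError, ValueError):
    """A file could not be parsed; carries a line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class LineageError(TaxodelimError, ValueError):
    """A hit lacks taxonomy lineage information in strict mode."""
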