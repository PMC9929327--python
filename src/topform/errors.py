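"""Exception hierarchy shared across the package."""


class TopformError(Exception):
    """Base class for all package-specific errors."""


class FormulaError(TopformError, ValueError):
    """Malformed elemental formula or unknown element symbol."""


class SequenceError(TopformError, ValueError):
    """Non-canonical residue or otherwise invalid protein sequence."""


class LadderError(TopformError, ValueError):
    """Fragment ladder requested for a sequence too short to cleave."""


class ProteoformParseError(TopformError, ValueError):
    """Malformed bracketed proteoform string.

    Carries ``position``, the 0-based offset in the input where parsing failed,
    or ``None`` when the failure is not tied to a single character.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class TableFormatError(TopformError, ValueError):
    """Missing column or unparseable row in a tabular input file."""


class LocalizationError(TopformError, ValueError):
    """No residue placement is consistent with the matched fragments.

    ``conflict`` holds a pair of mutually contradictory fragment matches when
    one can be identified.
    """

    def __init__(self, message: str, conflict: tuple | None = None):
        self.conflict = conflict
        super().__init__(message)


class ConfigError(TopformError, ValueError):
    """Invalid run or simulation configuration."""


class FixtureError(TopformError, KeyError):
    """Unknown packaged fixture name."""
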