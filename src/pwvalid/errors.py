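"""Exception types shared across the validation framework."""


class PWValidError(Exception):
    """Base class for all framework errors."""


class DomainError(PWValidError, ValueError):
    """An argument is outside its mathematical or physiological domain."""


class InfeasibleMeanError(DomainError):
    """No positive SD can satisfy the tolerable-error bound for this mean."""


class ValidationDataError(PWValidError, ValueError):
    """Structured input-data validation failure (carries context)."""

    def __init__(self, message: str, participant_id: str | None = None,
                 line: int | None = None):
        self.participant_id = participant_id
        self.line = line
        prefix = ""
        if participant_id is not None:
            prefix += f"participant {participant_id!r}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class InsufficientDataError(PWValidError, ValueError):
    """Fewer observations than the analysis requires."""


class InsufficientBeatsError(InsufficientDataError):
    """Fewer matched cardiac cycles than the protocol minimum."""


class ConfigurationError(PWValidError, ValueError):
    """Invalid or missing study/simulation configuration."""
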