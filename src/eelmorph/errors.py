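"""Exception hierarchy shared by all stages."""


class EelmorphError(Exception):
    """Base class for all package errors."""


class SchemaError(EelmorphError):
    """A table is missing a required column or uses an unknown vocabulary."""


class RecordError(EelmorphError):
    """A single row violates a field invariant; carries the row context."""


class TreeError(EelmorphError):
    """Tree parsing or structural problem (duplicate labels, no root, ...)."""


class CalibrationError(EelmorphError):
    """Node-age assignment conflict (parent not older than child, etc.)."""


class ConfigError(EelmorphError):
    """A simulation configuration is infeasible or inconsistent."""
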