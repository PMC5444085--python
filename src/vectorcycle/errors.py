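"""Exception hierarchy.

ValidationError and ConfigError signal bad user input (CLI exit code 1);
TotalBlockadeError and UndefinedProfileError signal model states with no
defined answer (CLI exit code 2).
"""


class ValidationError(ValueError):
    """An input value violates a domain constraint (e.g. outside [0, 1])."""


class ConfigError(ValidationError):
    """A configuration file violates its schema."""


class TotalBlockadeError(RuntimeError):
    """Every attack attempt is non-lethally blocked: no feeding is possible
    and expected encounters diverge."""


class UndefinedProfileError(RuntimeError):
    """A behaviour profile cannot be inferred because no residual feeding
    remains."""
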