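"""Exception hierarchy used across the package.

All validation failures derive from :class:`ValueError` so that callers can
catch broadly; the CLI maps each class onto a distinct exit code.
"""


class FormatError(ValueError):
    """A pose-tracking file violates the documented CSV dialect."""


class ConfigError(ValueError):
    """A configuration file is missing a required key or violates an invariant."""


class UndefinedAngleError(ValueError):
    """Head and foot coincide, so the body vector has no direction."""


class DegenerateDataError(ValueError):
    """A statistical test received data on which it is undefined."""


class FitError(RuntimeError):
    """A maximum-likelihood fit failed to converge or the data are degenerate."""
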