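"""Exception hierarchy for the coweda package.

All domain errors derive from :class:`CowedaError` so callers (and the CLI)
can distinguish validation problems (exit code 2) from runtime/solver
failures (exit code 3).
"""


class CowedaError(Exception):
    """Base class for all coweda errors."""


class SchemaError(CowedaError):
    """A structured input (CSV, YAML) does not match its documented schema."""


class ValidationError(CowedaError):
    """A value violates a domain invariant (negative resistance, bad range...)."""


class ConfigurationError(CowedaError):
    """Inconsistent run configuration (e.g. insulation missing a region)."""


class CalibrationError(CowedaError):
    """The thermoneutral steady-state calibration produced unphysical values."""


class SolverError(CowedaError):
    """The integrator encountered a non-finite state."""


class InputError(CowedaError):
    """Bad input series / comparison data for the evaluation machinery."""
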