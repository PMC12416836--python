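"""Exception hierarchy for lineagesim.

All package errors derive from :class:`LineageSimError` so callers can catch
one base class; subclasses distinguish configuration mistakes (bad parameters,
unknown names), bad runtime inputs (malformed trajectories, inconsistent
schedules) and numerical failures during integration.
"""


class LineageSimError(Exception):
    """Base class for all lineagesim errors."""


class ConfigurationError(LineageSimError, ValueError):
    """A parameter, config key or model contract is invalid."""


class InputError(LineageSimError, ValueError):
    """A runtime input (trajectory, lineage, schedule, matrix) is invalid."""


class SchemaError(InputError):
    """Column/species names do not match what a fitted object expects."""


class NumericsError(LineageSimError, RuntimeError):
    """Non-finite state or an undefined quantity arose during computation."""
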