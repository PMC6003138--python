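"""Exception hierarchy shared across the package."""

from __future__ import annotations


class MechSpikeError(Exception):
    """Base class for all mechspike errors."""


class InvalidArgumentError(MechSpikeError, ValueError):
    """An argument violates a precondition (non-positive dt, bad tau, ...)."""


class TraceFormatError(MechSpikeError, ValueError):
    """A trace file is malformed (non-uniform time grid, empty, wrong shape)."""


class NumericalOverflowError(MechSpikeError, FloatingPointError):
    """The integrator produced a non-finite state.

    Carries ``step``, the sample index at which the state became non-finite.
    """

    def __init__(self, message: str, step: int):
        super().__init__(message)
        self.step = step


class UndefinedStatisticError(MechSpikeError, ValueError):
    """Too few events to define the requested interval statistic."""


class ConfigValidationError(MechSpikeError, ValueError):
    """A run configuration contains unknown or inconsistent keys.

    Carries ``keys``, the list of every offending (dotted) key.
    """

    def __init__(self, message: str, keys: list[str] | None = None):
        super().__init__(message)
        self.keys = keys or []
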