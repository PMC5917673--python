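"""Exception hierarchy shared across the package."""


class ProtoforgeError(Exception):
    """Base class for all package-specific errors."""


class NetworkParseError(ProtoforgeError):
    """A network file could not be parsed under the requested dialect."""


class IntegrityError(ProtoforgeError):
    """A model violates referential integrity (dangling ids, duplicates)."""


class MergeConflictError(ProtoforgeError):
    """Two models declare the same species id with conflicting roles."""


class KineticsConfigError(ProtoforgeError):
    """A rate law is missing a constant or a substrate slot."""


class UnsupportedOrderError(ProtoforgeError):
    """Stochastic/deterministic conversion requested for reaction order > 2."""


class DivergentRateError(ProtoforgeError):
    """Per-step probability of 1 has no finite exponential rate."""


class CapabilityError(ProtoforgeError):
    """Input exceeds a documented search bound (e.g. > 3 logical inputs)."""


class InvariantError(ProtoforgeError):
    """A domain object violates one of its declared invariants."""


class FormulaSyntaxError(ProtoforgeError):
    """Temporal-logic formula text does not match the grammar."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message if position is None
                         else f"{message} (at column {position})")
        self.position = position


class ObservableError(ProtoforgeError):
    """A formula references an observable absent from the trace."""


class ContractError(ProtoforgeError):
    """An operation was called outside its contract (e.g. no free variables)."""


class SimulationError(ProtoforgeError):
    """The integrator or SSA kernel failed; carries the last good state."""

    def __init__(self, message: str, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class FixtureLookupError(ProtoforgeError):
    """Unknown fixture name; lists the valid names."""
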