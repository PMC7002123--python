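"""Exception hierarchy for viswarm."""


class ViswarmError(Exception):
    """Base class for all viswarm errors."""


class DegenerateGeometryError(ViswarmError, ValueError):
    """Raised when two agents occupy the same point (no defined projection)."""


class IntegrationError(ViswarmError, RuntimeError):
    """Raised when a time step produces a non-finite agent state.

    Attributes
    ----------
    agent : int
        Index of the first offending agent.
    term : str
        Name of the state component that became non-finite.
    step : int or None
        Step index within a `run`, if available.
    """

    def __init__(self, agent: int, term: str, step: int | None = None):
        self.agent = agent
        self.term = term
        self.step = step
        where = f" at step {step}" if step is not None else ""
        super().__init__(f"non-finite state in term '{term}' for agent {agent}{where}")


class ConfigError(ViswarmError, ValueError):
    """Raised for malformed or inconsistent experiment configurations."""


class MetricError(ViswarmError, ValueError):
    """Raised when a metric is undefined for the given input (e.g. N < 2)."""
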