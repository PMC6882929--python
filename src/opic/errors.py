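"""Exception hierarchy for the opic package."""


class OpicError(Exception):
    """Base class for all package errors."""


class EthogramError(OpicError):
    """Invalid ethogram definition or ethogram file."""


class EventError(OpicError):
    """Invalid event record or observation."""


class ReadError(OpicError):
    """An event file could not be parsed into a valid observation."""


class MetricsError(OpicError):
    """Sleep metrics cannot be derived (missing or ambiguous anchor events)."""


class GenerationError(OpicError):
    """A synthetic night scenario is infeasible."""


class SizeError(OpicError):
    """Problem instance too large for the exhaustive oracle."""
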