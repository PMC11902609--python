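"""Exception hierarchy.

All user-facing errors derive from :class:`BussegError` so callers (and the
CLI) can map them to exit codes without matching on message text.
"""


class BussegError(Exception):
    """Base class for all busseg errors."""


class InvalidParameterError(BussegError, ValueError):
    """A configuration or function parameter is out of its valid range."""


class InvalidInputError(BussegError, ValueError):
    """An input array, file or manifest violates a precondition."""


class InvalidSpecError(BussegError, ValueError):
    """A phantom specification is internally inconsistent."""


class TrainingError(BussegError, ValueError):
    """Classifier training cannot proceed (e.g. a class has no pixels)."""


class RayTooShortError(BussegError, ValueError):
    """A ray profile has too few samples for the requested gradient window."""


class EmptyContourError(BussegError, RuntimeError):
    """No boundary evidence was found on any ray."""


class DegenerateGeometryError(BussegError, RuntimeError):
    """A geometric reduction (e.g. hemisphere clipping) produced nothing."""
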