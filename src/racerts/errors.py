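"""Exception hierarchy.

All package-specific errors derive from :class:`RacerTSError` so callers can
catch everything with one clause while still discriminating failure modes.
"""


class RacerTSError(Exception):
    """Base class for all errors raised by this package."""


class XYZFormatError(RacerTSError, ValueError):
    """A (multi-)xyz file could not be parsed or violates its own header."""


class GeometryError(RacerTSError, ValueError):
    """Input coordinates are physically unusable (e.g. overlapping atoms)."""


class TemplateError(RacerTSError, ValueError):
    """A bonding template does not match the structure's composition."""


class MappingError(RacerTSError, ValueError):
    """No consistent atom mapping between template and 3D structure."""


class EmbeddingError(RacerTSError, RuntimeError):
    """Distance-geometry embedding produced no acceptable conformer."""


class RefinementError(RacerTSError, RuntimeError):
    """No energy engine in the chain could handle the system."""


class EngineUnavailableError(RefinementError):
    """An external engine's backing executable is not installed."""


class ValidationError(RacerTSError, ValueError):
    """An argument violates a documented precondition."""
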