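"""Exception hierarchy for the cytoarch pipeline."""


class CytoarchError(Exception):
    """Base class for all cytoarch errors."""


class FormatError(CytoarchError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(CytoarchError):
    """An in-memory object violates a domain invariant."""


class ConfigurationError(CytoarchError):
    """Required configuration (e.g. voxel size) is missing or inconsistent."""


class GenerationError(CytoarchError):
    """Synthetic-scene generation could not satisfy its constraints."""


class DegenerateInputError(CytoarchError):
    """Statistical input is degenerate (e.g. zero variance everywhere)."""
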