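"""Exception hierarchy."""


class ArchLabelError(Exception):
    """Base class for all archlabel errors."""


class MeshFormatError(ArchLabelError):
    """A mesh file could not be parsed in the requested format."""


class AnnotationError(ArchLabelError):
    """A label sidecar is inconsistent with its mesh."""


class EmptyDetectionError(ArchLabelError):
    """A sampling box contains no cloud points."""


class PriorMissingError(ArchLabelError):
    """A required distance-prior entry has no observation behind it."""


class ConfigError(ArchLabelError):
    """Invalid run configuration."""
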