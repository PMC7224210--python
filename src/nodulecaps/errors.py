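"""Exception types shared across the pipeline."""


class PlacementError(ValueError):
    """Requested nodules cannot be placed without overlap in the volume."""


class ExtractionError(ValueError):
    """A patch crop falls outside the volume or exceeds the padded size."""


class ShapeError(ValueError):
    """An array does not match the shape a network or layer expects."""


class StageDependencyError(RuntimeError):
    """A pipeline stage is missing an artifact an earlier stage produces."""
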