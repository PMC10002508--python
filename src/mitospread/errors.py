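"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A numeric parameter is outside its admissible range."""


class GeometryError(ValueError):
    """An axon trace or scene geometry is malformed."""


class PlacementError(RuntimeError):
    """Rejection sampling could not place the requested objects."""


class DegenerateImageError(ValueError):
    """An image has no contrast, so an automatic threshold is undefined."""
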