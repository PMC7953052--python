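"""Exception types shared across the package."""


class GraphFormatError(ValueError):
    """A graph/attribute file could not be parsed (carries the line number)."""


class ShapeError(ValueError):
    """Dimensions of two objects that must agree do not."""


class ParameterError(ValueError):
    """A configuration value violates its documented range."""


class CapacityError(ValueError):
    """A sampling request exceeds the number of eligible items.

    ``available`` holds the eligible count when it is known.
    """

    def __init__(self, message: str, available: int | None = None):
        super().__init__(message)
        self.available = available
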