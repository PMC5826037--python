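"""Exception hierarchy.

Everything raised on purpose derives from :class:`MiaClustError` so callers
(and the CLI) can distinguish validated failures from genuine bugs.
"""


class MiaClustError(Exception):
    """Base class for all errors raised by miaclust."""


class ParameterError(MiaClustError, ValueError):
    """An argument is outside its documented range or of the wrong shape."""


class FormatError(MiaClustError, IOError):
    """A file could not be parsed as a supported volume format."""


class AnisotropyError(MiaClustError, ValueError):
    """Voxel spacing is anisotropic beyond tolerance; the pipeline assumes
    isometric voxels."""


class DegenerateInputError(MiaClustError, ValueError):
    """The intensity distribution cannot support the requested number of
    classes (fewer distinct values than classes)."""


class CenterCollapseError(MiaClustError, ArithmeticError):
    """Two fuzzy c-means class centers collapsed onto each other."""

    def __init__(self, class_a: int, class_b: int, value: float):
        self.class_a = class_a
        self.class_b = class_b
        self.value = value
        super().__init__(
            f"c-means centers of classes {class_a} and {class_b} collapsed "
            f"at intensity {value:g}"
        )


class EmptyStructureError(MiaClustError, ValueError):
    """A thickness measurement was requested on an empty mask."""


class GeometryError(MiaClustError, ValueError):
    """A phantom specification cannot be realised in the requested shape."""
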