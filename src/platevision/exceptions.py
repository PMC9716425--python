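"""Exception types shared across pipeline stages."""


class PlateVisionError(RuntimeError):
    """Base class for pipeline errors."""


class PlacementError(PlateVisionError):
    """Food items could not be placed on the plate without overlap."""


class DetectionError(PlateVisionError):
    """No plate-like circular region was found in the image."""


class DegenerateDataError(PlateVisionError):
    """Training data contain a single class (all food or all background)."""


class UnsupportedSceneError(PlateVisionError):
    """The scene does not contain the geometry the operation requires."""


class MissingClassError(PlateVisionError):
    """A menu class is absent from every training label map."""


class MissingReferenceError(PlateVisionError, KeyError):
    """No daily reference amount is available for a nutrient."""
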