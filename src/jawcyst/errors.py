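"""Exception types shared across the pipeline."""


class JawCystError(Exception):
    """Base class for package errors."""


class PlacementError(JawCystError):
    """A lesion could not be placed to satisfy its class's overlap rule."""

    def __init__(self, scene_id: str, cyst_class: str, attempts: int):
        self.scene_id = scene_id
        super().__init__(
            f"scene {scene_id!r}: could not place a {cyst_class} lesion "
            f"satisfying its tooth-overlap rule within {attempts} attempts"
        )


class DegenerateInputError(JawCystError):
    """An input is empty or collapses to zero area/size."""


class AnnotationParseError(JawCystError):
    """A plain-text annotation line could not be parsed."""

    def __init__(self, path, line_no: int, message: str):
        self.path = path
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class FitError(JawCystError):
    """Model fitting received unusable data (e.g. a single class)."""


class ShapeError(JawCystError):
    """An array has the wrong dimensionality for the model."""
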