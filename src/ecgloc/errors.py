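"""Exception hierarchy for the electrode-localization pipeline."""


class EcglocError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EcglocError, ValueError):
    """An input violates a documented precondition (shape, range, schema)."""


class ConfigError(EcglocError, ValueError):
    """A configuration value is out of its admissible range."""


class EmptyClusterError(EcglocError):
    """Density clustering labeled every point as noise; eps/min_points are mis-set."""


class NoOverlapError(EcglocError):
    """ICP found zero correspondences at the initial alignment."""


class ReconstructionError(EcglocError):
    """Sequential multi-view alignment aborted on a failing pair of views.

    Attributes
    ----------
    pair : tuple of int
        Indices (k-1, k) of the consecutive views that could not be aligned.
    """

    def __init__(self, message: str, pair: tuple[int, int]):
        super().__init__(message)
        self.pair = pair


class SeedingError(EcglocError):
    """Too few electrodes of the seeding class are visible in the seed view."""

    def __init__(self, message: str, cls: str, view_index: int):
        super().__init__(message)
        self.cls = cls
        self.view_index = view_index


class LayoutError(EcglocError):
    """Phantom electrode strips collide on the torso surface."""
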