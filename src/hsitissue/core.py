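"""Core domain types for hyperspectral tissue recognition.

A hyperspectral acquisition is an H x W x B *hypercube*: a full relative-absorption
spectrum (B bands, here 100 bands spanning 500-1000 nm) at every pixel. Ground truth
comes as a sparse annotation mask over the same spatial grid, where 0 means
"unlabeled" and codes 1..7 name the seven classes an operating surgeon can identify
with certainty in a dissected neck field: artery, fat, metal (retractor), muscle,
nerve, skin and vein.

Conventions, fixed once and asserted in tests:

* coordinates are 0-based ``(row, col)``, row-major; the band axis is last;
* class codes are assigned alphabetically, artery=1 ... vein=7, so confusion
  matrices are ordered identically across runs;
* unlabeled pixels (code 0) are never treated as a class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class FormatError(ValueError):
    """A file or in-memory structure violates the declared format."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Band-center wavelengths in nm; strictly increasing and equally spaced."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise FormatError("wavelength grid must be a 1-D array with >= 2 bands")
        diffs = np.diff(values)
        if not np.all(diffs > 0):
            raise FormatError("wavelengths must be strictly increasing")
        if not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-9):
            raise FormatError("wavelengths must be equally spaced")

    @classmethod
    def default(cls, n_bands: int = 100, start: float = 500.0, stop: float = 1000.0) -> "WavelengthGrid":
        """The camera's grid: ``n_bands`` equally spaced band centers in [start, stop] nm."""
        return cls(np.linspace(start, stop, n_bands))

    @property
    def n_bands(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n_bands

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(np.allclose(self.values, other.values))


#: Display colors, one per class, used by annotation overlays and error maps.
_CLASS_COLORS = {
    "artery": (220, 20, 60),
    "fat": (255, 215, 0),
    "metal": (128, 128, 128),
    "muscle": (178, 34, 34),
    "nerve": (0, 255, 127),
    "skin": (244, 164, 96),
    "vein": (30, 144, 255),
}


@dataclass(frozen=True)
class TissueClassSet:
    """The fixed 7-class label set; integer codes 1..7, 0 reserved for unlabeled."""

    labels: tuple = ("artery", "fat", "metal", "muscle", "nerve", "skin", "vein")

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise FormatError("class labels must be unique")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    @property
    def codes(self) -> tuple:
        return tuple(range(1, len(self.labels) + 1))

    def code(self, label: str) -> int:
        return self.labels.index(label) + 1

    def label(self, code: int) -> str:
        if not 1 <= code <= len(self.labels):
            raise KeyError(f"class code {code} outside 1..{len(self.labels)}")
        return self.labels[code - 1]

    def color(self, code: int) -> tuple:
        return _CLASS_COLORS.get(self.label(code), (255, 255, 255))

    def __len__(self) -> int:
        return self.n_classes


DEFAULT_CLASSES = TissueClassSet()


@dataclass
class HSICube:
    """An H x W x B relative-absorption volume with its wavelength axis.

    ``data`` is float, all finite; ``wavelengths`` has exactly B entries.
    """

    data: np.ndarray
    wavelengths: WavelengthGrid
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise FormatError(f"cube must be H x W x B, got shape {self.data.shape}")
        if self.data.shape[2] != self.wavelengths.n_bands:
            raise FormatError(
                f"band axis has {self.data.shape[2]} entries but wavelength grid has "
                f"{self.wavelengths.n_bands}"
            )
        if not np.all(np.isfinite(self.data)):
            raise FormatError("cube contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def curve(self, row: int, col: int) -> "SpectralCurve":
        """The spectral curve at one pixel."""
        return SpectralCurve(self.data[row, col, :].copy(), self.wavelengths)


@dataclass
class AnnotationMask:
    """An H x W integer label map; 0 = unlabeled, 1..K = classes."""

    labels: np.ndarray
    class_set: TissueClassSet = field(default_factory=TissueClassSet)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("mask labels must be integers")
        self.labels = self.labels.astype(np.uint8)
        bad = np.setdiff1d(np.unique(self.labels), [0, *self.class_set.codes])
        if bad.size:
            raise FormatError(f"mask contains codes outside the class set: {bad.tolist()}")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def n_annotated(self) -> int:
        return int(np.count_nonzero(self.labels))

    def class_counts(self) -> dict:
        """Annotated-pixel count per class code (codes with zero pixels omitted)."""
        codes, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(c): int(n) for c, n in zip(codes, counts)}


@dataclass
class SpectralCurve:
    """A single length-B relative-absorption spectrum."""

    values: np.ndarray
    wavelengths: WavelengthGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size != self.wavelengths.n_bands:
            raise FormatError(
                f"curve has {self.values.size} values for {self.wavelengths.n_bands} bands"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("curve contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


def annotated_pixels(mask: AnnotationMask) -> list:
    """All annotated pixels as ``(row, col, class_code)`` in row-major order.

    Exactly the pixels with nonzero code; unlabeled pixels never appear.
    """
    rows, cols = np.nonzero(mask.labels)
    return [(int(r), int(c), int(mask.labels[r, c])) for r, c in zip(rows, cols)]
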