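"""Spectral normalization, band auto-scaling and sub-volume dataset assembly.

Two distinct standardizations appear in this pipeline and must not be confused:

* **SNV** (standard normal variate) standardizes each *curve* across its bands —
  mean 0, SD 1 per pixel — which removes multiplicative/additive illumination
  effects (surface orientation, non-flat geometry). It needs no training data
  and is an optional ablation for both models.
* **Band auto-scaling** standardizes each *band* across training curves — mean 0,
  unit variance per wavelength — and is fitted on the training fold only, then
  applied to test data. It is used on the SVM feature path.

The per-pixel classification unit is a ``SubVolume``: a w x w x B block (default
5 x 5 x 100) centered on the pixel of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AnnotationMask,
    HSICube,
    SpectralCurve,
    TissueClassSet,
    WavelengthGrid,
)


class DegenerateSpectrumError(ValueError):
    """A curve with zero spread cannot be standardized; never silently divided."""


def snv_normalize(curve: SpectralCurve) -> SpectralCurve:
    """Standard normal variate: rescale one curve to mean 0, SD 1.

    Invariant under positive affine maps of the input (``snv(a*x + b) == snv(x)``
    for ``a > 0``) and idempotent. A constant curve raises
    :class:`DegenerateSpectrumError`.
    """
    values = curve.values
    sd = values.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSpectrumError("constant spectrum has no SNV normalization")
    return SpectralCurve((values - values.mean()) / sd, curve.wavelengths)


def snv_normalize_cube(cube: HSICube) -> HSICube:
    """Apply SNV to every pixel's spectral curve independently."""
    data = cube.data.astype(np.float64)
    sd = data.std(axis=2)
    if np.any(sd == 0):
        r, c = np.argwhere(sd == 0)[0]
        raise DegenerateSpectrumError(f"constant spectrum at pixel ({r}, {c})")
    out = (data - data.mean(axis=2, keepdims=True)) / sd[..., None]
    return HSICube(out.astype(np.float32), cube.wavelengths, subject_id=cube.subject_id)


@dataclass
class BandScaler:
    """Per-band standardization (mean centering, unit variance), fit on training data."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, curves: np.ndarray) -> "BandScaler":
        """Fit on an (n x B) array of training curves; every band must vary.

        A zero-variance band raises a ``ValueError`` naming the band — it means
        the training fold is degenerate, and scaling it would be meaningless.
        """
        curves = np.asarray(curves, dtype=np.float64)
        if curves.ndim != 2 or curves.shape[0] < 2:
            raise ValueError("band scaler needs >= 2 training curves")
        mean = curves.mean(axis=0)
        sd = curves.std(axis=0)
        dead = np.nonzero(sd == 0)[0]
        if dead.size:
            raise ValueError(f"zero-variance band(s) in training data: {dead.tolist()}")
        return cls(mean, sd)

    def transform(self, curves: np.ndarray) -> np.ndarray:
        curves = np.asarray(curves, dtype=np.float64)
        if curves.shape[-1] != self.mean.size:
            raise ValueError(
                f"curves have {curves.shape[-1]} bands, scaler was fit on {self.mean.size}"
            )
        return (curves - self.mean) / self.sd

    def inverse_transform(self, curves: np.ndarray) -> np.ndarray:
        return np.asarray(curves) * self.sd + self.mean


def fit_band_scaler(curves: np.ndarray) -> BandScaler:
    """Functional alias for :meth:`BandScaler.fit`."""
    return BandScaler.fit(curves)


def apply_band_scaler(scaler: BandScaler, curve: SpectralCurve) -> SpectralCurve:
    """Standardize one curve with a fitted scaler: ``(x - mu_b) / sigma_b`` per band."""
    return SpectralCurve(scaler.transform(curve.values[None, :])[0], curve.wavelengths)


@dataclass
class SubVolume:
    """A w x w x B block centered on a pixel, with optional class label."""

    values: np.ndarray
    center: tuple
    subject_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("sub-volume must be w x w x B with square spatial window")
        if self.values.shape[0] % 2 == 0:
            raise ValueError("sub-volume window must be odd-sided")

    @property
    def window(self) -> int:
        return self.values.shape[0]


def extract_subvolume(cube: HSICube, center: tuple, window: int = 5) -> SubVolume:
    """Extract the w x w x B block centered on ``center`` (0-based row, col).

    At interior pixels this is exactly the raw cube block; near borders,
    out-of-image positions are filled by edge replication so the operation is
    total over the image.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    r, c = center
    h, w, _ = cube.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"center {center} outside cube of shape {h} x {w}")
    half = window // 2
    rows = np.clip(np.arange(r - half, r + half + 1), 0, h - 1)
    cols = np.clip(np.arange(c - half, c + half + 1), 0, w - 1)
    block = cube.data[np.ix_(rows, cols)]
    return SubVolume(block.copy(), (int(r), int(c)), subject_id=cube.subject_id)


@dataclass
class SubVolumeDataset:
    """Labeled sub-volumes from annotated pixels, with per-class bookkeeping.

    ``normalization`` records the preprocessing applied ("none" or "snv"); models
    check it at inference so a model trained on SNV data can never silently
    consume raw data.
    """

    values: np.ndarray  # n x w x w x B
    labels: np.ndarray  # n, class codes (all > 0)
    subject_ids: np.ndarray  # n, strings
    centers: np.ndarray  # n x 2
    class_set: TissueClassSet
    wavelengths: WavelengthGrid
    normalization: str = "none"

    def __post_init__(self) -> None:
        if len(self.values) != len(self.labels) or len(self.labels) != len(self.subject_ids):
            raise ValueError("values, labels and subject_ids must align")
        if len(self.labels) and self.labels.min() < 1:
            raise ValueError("dataset labels must be nonzero class codes")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def window(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[3]

    def class_counts(self) -> dict:
        codes, counts = np.unique(self.labels, return_counts=True)
        return {int(c): int(n) for c, n in zip(codes, counts)}

    def subset(self, index: np.ndarray) -> "SubVolumeDataset":
        return SubVolumeDataset(
            self.values[index],
            self.labels[index],
            self.subject_ids[index],
            self.centers[index],
            self.class_set,
            self.wavelengths,
            self.normalization,
        )

    def split_by_subject(self, held_out: str) -> tuple:
        """(training set, held-out set) for one leave-one-subject-out fold."""
        test = self.subject_ids == held_out
        if not test.any():
            raise ValueError(f"no samples for subject '{held_out}'")
        return self.subset(~test), self.subset(test)


def build_dataset(
    subjects: list,
    window: int = 5,
    normalization: str = "none",
) -> SubVolumeDataset:
    """One labeled sub-volume per annotated pixel, over (cube, mask) pairs.

    ``subjects`` may be ``(cube, mask)`` tuples or objects with ``cube``/``mask``
    attributes. With ``normalization="snv"``, SNV is applied to every pixel curve
    of each cube *before* patch extraction.
    """
    if normalization not in ("none", "snv"):
        raise ValueError(f"unknown normalization '{normalization}'")
    blocks, labels, sids, centers = [], [], [], []
    class_set, wavelengths = None, None
    for subject in subjects:
        cube, mask = subject if isinstance(subject, tuple) else (subject.cube, subject.mask)
        if cube.shape[:2] != mask.shape:
            raise ValueError(
                f"cube {cube.shape[:2]} and mask {mask.shape} spatial dims differ"
            )
        class_set = class_set or mask.class_set
        wavelengths = wavelengths or cube.wavelengths
        if normalization == "snv":
            cube = snv_normalize_cube(cube)
        rows, cols = np.nonzero(mask.labels)
        for r, c in zip(rows, cols):
            sub = extract_subvolume(cube, (r, c), window)
            blocks.append(sub.values)
            labels.append(int(mask.labels[r, c]))
            sids.append(cube.subject_id)
            centers.append((r, c))
    b = wavelengths.n_bands if wavelengths else 0
    return SubVolumeDataset(
        np.asarray(blocks, dtype=np.float32).reshape(len(blocks), window, window, b),
        np.asarray(labels, dtype=np.int64),
        np.asarray(sids, dtype=object),
        np.asarray(centers, dtype=np.int64).reshape(len(centers), 2),
        class_set or TissueClassSet(),
        wavelengths or WavelengthGrid.default(),
        normalization,
    )


def svm_features(sub: SubVolume | np.ndarray) -> np.ndarray:
    """Reduce a w x w x B sub-volume to one value per wavelength (length B).

    The feature vector is the center pixel's spectrum — the relative absorption
    at each wavelength for the pixel being classified. For structures thinner
    than the window (nerves are one or two pixels wide) any spatial pooling
    drowns the minority spectrum in its neighborhood, so the center spectrum is
    the reduction that preserves the class signal while yielding exactly one
    dimension per wavelength. Accepts a single sub-volume or an
    (n x w x w x B) batch.
    """
    values = sub.values if isinstance(sub, SubVolume) else np.asarray(sub)
    if values.ndim == 3:
        half = values.shape[0] // 2
        return values[half, half, :].astype(np.float64)
    if values.ndim == 4:
        half = values.shape[1] // 2
        return values[:, half, half, :].astype(np.float64)
    raise ValueError("expected a w x w x B sub-volume or an n x w x w x B batch")


def class_spectral_stats(dataset: SubVolumeDataset) -> pd.DataFrame:
    """Per-class mean curve and per-band SD of the center-pixel spectra.

    Returns a tidy frame (class, wavelength_nm, mean, sd), the numeric backing of
    per-class spectral-distribution panels with or without SNV. Classes with no
    samples are simply absent.
    """
    half = dataset.window // 2
    center_curves = dataset.values[:, half, half, :].astype(np.float64)
    records = []
    for code in dataset.class_set.codes:
        sel = dataset.labels == code
        if not sel.any():
            continue
        curves = center_curves[sel]
        records.append(
            pd.DataFrame(
                {
                    "class": dataset.class_set.label(code),
                    "wavelength_nm": dataset.wavelengths.values,
                    "mean": curves.mean(axis=0),
                    "sd": curves.std(axis=0),
                }
            )
        )
    if not records:
        raise ValueError("dataset has no samples in any class")
    return pd.concat(records, ignore_index=True)
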