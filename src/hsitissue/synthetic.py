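"""Synthetic annotated hyperspectral surgical scenes.

In vivo hypercubes of a dissected neck field are hard to obtain and rarely
shareable, so this module generates cohorts of synthetic subjects that reproduce
the *statistical structure* of such data — which is what the downstream pipeline
actually exercises:

* smooth class-specific mean spectral curves with band-correlated intra-class
  deviation, where muscle, nerve and fat are deliberately the most similar classes
  and vein and skin the most dissimilar tissues;
* per-pixel multiplicative gain and additive offset (illumination-geometry
  effects) — exactly the affine family that SNV normalization cancels;
* a "metal" class with occasional saturating specular spikes, giving it by far
  the largest spectral variance;
* severe class imbalance, with nerves as the thinnest curvilinear structures;
* between-subject spectral shifts, the dominant source of intra-class variation,
  so leave-one-subject-out evaluation is genuinely harder than a random split.

Mean curves are sums of a few Gaussian bumps over 500-1000 nm. They are package
defaults constrained by the ordinal relations above; no numeric curve is claimed
to match any particular tissue measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import (
    AnnotationMask,
    HSICube,
    SpectralCurve,
    TissueClassSet,
    WavelengthGrid,
)


class ConfigError(ValueError):
    """Scene configuration cannot be realized."""


def _bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


@dataclass
class SpectralClassModel:
    """Generative spectral model for one class.

    A sampled curve is ``gain * (mean + subject_shift + smooth_deviation) + offset
    + noise`` with ``gain`` positive around 1 and ``offset`` around 0; for metal,
    with probability ``specular_prob`` a large positive specular plateau replaces
    the curve shape entirely.
    """

    label: str
    mean_curve: SpectralCurve
    smooth_deviation_scale: float = 0.0
    gain_sd: float = 0.0
    offset_sd: float = 0.0
    noise_sd: float = 0.0
    specular_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("smooth_deviation_scale", "gain_sd", "offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.specular_prob <= 1.0:
            raise ConfigError("specular_prob must be in [0, 1]")


_N_DEV_BUMPS = 6  # band-correlated deviation basis size


def _smooth_basis(grid: WavelengthGrid, width: float = 0.14) -> np.ndarray:
    """Gaussian bump basis (K x B) used for band-correlated random deviations."""
    t = (grid.values - grid.values[0]) / (grid.values[-1] - grid.values[0])
    centers = np.linspace(0.05, 0.95, _N_DEV_BUMPS)
    return np.stack([_bump(t, c, width) for c in centers])


def default_class_models(
    grid: WavelengthGrid | None = None,
    nerve_muscle_similarity: float = 0.0,
) -> dict:
    """The seven default class models, keyed by label.

    ``nerve_muscle_similarity`` is a confusability dial in [0, 1]: it blends the
    nerve mean curve toward the muscle mean curve, making the hardest class pair
    harder still. 0 keeps the default curves.
    """
    grid = grid or WavelengthGrid.default()
    t = (grid.values - grid.values[0]) / (grid.values[-1] - grid.values[0])

    means = {
        "muscle": 0.55 + 0.25 * _bump(t, 0.35, 0.12) + 0.15 * _bump(t, 0.75, 0.20),
        "nerve": 0.55 + 0.22 * _bump(t, 0.38, 0.13) + 0.17 * _bump(t, 0.72, 0.20),
        "fat": 0.48 + 0.30 * _bump(t, 0.30, 0.14) + 0.10 * _bump(t, 0.80, 0.17),
        "artery": 0.45 + 0.50 * _bump(t, 0.18, 0.08) + 0.25 * _bump(t, 0.55, 0.12),
        "vein": 0.25 + 0.70 * _bump(t, 0.90, 0.30),
        "skin": 1.10 - 0.70 * _bump(t, 0.55, 0.35),
        "metal": 1.30 + 0.20 * _bump(t, 0.50, 0.60),
    }
    if not 0.0 <= nerve_muscle_similarity <= 1.0:
        raise ConfigError("nerve_muscle_similarity must be in [0, 1]")
    if nerve_muscle_similarity:
        s = nerve_muscle_similarity
        means["nerve"] = (1 - s) * means["nerve"] + s * means["muscle"]

    tissue_kwargs = dict(
        smooth_deviation_scale=0.02, gain_sd=0.08, offset_sd=0.05, noise_sd=0.015
    )
    models = {
        label: SpectralClassModel(label, SpectralCurve(mean, grid), **tissue_kwargs)
        for label, mean in means.items()
        if label != "metal"
    }
    models["metal"] = SpectralClassModel(
        "metal",
        SpectralCurve(means["metal"], grid),
        smooth_deviation_scale=0.06,
        gain_sd=0.25,
        offset_sd=0.10,
        noise_sd=0.05,
        specular_prob=0.35,
    )
    return models


def sample_curves(
    model: SpectralClassModel,
    subject_shift: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` curves (n x B) from a class model given a per-subject shift."""
    grid = model.mean_curve.wavelengths
    b = grid.n_bands
    basis = _smooth_basis(grid)
    gain = np.exp(rng.normal(0.0, model.gain_sd, size=(n, 1)))
    offset = rng.normal(0.0, model.offset_sd, size=(n, 1))
    coefs = rng.normal(0.0, 1.0, size=(n, _N_DEV_BUMPS))
    deviation = model.smooth_deviation_scale * coefs @ basis
    noise = rng.normal(0.0, model.noise_sd, size=(n, b))
    curves = gain * (model.mean_curve.values + subject_shift + deviation) + offset + noise

    if model.specular_prob > 0:
        specular = rng.random(n) < model.specular_prob
        if specular.any():
            t = (grid.values - grid.values[0]) / (grid.values[-1] - grid.values[0])
            amp = rng.uniform(2.5, 4.0, size=(n, 1))
            plateau = amp * (0.8 + 0.2 * _bump(t, 0.5, 0.4))
            curves[specular] = plateau[specular] + noise[specular]
    return curves


def sample_curve(
    model: SpectralClassModel,
    subject_shift: SpectralCurve | np.ndarray | None,
    rng: np.random.Generator,
) -> SpectralCurve:
    """Draw a single curve; see :func:`sample_curves`."""
    grid = model.mean_curve.wavelengths
    shift = np.zeros(grid.n_bands) if subject_shift is None else np.asarray(
        subject_shift.values if isinstance(subject_shift, SpectralCurve) else subject_shift
    )
    return SpectralCurve(sample_curves(model, shift, 1, rng)[0], grid)


@dataclass
class SceneConfig:
    """Geometry, spectral models and annotation policy for one synthetic cohort.

    Defaults give a desk-scale 64 x 64 scene; the full-resolution 640 x 476 frame
    of the camera is supported but not the default. Nerves are always the
    thinnest structures (``nerve_width <= vessel_width``).
    """

    height: int = 64
    width: int = 64
    n_bands: int = 100
    wavelength_start: float = 500.0
    wavelength_stop: float = 1000.0
    vessel_width: int = 4
    nerve_width: int = 1
    subject_effect_sd: float = 0.022
    nerve_muscle_similarity: float = 0.6
    annotation_erosion: int = 1
    annotation_fraction: float = 0.25
    min_annotated_per_class: int = 40
    max_annotated_per_class: int | None = 400
    seed: int = 0
    class_models: dict | None = None
    class_set: TissueClassSet = field(default_factory=TissueClassSet)

    def __post_init__(self) -> None:
        if self.nerve_width > self.vessel_width:
            raise ConfigError("nerves must be the thinnest structures (nerve_width <= vessel_width)")
        if self.height < 32 or self.width < 32:
            raise ConfigError("scene must be at least 32 x 32 to place all seven classes")
        if not 0 < self.annotation_fraction <= 1:
            raise ConfigError("annotation_fraction must be in (0, 1]")

    @property
    def wavelengths(self) -> WavelengthGrid:
        return WavelengthGrid.default(self.n_bands, self.wavelength_start, self.wavelength_stop)

    def models(self) -> dict:
        if self.class_models is not None:
            return self.class_models
        return default_class_models(self.wavelengths, self.nerve_muscle_similarity)

    def zero_variability(self) -> "SceneConfig":
        """A copy with every stochastic spectral scale set to 0 (separability dial).

        Classes then emit exactly their mean curves, so any reasonable classifier
        should reach per-class sensitivity ~1; used as a pipeline smoke test."""
        models = {
            label: replace(
                m,
                smooth_deviation_scale=0.0,
                gain_sd=0.0,
                offset_sd=0.0,
                noise_sd=0.0,
                specular_prob=0.0,
            )
            for label, m in self.models().items()
        }
        return replace(self, class_models=models, subject_effect_sd=0.0)


@dataclass
class SyntheticSubject:
    """One generated subject: hypercube, sparse annotation mask, dense truth."""

    cube: HSICube
    mask: AnnotationMask
    subject_id: str
    region_labels: np.ndarray | None = None  # dense ground truth, H x W


def _render_regions(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Dense class-code layout: skin background, fat margin, muscle block,
    artery/nerve/vein as jittered sinusoidal tubes, metal bar."""
    h, w = config.height, config.width
    cs = config.class_set
    labels = np.full((h, w), cs.code("skin"), dtype=np.uint8)

    fat_top = int(0.12 * h) + rng.integers(-1, 2)
    fat_bot = int(0.28 * h) + rng.integers(-1, 2)
    labels[fat_top:fat_bot, :] = cs.code("fat")

    mus_top, mus_bot = fat_bot, int(0.85 * h)
    mus_l, mus_r = int(0.08 * w), int(0.92 * w)
    labels[mus_top:mus_bot, mus_l:mus_r] = cs.code("muscle")

    rows = np.arange(mus_top, mus_bot)
    period = h * (0.9 + 0.2 * rng.random())
    amp = 0.04 * w

    def tube(center_frac: float, width: int, code: int, phase: float) -> None:
        centers = center_frac * w + amp * np.sin(2 * np.pi * rows / period + phase)
        half = width / 2.0
        for r, c in zip(rows, centers):
            lo = int(np.floor(c - half + 0.5))
            hi = lo + width
            lo, hi = max(lo, mus_l), min(hi, mus_r)
            labels[r, lo:hi] = code

    phases = rng.uniform(0, 2 * np.pi, size=3)
    tube(0.32, config.vessel_width, cs.code("artery"), phases[0])
    tube(0.58, config.vessel_width, cs.code("vein"), phases[1])
    tube(0.45, config.nerve_width, cs.code("nerve"), phases[2])  # in the bundle

    met_top, met_bot = int(0.88 * h), int(0.97 * h)
    met_l, met_r = int(0.55 * w), int(0.95 * w)
    labels[met_top:met_bot, met_l:met_r] = cs.code("metal")
    return labels


def _annotate(config: SceneConfig, regions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sparse annotation: eroded core of each region, subsampled.

    Emulates conservative manual annotation, where only pixels the annotator is
    certain of are labeled; thin structures whose core erodes away keep their
    full region instead."""
    mask = np.zeros_like(regions)
    for code in config.class_set.codes:
        region = regions == code
        if not region.any():
            continue
        core = region
        if config.annotation_erosion > 0:
            eroded = ndimage.binary_erosion(region, iterations=config.annotation_erosion)
            if eroded.any():
                core = eroded
        rr, cc = np.nonzero(core)
        n = rr.size
        keep = max(1, int(round(config.annotation_fraction * n)))
        # thin structures (nerves, vessels) are annotated along their whole
        # length in practice, so a floor keeps them from vanishing
        keep = max(keep, min(n, config.min_annotated_per_class))
        if config.max_annotated_per_class is not None:
            keep = min(keep, config.max_annotated_per_class)
        idx = rng.choice(n, size=keep, replace=False) if keep < n else np.arange(n)
        mask[rr[idx], cc[idx]] = code
    return mask


def make_subject(config: SceneConfig, subject_index: int) -> SyntheticSubject:
    """Generate one subject, deterministic given (config.seed, subject_index)."""
    ss = np.random.SeedSequence([config.seed, subject_index])
    rng_geom, rng_shift, rng_pix, rng_ann = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    grid = config.wavelengths
    models = config.models()
    regions = _render_regions(config, rng_geom)
    present = set(np.unique(regions))
    missing = [config.class_set.label(c) for c in config.class_set.codes if c not in present]
    if missing:
        raise ConfigError(f"scene too small to place classes: {missing}")

    basis = _smooth_basis(grid, width=0.18)
    shifts = {
        label: config.subject_effect_sd
        * rng_shift.normal(0.0, 1.0, size=_N_DEV_BUMPS) @ basis
        for label in sorted(models)
    }

    data = np.empty((config.height, config.width, grid.n_bands), dtype=np.float32)
    for code in config.class_set.codes:
        label = config.class_set.label(code)
        rr, cc = np.nonzero(regions == code)
        curves = sample_curves(models[label], shifts[label], rr.size, rng_pix)
        data[rr, cc, :] = curves.astype(np.float32)

    mask = _annotate(config, regions, rng_ann)
    subject_id = f"subject_{subject_index + 1:02d}"
    return SyntheticSubject(
        cube=HSICube(data, grid, subject_id=subject_id),
        mask=AnnotationMask(mask, config.class_set),
        subject_id=subject_id,
        region_labels=regions,
    )


def make_cohort(config: SceneConfig, n_subjects: int = 8) -> list:
    """Generate a cohort of subjects with independent between-subject shifts.

    At least 2 subjects are required (leave-one-subject-out cross-validation is
    undefined otherwise). Deterministic given ``config.seed``.
    """
    if n_subjects < 2:
        raise ConfigError("a cohort needs >= 2 subjects for leave-one-out evaluation")
    return [make_subject(config, i) for i in range(n_subjects)]
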