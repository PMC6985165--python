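"""Pattern and luminance camouflage from photographs: granularity analysis
and photo-centred repeated-measures effect sizes.

Fish likely judge luminance and pattern with their double cones, which peak
in the green, so regions of interest are analysed on the image's green
channel. Each region yields three quantities: *pattern contrast* (total
energy of the spatial-frequency spectrum), *pattern size* (the octave scale
holding peak energy, in pixel periods) and *total reflectance* (mean masked
luminance). Differences between an animal and each background type are
summarised as Cohen's d for repeated-measures designs after log
transformation and per-photo pairing (each photo contributes one paired
difference, removing between-photo lighting differences); |d| < 0.8 is read
as a pattern/luminance "match".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

ITEM_TYPES = (
    "green_stomatopod",
    "sandy_stomatopod",
    "sand",
    "rubble",
    "thalassia_clean",
    "thalassia_silt",
)

#: Minimum number of masked pixels for a meaningful granularity spectrum.
MIN_MASKED_PIXELS = 64 * 64

#: |d| below this is a pattern/luminance match.
EFFECT_SIZE_MATCH_THRESHOLD = 0.8

#: Offset added before log-transforming (pattern energies can be ~0).
LOG_EPS = 1e-6


@dataclass
class ImageRegion:
    """Green-channel intensities in [0, 1] with a boolean region mask."""

    pixels: np.ndarray
    mask: np.ndarray
    photo_id: str = ""
    item_type: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("region pixels must be a 2-D array")
        if self.mask.shape != self.pixels.shape:
            raise ValueError("mask and pixels must have the same shape")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixel intensities must lie in [0, 1]")
        if self.item_type and self.item_type not in ITEM_TYPES:
            raise ValueError(f"unknown item_type {self.item_type!r}; expected one of {ITEM_TYPES}")

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


@dataclass
class GranularitySpectrum:
    """Energy per octave spatial scale (pixel period)."""

    scales: np.ndarray
    energies: np.ndarray

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if np.any(self.energies < 0):
            raise ValueError("energies must be non-negative")


@dataclass
class PatternSummary:
    """(pattern contrast, pattern size, total reflectance) for one region."""

    pattern_contrast: float
    pattern_size: float
    total_reflectance: float
    photo_id: str = ""
    item_type: str = ""
    degenerate_peak: bool = False

    def value(self, variable: str) -> float:
        if variable not in ("pattern_contrast", "pattern_size", "total_reflectance"):
            raise ValueError(f"unknown pattern variable {variable!r}")
        return getattr(self, variable)


@dataclass
class PairedSamples:
    """Per-photo paired (animal, background) values on the log scale."""

    photo_ids: list[str]
    animal: np.ndarray
    background: np.ndarray
    variable: str
    contrast_pair: tuple[str, str]

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if len(self.animal) != len(self.background) or len(self.animal) != len(self.photo_ids):
            raise ValueError("paired samples must align one animal and one background value per photo")

    @property
    def differences(self) -> np.ndarray:
        return self.animal - self.background


@dataclass
class EffectSize:
    d: float
    contrast_pair: tuple[str, str]
    variable: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.d):
            raise ValueError("effect size must be finite")


def _srgb_to_linear(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def extract_region(
    image: str | Path | np.ndarray,
    mask: np.ndarray,
    photo_id: str = "",
    item_type: str = "",
    linearize: bool = True,
) -> ImageRegion:
    """Green channel of an RGB image, scaled to [0, 1], with a region mask.

    ``image`` may be a PNG/TIFF path or an (H, W, 3[+alpha]) array. By
    default 8/16-bit files are gamma-decoded from sRGB to linear intensity;
    pass ``linearize=False`` for images already stored linearly.
    """
    if isinstance(image, (str, Path)):
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(Path(image)))
    else:
        arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"expected an RGB image, got shape {arr.shape}")
    green = arr[..., 1].astype(float)
    if np.issubdtype(arr.dtype, np.integer):
        green = green / np.iinfo(arr.dtype).max
    if green.max() > 1 + 1e-9 or green.min() < 0:
        raise ValueError("float image intensities must lie in [0, 1]")
    if linearize:
        green = _srgb_to_linear(green)
    mask = np.asarray(mask, dtype=bool)
    region = ImageRegion(pixels=green, mask=mask, photo_id=photo_id, item_type=item_type)
    if region.n_masked < MIN_MASKED_PIXELS:
        raise ValueError(
            f"mask covers {region.n_masked} pixels; granularity needs >= {MIN_MASKED_PIXELS}"
        )
    return region


def _octave_scales(height: int, width: int) -> np.ndarray:
    smax = min(height, width) // 2
    scales = []
    s = 2
    while s <= smax:
        scales.append(s)
        s *= 2
    if not scales:
        raise ValueError(f"region {height}x{width} too small for any octave scale")
    return np.asarray(scales, dtype=float)


def granularity_spectrum(region: ImageRegion) -> GranularitySpectrum:
    """Fourier pattern-energy spectrum over octave spatial scales.

    The masked region is mean-subtracted (masked-out pixels filled with the
    region mean, i.e. zero after subtraction), zero-padded to a power-of-two
    frame, and transformed. The energy at octave scale s is the sum of
    squared Fourier amplitudes over the annulus of spatial periods
    [s/sqrt(2), s*sqrt(2)), normalised by the masked-pixel count so that the
    energies sum to (approximately) the pixel variance within the mask.
    """
    if region.n_masked < MIN_MASKED_PIXELS:
        raise ValueError(
            f"mask covers {region.n_masked} pixels; granularity needs >= {MIN_MASKED_PIXELS}"
        )
    h, w = region.pixels.shape
    mean = region.pixels[region.mask].mean()
    x = np.where(region.mask, region.pixels - mean, 0.0)

    hp = 1 << (h - 1).bit_length()
    wp = 1 << (w - 1).bit_length()
    frame = np.zeros((hp, wp))
    frame[:h, :w] = x

    power = np.abs(np.fft.fft2(frame)) ** 2
    fy = np.fft.fftfreq(hp)[:, None]
    fx = np.fft.fftfreq(wp)[None, :]
    fr = np.sqrt(fx * fx + fy * fy)

    scales = _octave_scales(h, w)
    energies = np.empty(len(scales))
    norm = (hp * wp) * region.n_masked  # Parseval: sum|F|^2 / Nfft = sum x^2
    root2 = np.sqrt(2.0)
    for k, s in enumerate(scales):
        f_lo = 1.0 / (s * root2)  # longest period in the annulus (exclusive)
        f_hi = root2 / s  # shortest period (inclusive)
        sel = (fr > f_lo) & (fr <= f_hi)
        energies[k] = power[sel].sum() / norm
    return GranularitySpectrum(scales=scales, energies=energies)


def pattern_summary(g: GranularitySpectrum, region: ImageRegion) -> PatternSummary:
    """Reduce a granularity spectrum to (contrast, size, reflectance).

    Pattern contrast is the total energy; pattern size is the scale of peak
    energy (ties broken toward the larger scale); total reflectance is the
    mean masked intensity. A region with essentially no spatial variation is
    flagged as a degenerate peak.
    """
    total = float(g.energies.sum())
    degenerate = total < 1e-9
    if degenerate:
        size = float(g.scales[-1])
        logger.info("degenerate pattern peak (no spatial variation) in %r", region.item_type)
    else:
        best = g.energies.max()
        candidates = np.flatnonzero(np.isclose(g.energies, best, rtol=1e-12, atol=0.0))
        if len(candidates) > 1:
            logger.info("tied peak energies at scales %s; taking the largest", g.scales[candidates])
        size = float(g.scales[candidates[-1]])
    return PatternSummary(
        pattern_contrast=total,
        pattern_size=size,
        total_reflectance=float(region.pixels[region.mask].mean()),
        photo_id=region.photo_id,
        item_type=region.item_type,
        degenerate_peak=degenerate,
    )


def photo_centred_effects(
    summaries: list[PatternSummary],
    animal_type: str,
    background_type: str,
    variable: str,
    eps: float = LOG_EPS,
) -> PairedSamples:
    """Per-photo paired log values of one variable for an animal/background pair.

    Each variable is log(x + eps)-transformed. Within every photo the animal
    value (averaged if several regions) is paired with the mean value over
    that photo's regions of ``background_type``. Photos lacking either item
    are excluded (logged). Pairing within photos removes any per-photo
    additive effect on the log scale, playing the role of a photo random
    effect.
    """
    by_photo: dict[str, dict[str, list[float]]] = {}
    for s in summaries:
        by_photo.setdefault(s.photo_id, {}).setdefault(s.item_type, []).append(
            float(np.log(s.value(variable) + eps))
        )
    photo_ids, animal_vals, bg_vals = [], [], []
    for pid in sorted(by_photo):
        items = by_photo[pid]
        if animal_type not in items or background_type not in items:
            logger.info("photo %r lacks %r or %r; excluded from pairing", pid, animal_type, background_type)
            continue
        photo_ids.append(pid)
        animal_vals.append(np.mean(items[animal_type]))
        bg_vals.append(np.mean(items[background_type]))
    return PairedSamples(
        photo_ids=photo_ids,
        animal=np.array(animal_vals),
        background=np.array(bg_vals),
        variable=variable,
        contrast_pair=(animal_type, background_type),
    )


def cohens_d_rm(pairs: PairedSamples, variant: str = "d_av") -> EffectSize:
    """Cohen's d for repeated-measures designs from per-photo paired values.

    ``d_av`` (default): mean paired difference divided by the average of the
    two conditions' across-photo standard deviations. ``d_z``: mean paired
    difference divided by the standard deviation of the differences.
    """
    n = len(pairs.photo_ids)
    if n < 3:
        raise ValueError(f"need >= 3 paired photos to estimate an effect size, got {n}")
    diff = pairs.differences
    mean_diff = diff.mean()
    if variant == "d_av":
        sd = 0.5 * (pairs.animal.std(ddof=1) + pairs.background.std(ddof=1))
    elif variant == "d_z":
        sd = diff.std(ddof=1)
    else:
        raise ValueError(f"unknown Cohen's d variant {variant!r}")
    if sd == 0:
        d = 0.0 if mean_diff == 0 else np.inf
        if not np.isfinite(d):
            raise ValueError("zero spread with non-zero mean difference; effect size undefined")
    else:
        d = mean_diff / sd
    return EffectSize(d=float(d), contrast_pair=pairs.contrast_pair, variable=pairs.variable)


def match_by_effect_size(e: EffectSize, threshold: float = EFFECT_SIZE_MATCH_THRESHOLD) -> bool:
    """|d| strictly below the threshold counts as a background match."""
    return abs(e.d) < threshold
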