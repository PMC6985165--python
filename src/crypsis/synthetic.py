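"""Synthetic spectra, illuminants and scene images with known ground truth.

The study's raw reflectance spectra and field photographs are not publicly
deposited, so this module generates stand-ins that reproduce their
*structure*: smooth reflectance curves with UV tails and long-wavelength
plateaus; a tropical-reef illuminant whose spectrum narrows with depth
(attenuation minimum near 480 nm, rising toward the UV and strongly beyond
600 nm); and textured scene images with controllable dominant pattern scale,
RMS contrast and mean luminance. Every generator is seed-deterministic and
scene generators return a machine-readable ground-truth record alongside
the data.

Scene presets are named after the comparisons they emulate: the purple,
short-wavelength-reflecting meral-spot colours are chromatically distinct
from every background (mismatch presets), while sandy body colouration
shares the rubble/sand spectral family and differs mainly in overall
intensity (match preset), which the log-form receptor-noise model treats as
achromatic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .receptor import catch_vector, receptor_noise, rnl_distance
from .spectra import CANONICAL_GRID, Spectrum, WavelengthGrid
from .visual import IlluminantModel, VisualSystem, build_fish_system, irradiance_at_depth


@dataclass(frozen=True)
class SpectrumRecipe:
    """Generative description of one reflectance class.

    ``peaks`` are (centre nm, width nm, amplitude) Gaussians added to the
    baseline; ``plateau_above``/``plateau_level`` emulate the reflectance
    plateau beyond ~700 nm common to these spectra; ``noise_sd`` is per-point
    multiplicative lognormal measurement noise; ``jitter_sd`` is per-sample
    lognormal jitter applied to the baseline and peak amplitudes (the
    between-individual variation within a colour class).
    """

    baseline: float = 0.1
    peaks: tuple[tuple[float, float, float], ...] = ()
    plateau_above: float = 700.0
    plateau_level: float = 0.0
    noise_sd: float = 0.0
    jitter_sd: float = 0.0
    scale: float = 1.0

    def template_values(self, grid: WavelengthGrid = CANONICAL_GRID) -> np.ndarray:
        """The noiseless expected spectrum of this recipe."""
        wl = grid.wavelengths
        vals = np.full_like(wl, float(self.baseline))
        for centre, width, amp in self.peaks:
            vals = vals + amp * np.exp(-0.5 * ((wl - centre) / width) ** 2)
        if self.plateau_level > 0:
            vals = vals + self.plateau_level / (1.0 + np.exp(-(wl - self.plateau_above) / 15.0))
        return np.clip(vals * self.scale, 0.0, None)


def make_reflectance(
    recipe: SpectrumRecipe,
    seed: int | np.random.Generator | None = None,
    label: str = "",
    grid: WavelengthGrid = CANONICAL_GRID,
) -> Spectrum:
    """Draw one reflectance spectrum from a recipe (seed-deterministic)."""
    rng = np.random.default_rng(seed)
    wl = grid.wavelengths
    baseline = recipe.baseline
    if recipe.jitter_sd > 0:
        baseline = baseline * rng.lognormal(0.0, recipe.jitter_sd)
    vals = np.full_like(wl, float(baseline))
    for centre, width, amp in recipe.peaks:
        a = amp * rng.lognormal(0.0, recipe.jitter_sd) if recipe.jitter_sd > 0 else amp
        vals = vals + a * np.exp(-0.5 * ((wl - centre) / width) ** 2)
    if recipe.plateau_level > 0:
        lvl = recipe.plateau_level
        if recipe.jitter_sd > 0:
            lvl = lvl * rng.lognormal(0.0, recipe.jitter_sd)
        vals = vals + lvl / (1.0 + np.exp(-(wl - recipe.plateau_above) / 15.0))
    vals = vals * recipe.scale
    if recipe.noise_sd > 0:
        vals = vals * rng.lognormal(0.0, recipe.noise_sd, size=vals.shape)
    return Spectrum(wl, np.clip(vals, 0.0, None), kind="reflectance", label=label)


# ---------------------------------------------------------------------------
# Reflectance templates for the study's colour classes. Shapes follow the
# qualitative descriptions: all classes have some UV reflectance, tend to
# rise toward 600-700 nm, and plateau beyond 700 nm; meral-spot colours are
# purple (short-wavelength reflecting); vegetation is green-peaked with a
# strong red-edge plateau; sand/rubble rise steadily toward long wavelengths.
# ---------------------------------------------------------------------------
TEMPLATES: dict[str, SpectrumRecipe] = {
    # meral spot centres: purple (UV/short-wave peak plus long-wave rise),
    # lighter overall than seagrass but darker than rubble; rubble-collected
    # animals have lighter (higher total reflectance) spots
    "meral_centre_rubble": SpectrumRecipe(
        baseline=0.07, peaks=((400.0, 55.0, 0.06),), plateau_above=690.0,
        plateau_level=0.22, scale=1.4, jitter_sd=0.12, noise_sd=0.01,
    ),
    "meral_centre_seagrass": SpectrumRecipe(
        baseline=0.07, peaks=((400.0, 55.0, 0.06),), plateau_above=690.0,
        plateau_level=0.22, scale=0.8, jitter_sd=0.12, noise_sd=0.01,
    ),
    # pale ring around the meral spot: UV-reflective, brighter than seagrass,
    # darker than rubble except in the UV
    "meral_ring": SpectrumRecipe(
        baseline=0.12, peaks=((380.0, 45.0, 0.15),), plateau_above=700.0,
        plateau_level=0.10, jitter_sd=0.10, noise_sd=0.01,
    ),
    # seagrasses: green peak near 550 nm, low UV, red-edge plateau
    "thalassia": SpectrumRecipe(
        baseline=0.02, peaks=((550.0, 40.0, 0.035),), plateau_above=705.0,
        plateau_level=0.12, jitter_sd=0.12, noise_sd=0.01,
    ),
    "syringodium": SpectrumRecipe(
        baseline=0.025, peaks=((555.0, 45.0, 0.03),), plateau_above=705.0,
        plateau_level=0.11, jitter_sd=0.12, noise_sd=0.01,
    ),
    # substrates: bright, reflectance rising steadily toward long wavelengths
    "rubble": SpectrumRecipe(
        baseline=0.18, peaks=((700.0, 130.0, 0.15),), plateau_above=700.0,
        plateau_level=0.05, jitter_sd=0.12, noise_sd=0.01,
    ),
    "sand": SpectrumRecipe(
        baseline=0.18, peaks=((700.0, 130.0, 0.15),), plateau_above=700.0,
        plateau_level=0.05, scale=1.8, jitter_sd=0.12, noise_sd=0.01,
    ),
    # dorsal body colours
    # green body colour: similar green peak to the seagrasses but less
    # saturated (higher baseline, weaker red edge), a supra-threshold
    # chromatic difference for the fish receiver
    "green_stomatopod": SpectrumRecipe(
        baseline=0.05, peaks=((555.0, 55.0, 0.05),), plateau_above=705.0,
        plateau_level=0.08, jitter_sd=0.12, noise_sd=0.01,
    ),
    "sandy_stomatopod": SpectrumRecipe(
        baseline=0.18, peaks=((700.0, 130.0, 0.15),), plateau_above=700.0,
        plateau_level=0.05, scale=1.3, jitter_sd=0.12, noise_sd=0.01,
    ),
}


def make_illuminant(preset: str = "reef_surface", grid: WavelengthGrid = CANONICAL_GRID) -> IlluminantModel:
    """Deterministic tropical-reef illuminant model.

    The surface spectrum is a smooth daylight-like hump; the diffuse
    attenuation K(lambda) has its minimum near 480 nm and rises toward the
    UV and strongly beyond 600 nm, so the spectrum narrows and blue-shifts
    with depth.
    """
    if preset != "reef_surface":
        raise ValueError(f"unknown illuminant preset {preset!r}")
    wl = grid.wavelengths
    surface = 0.15 + np.exp(-0.5 * ((wl - 560.0) / 160.0) ** 2)
    dev = np.abs(wl - 480.0)
    k = np.where(
        wl >= 480.0,
        0.025 + 0.55 * (dev / 320.0) ** 2.5,
        0.025 + 0.20 * (dev / 180.0) ** 2,
    )
    return IlluminantModel(
        surface=Spectrum(wl, surface, kind="irradiance", label="reef_surface"),
        attenuation=Spectrum(wl, k, kind="irradiance", label="reef_attenuation"),
    )


@dataclass(frozen=True)
class SceneRecipe:
    """One chromatic comparison: an animal colour class against a background class."""

    name: str
    animal_template: str
    background_template: str
    n_animal: int = 10
    n_background: int = 10
    intended: str = "mismatch"  # ground-truth label: match | mismatch
    chromatic_offset_nm: float = 0.0  # shift applied to animal peak centres
    luminance_scale: float = 1.0  # intensity multiplier on the animal class
    depth_m: float = 1.0

    def __post_init__(self) -> None:
        if self.n_animal < 2 or self.n_background < 2:
            raise ValueError("group sizes must be >= 2 to enter the statistics")
        if self.intended not in ("match", "mismatch"):
            raise ValueError(f"intended must be 'match' or 'mismatch', got {self.intended!r}")


#: Presets named after the comparisons they emulate. Sample sizes follow the
#: study design (30 rubble-collected and 24 seagrass-collected meral spots,
#: 13 meral rings, 8-10 animals per body-colour class, 10 background samples
#: per type).
SCENE_PRESETS: dict[str, SceneRecipe] = {
    "meral_vs_seagrass": SceneRecipe(
        name="meral_vs_seagrass", animal_template="meral_centre_seagrass",
        background_template="thalassia", n_animal=24, n_background=10, intended="mismatch",
    ),
    "meral_vs_rubble": SceneRecipe(
        name="meral_vs_rubble", animal_template="meral_centre_rubble",
        background_template="rubble", n_animal=30, n_background=10, intended="mismatch",
    ),
    "green_vs_thalassia": SceneRecipe(
        name="green_vs_thalassia", animal_template="green_stomatopod",
        background_template="thalassia", n_animal=8, n_background=10, intended="mismatch",
    ),
    "sandy_vs_rubble": SceneRecipe(
        name="sandy_vs_rubble", animal_template="sandy_stomatopod",
        background_template="rubble", n_animal=10, n_background=10, intended="match",
    ),
    "sandy_vs_sand": SceneRecipe(
        name="sandy_vs_sand", animal_template="sandy_stomatopod",
        background_template="sand", n_animal=10, n_background=10, intended="match",
    ),
}


def _offset_recipe(recipe: SpectrumRecipe, offset_nm: float, scale: float) -> SpectrumRecipe:
    peaks = tuple((c + offset_nm, w, a) for c, w, a in recipe.peaks)
    return replace(recipe, peaks=peaks, scale=recipe.scale * scale)


def make_scene_spectra(
    recipe: SceneRecipe,
    seed: int | np.random.Generator | None = None,
    system: VisualSystem | None = None,
    illuminant: IlluminantModel | None = None,
) -> tuple[dict[str, list[Spectrum]], dict]:
    """Draw the two sample groups of a scene plus a ground-truth record.

    The ground truth holds the chromatic distance (JND, for the fish
    receiver under the scene's illuminant and depth) between the *noiseless*
    class templates, and the intended match/mismatch label.
    """
    rng = np.random.default_rng(seed)
    animal_recipe = _offset_recipe(
        TEMPLATES[recipe.animal_template], recipe.chromatic_offset_nm, recipe.luminance_scale
    )
    bg_recipe = TEMPLATES[recipe.background_template]
    animals = [
        make_reflectance(animal_recipe, rng, label=f"{recipe.animal_template}/{i:02d}")
        for i in range(recipe.n_animal)
    ]
    backgrounds = [
        make_reflectance(bg_recipe, rng, label=f"{recipe.background_template}/{i:02d}")
        for i in range(recipe.n_background)
    ]

    system = system or build_fish_system()
    illuminant = illuminant or make_illuminant()
    irr = irradiance_at_depth(illuminant, recipe.depth_m)
    grid = CANONICAL_GRID
    t_animal = Spectrum(grid.wavelengths, animal_recipe.template_values(grid),
                        kind="reflectance", label=f"{recipe.animal_template}/template")
    t_bg = Spectrum(grid.wavelengths, bg_recipe.template_values(grid),
                    kind="reflectance", label=f"{recipe.background_template}/template")
    noise = receptor_noise(system)
    true_jnd = rnl_distance(
        catch_vector(system, t_animal, irr),
        catch_vector(system, t_bg, irr),
        noise,
    )
    ground_truth = {
        "scene": recipe.name,
        "intended": recipe.intended,
        "true_centroid_jnd": float(true_jnd),
        "depth_m": recipe.depth_m,
        "n_animal": recipe.n_animal,
        "n_background": recipe.n_background,
    }
    return (
        {recipe.animal_template: animals, recipe.background_template: backgrounds},
        ground_truth,
    )


# ---------------------------------------------------------------------------
# Textured scene images
# ---------------------------------------------------------------------------

#: Per-item-type texture parameters (dominant period px, RMS contrast, mean
#: luminance) for the photo generator. Green animals share the clean-blade
#: texture family; sandy animals share the sand/rubble family.
TEXTURE_PARAMS: dict[str, tuple[float, float, float]] = {
    "sand": (8.0, 0.06, 0.55),
    "rubble": (16.0, 0.09, 0.45),
    "thalassia_clean": (32.0, 0.025, 0.22),
    "thalassia_silt": (16.0, 0.055, 0.38),
    "green_stomatopod": (32.0, 0.025, 0.22),
    "sandy_stomatopod": (16.0, 0.075, 0.50),
}


def make_texture(
    pattern_period: float,
    pattern_contrast: float,
    mean_luminance: float,
    size: int = 128,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Band-limited noise texture as an RGB float image in [0, 1].

    White noise is filtered in the Fourier domain with a log-Gaussian band
    around the target spatial frequency 1/period, scaled to the requested
    RMS contrast (pixel standard deviation) and mean. The signal lives in
    the green channel; red and blue carry the mean only.
    """
    if pattern_contrast < 0 or not 0 <= mean_luminance <= 1:
        raise ValueError("contrast must be >= 0 and mean luminance in [0, 1]")
    rng = np.random.default_rng(seed)
    if pattern_contrast == 0:
        green = np.full((size, size), mean_luminance)
    else:
        noise = rng.standard_normal((size, size))
        f = np.fft.fft2(noise)
        fy = np.fft.fftfreq(size)[:, None]
        fx = np.fft.fftfreq(size)[None, :]
        fr = np.sqrt(fx * fx + fy * fy)
        f0 = 1.0 / pattern_period
        with np.errstate(divide="ignore"):
            logratio = np.where(fr > 0, np.log2(np.maximum(fr, 1e-12) / f0), np.inf)
        band = np.exp(-0.5 * (logratio / 0.35) ** 2)
        band[0, 0] = 0.0
        tex = np.real(np.fft.ifft2(f * band))
        tex = (tex - tex.mean()) / tex.std()
        green = mean_luminance + pattern_contrast * tex
        green = np.clip(green, 0.0, 1.0)
    img = np.empty((size, size, 3))
    img[..., 0] = mean_luminance
    img[..., 1] = green
    img[..., 2] = mean_luminance
    return img


def _linear_to_srgb(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * np.power(np.maximum(c, 0.0), 1 / 2.4) - 0.055)


def save_texture(image: np.ndarray, path: str | Path) -> None:
    """Write a linear-light RGB float image to PNG with sRGB encoding."""
    import imageio.v3 as iio

    srgb = np.clip(_linear_to_srgb(np.asarray(image, dtype=float)), 0.0, 1.0)
    iio.imwrite(Path(path), (srgb * 255.0 + 0.5).astype(np.uint8))


@dataclass
class ScenePhoto:
    """One synthetic field photo: regions of several item types, sharing a
    per-photo luminance effect."""

    photo_id: str
    regions: dict[str, np.ndarray]  # item_type -> linear green-channel array


def make_scene_photos(
    habitat: str,
    n_photos: int,
    seed: int | np.random.Generator | None = None,
    size: int = 128,
    photo_effect_sd: float = 0.10,
    region_jitter_sd: float = 0.35,
    lum_jitter_sd: float = 0.15,
    texture_params: Mapping[str, tuple[float, float, float]] | None = None,
) -> list[ScenePhoto]:
    """Photo sets emulating the field-photography design.

    ``habitat`` selects the item types present: rubble habitat photos carry
    both animal colour classes plus sand and rubble regions; seagrass
    habitat photos carry the animals plus sand, clean-blade and silty-blade
    regions. Each photo applies one shared lognormal luminance multiplier to
    all its regions (the between-photo effect the paired analysis removes),
    and every region draws its own lognormal jitter on pattern period and
    contrast — real substrate patches vary in grain from photo to photo.
    """
    if habitat == "rubble":
        item_types = ["green_stomatopod", "sandy_stomatopod", "sand", "rubble"]
    elif habitat == "seagrass":
        item_types = ["green_stomatopod", "sandy_stomatopod", "sand", "thalassia_clean", "thalassia_silt"]
    else:
        raise ValueError(f"unknown habitat {habitat!r}")
    params = dict(texture_params or TEXTURE_PARAMS)
    rng = np.random.default_rng(seed)
    photos = []
    for p in range(n_photos):
        mult = rng.lognormal(0.0, photo_effect_sd)
        regions = {}
        for it in item_types:
            period, contrast, lum = params[it]
            period = period * rng.lognormal(0.0, region_jitter_sd)
            contrast = contrast * rng.lognormal(0.0, region_jitter_sd)
            lum = lum * rng.lognormal(0.0, lum_jitter_sd)
            img = make_texture(
                min(period, size / 4.0), contrast * mult, min(lum * mult, 1.0),
                size=size, seed=rng,
            )
            regions[it] = img[..., 1]
        photos.append(ScenePhoto(photo_id=f"{habitat}_{p:03d}", regions=regions))
    return photos
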