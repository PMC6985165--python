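"""Visual systems: receptor sensitivity templates, receiver definitions, and
depth-dependent underwater light.

Two receivers are modelled. The stomatopod *Neogonodactylus oerstedii* has
twelve photoreceptor classes associated with chromatic vision, spanning the
UV to the far red; only abundance-free Weber contrasts are computed for it.
The Picasso triggerfish *Rhinecanthus aculeatus* stands in for a typical
trichromatic reef predator, with cone peaks at 420/480/520 nm, a 1:2:2
(S:M:L) receptor ratio and a Weber fraction of 0.05.

Sensitivity curves are built from the Govardovskii A1 alpha-band visual
pigment template (the field-standard absorbance template); a Gaussian
template is available for closed-form checks. Underwater irradiance follows
Beer-Lambert attenuation: I(lambda, d) = I_surface(lambda) * exp(-K(lambda) * d).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra import CANONICAL_GRID, Spectrum, WavelengthGrid

FISH_PEAKS_NM = (420.0, 480.0, 520.0)
FISH_ABUNDANCES = (1.0, 2.0, 2.0)
FISH_WEBER_FRACTION = 0.05
FISH_INTEGRATION_RANGE = (340.0, 700.0)

STOMATOPOD_INTEGRATION_RANGE = (300.0, 800.0)
# Placeholder peaks: twelve values evenly spanning the UV-to-far-red range of
# the published midband/peripheral sensitivities. Measured curves supplied as
# spectral tables take precedence over these templates.
STOMATOPOD_DEFAULT_PEAKS = tuple(np.linspace(315.0, 700.0, 12))
# Four R8/peripheral UV-short channels, then midband rows 1-4, dorsal (D) and
# proximal (P) tiers, ordered by ascending peak wavelength.
STOMATOPOD_CHANNEL_NAMES = (
    "R1R8", "R2R8", "PrD", "PrP",
    "R1D", "R1P", "R2D", "R2P", "R3D", "R3P", "R4D", "R4P",
)


@dataclass
class ReceptorSensitivity:
    """A named photoreceptor class with its peak-normalised sensitivity curve."""

    name: str
    lambda_max: float
    curve: Spectrum

    def __post_init__(self) -> None:
        if self.curve.kind != "sensitivity":
            raise ValueError(f"receptor curve must have kind 'sensitivity', got {self.curve.kind!r}")
        peak = self.curve.values.max()
        if abs(peak - 1.0) > 1e-9:
            raise ValueError(f"receptor {self.name!r} not peak-normalised (max={peak})")
        wl_at_peak = self.curve.wavelengths[int(np.argmax(self.curve.values))]
        step = float(np.max(np.diff(self.curve.wavelengths)))
        if abs(wl_at_peak - self.lambda_max) > step + 1e-9:
            raise ValueError(
                f"receptor {self.name!r}: curve peaks at {wl_at_peak} nm, "
                f"declared lambda_max {self.lambda_max} nm"
            )


@dataclass
class VisualSystem:
    """An ordered set of receptors plus noise and integration parameters.

    ``abundances`` are the relative receptor numbers eta_i entering the
    receptor-noise model; ``weber_fraction`` is the noise-to-signal ratio nu
    of the most abundant class.
    """

    receptors: list[ReceptorSensitivity]
    integration_range: tuple[float, float]
    abundances: np.ndarray
    weber_fraction: float
    name: str = ""

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        names = [r.name for r in self.receptors]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate receptor names: {names}")
        if len(self.abundances) != len(self.receptors):
            raise ValueError("one abundance per receptor required")
        if np.any(self.abundances <= 0):
            raise ValueError("all receptor abundances must be > 0")
        if self.weber_fraction <= 0:
            raise ValueError("weber_fraction must be > 0")
        lo, hi = self.integration_range
        for r in self.receptors:
            if lo < r.curve.wavelengths[0] or hi > r.curve.wavelengths[-1]:
                raise ValueError(
                    f"integration range ({lo}, {hi}) exceeds support of receptor {r.name!r}"
                )

    @property
    def n_receptors(self) -> int:
        return len(self.receptors)

    @property
    def receptor_names(self) -> list[str]:
        return [r.name for r in self.receptors]


@dataclass
class IlluminantModel:
    """Surface irradiance plus per-metre diffuse attenuation K(lambda), 1/m."""

    surface: Spectrum
    attenuation: Spectrum

    def __post_init__(self) -> None:
        if not np.array_equal(self.surface.wavelengths, self.attenuation.wavelengths):
            raise ValueError("surface and attenuation must share a wavelength grid")
        if np.any(self.attenuation.values < 0):
            raise ValueError("attenuation coefficients must be >= 0")


def _govardovskii_alpha(wl: np.ndarray, lambda_max: float) -> np.ndarray:
    """Govardovskii et al. A1 alpha-band absorbance template."""
    x = lambda_max / wl
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    return 1.0 / (np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D)


def _gaussian_alpha(wl: np.ndarray, lambda_max: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - lambda_max) / sigma) ** 2)


def pigment_template(
    lambda_max: float,
    grid: WavelengthGrid = CANONICAL_GRID,
    name: str | None = None,
    shape: str = "govardovskii",
    sigma: float = 50.0,
) -> ReceptorSensitivity:
    """Build a peak-normalised receptor sensitivity curve from its peak wavelength.

    ``shape`` selects the Govardovskii A1 template (default) or a Gaussian of
    standard deviation ``sigma`` nm (useful for closed-form validation).
    """
    if not 300.0 <= lambda_max <= 720.0:
        raise ValueError(f"lambda_max {lambda_max} nm outside supported range 300-720 nm")
    wl = grid.wavelengths
    if lambda_max < wl[0] or lambda_max > wl[-1]:
        raise ValueError(f"lambda_max {lambda_max} nm outside grid [{wl[0]}, {wl[-1]}]")
    if shape == "govardovskii":
        vals = _govardovskii_alpha(wl, lambda_max)
    elif shape == "gaussian":
        vals = _gaussian_alpha(wl, lambda_max, sigma)
    else:
        raise ValueError(f"unknown template shape {shape!r}")
    vals = vals / vals.max()
    curve = Spectrum(wl, vals, kind="sensitivity", label=name or f"pigment_{lambda_max:g}nm")
    return ReceptorSensitivity(name or f"pigment_{lambda_max:g}nm", float(lambda_max), curve)


def build_fish_system(grid: WavelengthGrid = CANONICAL_GRID, shape: str = "govardovskii") -> VisualSystem:
    """The trichromatic reef-fish receiver (Picasso triggerfish).

    Cone peaks 420 (SWS), 480 (MWS), 520 (LWS) nm; abundances 1:2:2;
    Weber fraction 0.05; integration over 340-700 nm.
    """
    names = ("SWS", "MWS", "LWS")
    receptors = [
        pigment_template(lm, grid, name=n, shape=shape)
        for n, lm in zip(names, FISH_PEAKS_NM)
    ]
    return VisualSystem(
        receptors=receptors,
        integration_range=FISH_INTEGRATION_RANGE,
        abundances=np.array(FISH_ABUNDANCES),
        weber_fraction=FISH_WEBER_FRACTION,
        name="triggerfish",
    )


def build_stomatopod_system(
    lambda_max_list: Sequence[float] | None = None,
    grid: WavelengthGrid = CANONICAL_GRID,
    shape: str = "govardovskii",
) -> VisualSystem:
    """The 12-channel stomatopod receiver used for Weber-contrast modelling.

    Default peaks are evenly spaced placeholders for the published midband
    and peripheral sensitivities; pass measured peaks (or load curves from
    files) to override. Abundances are equal across channels — only Weber
    contrast, which is abundance-free, is computed for this receiver.
    """
    peaks = STOMATOPOD_DEFAULT_PEAKS if lambda_max_list is None else tuple(float(x) for x in lambda_max_list)
    if len(peaks) != 12:
        raise ValueError(f"the stomatopod system needs exactly 12 peaks, got {len(peaks)}")
    if not all(a < b for a, b in zip(peaks, peaks[1:])):
        raise ValueError("stomatopod peaks must be strictly increasing")
    if peaks[0] < 300.0 or peaks[-1] > 720.0:
        raise ValueError("stomatopod peaks must lie within 300-720 nm")
    receptors = [
        pigment_template(lm, grid, name=n, shape=shape)
        for n, lm in zip(STOMATOPOD_CHANNEL_NAMES, peaks)
    ]
    return VisualSystem(
        receptors=receptors,
        integration_range=STOMATOPOD_INTEGRATION_RANGE,
        abundances=np.ones(12),
        weber_fraction=0.05,
        name="stomatopod",
    )


def irradiance_at_depth(model: IlluminantModel, depth: float) -> Spectrum:
    """Downwelling irradiance at ``depth`` metres: surface * exp(-K * depth)."""
    if depth < 0:
        raise ValueError(f"depth must be >= 0 m, got {depth}")
    vals = model.surface.values * np.exp(-model.attenuation.values * depth)
    return Spectrum(
        model.surface.wavelengths.copy(),
        vals,
        kind="irradiance",
        label=f"{model.surface.label or 'irradiance'}@{depth:g}m",
    )
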