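"""Core colourimetry: quantum catch, Weber contrast, Von Kries adaptation,
Maxwell-triangle chromaticity and receptor-noise-limited (RNL) distance.

Quantum catch of receptor i viewing a surface with reflectance S under
irradiance I is

    q_i = integral R_i(lambda) S(lambda) I(lambda) dlambda

over the receiver's integration range (trapezoid rule on the canonical
1-nm grid). Weber contrast is (q_s - q_b) / q_b per receptor, positive when
the stimulus is lighter than the background. Von Kries adaptation divides
each catch by the catch from the adapting background; the adapted values are
then normalised to sum to one and, for a trichromat, projected into
Maxwell's triangle. Chromatic discriminability is the RNL distance in JND
units, a noise-weighted quadratic form of log catch ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np

from .spectra import Spectrum
from .visual import ReceptorSensitivity, VisualSystem

#: RNL distance below which two colours are treated as indistinguishable.
JND_INDISTINGUISHABLE = 1.0
#: RNL distance below which two colours may still be indistinguishable.
JND_POSSIBLY_INDISTINGUISHABLE = 3.0


@dataclass
class QuantumCatchVector:
    """Per-receptor photon-catch estimates for one stimulus."""

    system: VisualSystem
    values: np.ndarray
    stimulus_label: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.system.n_receptors:
            raise ValueError(
                f"catch vector length {len(self.values)} != receptor count {self.system.n_receptors}"
            )
        if np.any(self.values < 0):
            raise ValueError(f"negative quantum catch for {self.stimulus_label!r}")


@dataclass
class AdaptedCatch:
    """Von Kries adapted (v_i) and normalised (n_i) catches."""

    von_kries: np.ndarray
    normalised: np.ndarray

    def __post_init__(self) -> None:
        self.von_kries = np.asarray(self.von_kries, dtype=float)
        self.normalised = np.asarray(self.normalised, dtype=float)
        if np.any(self.von_kries < 0) or np.any(self.normalised < 0):
            raise ValueError("adapted catches must be non-negative")
        if abs(self.normalised.sum() - 1.0) > 1e-9:
            raise ValueError("normalised catches must sum to 1")


@dataclass(frozen=True)
class ChromaticityPoint:
    """Coordinates in Maxwell's triangle. The achromatic point is the origin;
    radial distance is saturation, angle relates to hue."""

    x: float
    y: float

    def __post_init__(self) -> None:
        r2 = self.x * self.x + self.y * self.y
        if r2 > 2.0 / 3.0 + 1e-9:
            raise ValueError(f"chromaticity ({self.x}, {self.y}) outside the triangle circumcircle")

    @property
    def saturation(self) -> float:
        return sqrt(self.x * self.x + self.y * self.y)


@dataclass
class WeberContrastVector:
    """Signed per-receptor Weber contrasts of a stimulus against a background."""

    values: np.ndarray
    stimulus_label: str = ""
    background_label: str = ""
    receptor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class NoiseModel:
    """Per-receptor noise standard deviations e_i of the RNL model."""

    e: np.ndarray

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        if np.any(self.e <= 0):
            raise ValueError("all receptor noise values must be > 0")


def quantum_catch(
    receptor: ReceptorSensitivity,
    reflectance: Spectrum,
    irradiance: Spectrum,
    integration_range: tuple[float, float],
) -> float:
    """Trapezoid integral of R_i * S * I over ``integration_range``."""
    wl = receptor.curve.wavelengths
    if not (np.array_equal(wl, reflectance.wavelengths) and np.array_equal(wl, irradiance.wavelengths)):
        raise ValueError("receptor, reflectance and irradiance must share one wavelength grid; resample first")
    lo, hi = integration_range
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(f"integration range ({lo}, {hi}) outside grid [{wl[0]}, {wl[-1]}]")
    m = (wl >= lo) & (wl <= hi)
    integrand = receptor.curve.values[m] * reflectance.values[m] * irradiance.values[m]
    return float(np.trapezoid(integrand, wl[m]))


def catch_vector(
    system: VisualSystem,
    reflectance: Spectrum,
    irradiance: Spectrum,
    label: str | None = None,
    group: str = "",
) -> QuantumCatchVector:
    """Quantum catch for every receptor of ``system``, in receptor order."""
    vals = np.array([
        quantum_catch(r, reflectance, irradiance, system.integration_range)
        for r in system.receptors
    ])
    return QuantumCatchVector(
        system=system,
        values=vals,
        stimulus_label=label if label is not None else reflectance.label,
        group=group,
    )


def weber_contrast(stimulus: QuantumCatchVector, background: QuantumCatchVector) -> WeberContrastVector:
    """Per-receptor Weber contrast (q_s - q_b) / q_b.

    Positive values mean the stimulus is lighter than the background in that
    receptor; negative values mean darker.
    """
    if stimulus.system is not background.system and stimulus.system.receptor_names != background.system.receptor_names:
        raise ValueError("stimulus and background catches come from different visual systems")
    zero = np.flatnonzero(background.values == 0)
    if zero.size:
        names = [stimulus.system.receptor_names[i] for i in zero]
        raise ValueError(f"background quantum catch is zero in receptor(s) {names}")
    omega = (stimulus.values - background.values) / background.values
    return WeberContrastVector(
        values=omega,
        stimulus_label=stimulus.stimulus_label,
        background_label=background.stimulus_label,
        receptor_names=list(stimulus.system.receptor_names),
    )


def von_kries_adapt(
    stimulus_catch: QuantumCatchVector,
    adapting_background: Spectrum,
    irradiance: Spectrum,
    system: VisualSystem,
) -> AdaptedCatch:
    """Von Kries adaptation against a background, then normalisation.

    v_i = q_i / integral(R_i * B * I); n_i = v_i / sum(v). A uniform rescaling
    of the irradiance cancels between stimulus and adapting catches.
    """
    adapt = catch_vector(system, adapting_background, irradiance).values
    zero = np.flatnonzero(adapt == 0)
    if zero.size:
        names = [system.receptor_names[i] for i in zero]
        raise ValueError(f"adapting background catch is zero in receptor(s) {names}")
    v = stimulus_catch.values / adapt
    total = v.sum()
    if total == 0:
        raise ValueError("stimulus catch is zero in every receptor; cannot normalise")
    return AdaptedCatch(von_kries=v, normalised=v / total)


def maxwell_coordinates(adapted: AdaptedCatch) -> ChromaticityPoint:
    """Project normalised trichromat catches (n_S, n_M, n_L) into Maxwell's triangle.

    x = (n_L - n_S) / sqrt(2);  y = sqrt(2/3) * (n_M - (n_L + n_S) / 2).

    With this grouping equal catches map to the origin (achromatic) and the
    three pure-receptor points sit at radius sqrt(2/3).
    """
    n = adapted.normalised
    if len(n) != 3:
        raise ValueError(f"Maxwell's triangle requires a trichromat, got {len(n)} receptors")
    n_s, n_m, n_l = n
    x = (n_l - n_s) / sqrt(2.0)
    y = sqrt(2.0 / 3.0) * (n_m - (n_l + n_s) / 2.0)
    return ChromaticityPoint(float(x), float(y))


def receptor_noise(system: VisualSystem) -> NoiseModel:
    """Per-receptor noise e_i = nu * sqrt(eta_ref / eta_i).

    ``nu`` (the system's Weber fraction) is the noise of the most abundant
    receptor class eta_ref; rarer classes are noisier by 1/sqrt(relative
    abundance). For nu = 0.05 and abundances (1, 2, 2) this gives
    e = (0.0707, 0.05, 0.05).
    """
    eta = system.abundances
    eta_ref = eta.max()
    e = system.weber_fraction * np.sqrt(eta_ref / eta)
    return NoiseModel(e=e)


def rnl_distance(
    a: QuantumCatchVector,
    b: QuantumCatchVector,
    noise: NoiseModel,
    signal_form: str = "log",
) -> float:
    """Receptor-noise-limited chromatic distance in JND units (trichromat form).

    Receptor signals are Delta f_i = ln(q_i^a / q_i^b) by default (the
    log-linear form, appropriate when contrasts are not small); the
    small-contrast linear form Delta f_i = (q_a - q_b)/q_b is available via
    ``signal_form='linear'``. The distance is

        dS^2 = [e1^2 (df3-df2)^2 + e2^2 (df3-df1)^2 + e3^2 (df1-df2)^2]
               / [(e1 e2)^2 + (e1 e3)^2 + (e2 e3)^2]

    A pure intensity change (uniform scaling of all catches) gives dS = 0
    under the log form.
    """
    if a.system.n_receptors != 3 or b.system.n_receptors != 3:
        raise ValueError("the trichromat RNL distance needs exactly 3 receptors")
    if len(noise.e) != 3:
        raise ValueError("noise model must have 3 receptor entries")
    qa, qb = a.values, b.values
    if np.any(qa <= 0) or np.any(qb <= 0):
        raise ValueError("RNL distance requires strictly positive quantum catches")
    if signal_form == "log":
        df = np.log(qa / qb)
    elif signal_form == "linear":
        df = (qa - qb) / qb
    else:
        raise ValueError(f"unknown signal_form {signal_form!r}")
    e1, e2, e3 = noise.e
    f1, f2, f3 = df
    num = (e1 * (f3 - f2)) ** 2 + (e2 * (f3 - f1)) ** 2 + (e3 * (f1 - f2)) ** 2
    den = (e1 * e2) ** 2 + (e1 * e3) ** 2 + (e2 * e3) ** 2
    return float(np.sqrt(num / den))
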