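"""Spectral measurements: containers, I/O, smoothing, resampling, averaging.

Every downstream computation (quantum catch, chromatic distances) integrates
products of spectra, so all curves are carried on explicit wavelength grids
and the pipeline resamples everything onto one canonical grid before any
arithmetic. Reflectance is stored as a proportion of a white standard
(values above 1 are permitted), irradiance as relative photon flux, and
receptor sensitivity as a dimensionless curve peak-normalised to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECTRUM_KINDS = ("reflectance", "irradiance", "sensitivity")

#: Canonical wavelength range (nm) used throughout the pipeline.
CANONICAL_START = 300.0
CANONICAL_STOP = 800.0
CANONICAL_STEP = 1.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres."""

    start: float
    stop: float
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"grid start ({self.start}) must be < stop ({self.stop})")
        if self.step <= 0:
            raise ValueError(f"grid step must be positive, got {self.step}")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"grid span ({self.start}-{self.stop}) is not divisible by step {self.step}"
            )

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1


#: The grid every spectrum is resampled onto before integration.
CANONICAL_GRID = WavelengthGrid(CANONICAL_START, CANONICAL_STOP, CANONICAL_STEP)


@dataclass
class Spectrum:
    """A sampled function of wavelength.

    Parameters
    ----------
    wavelengths : array of nm, strictly ascending
    values : array of non-negative reals, same length
    kind : one of ``reflectance``, ``irradiance``, ``sensitivity``
    label : free-text sample identity
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}; expected one of {SPECTRUM_KINDS}")
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if len(self.wavelengths) != len(self.values):
            raise ValueError("wavelengths and values must have equal length")
        if len(self.wavelengths) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(~np.isfinite(self.values)):
            raise ValueError(f"non-finite values in spectrum {self.label!r}")
        n_neg = int(np.sum(self.values < 0))
        if n_neg:
            # Negative instrument readings are physically impossible for
            # reflectance/irradiance; clip and log, do not fail.
            logger.info("clipped %d negative values to 0 in spectrum %r", n_neg, self.label)
            self.values = np.clip(self.values, 0.0, None)

    def __len__(self) -> int:
        return len(self.wavelengths)

    def copy(self, **overrides) -> "Spectrum":
        kw = dict(
            wavelengths=self.wavelengths.copy(),
            values=self.values.copy(),
            kind=self.kind,
            label=self.label,
        )
        kw.update(overrides)
        return Spectrum(**kw)

    def value_at(self, wavelength: float) -> float:
        """Linear interpolation at a single wavelength inside the support."""
        w = float(wavelength)
        if w < self.wavelengths[0] or w > self.wavelengths[-1]:
            raise ValueError(f"{w} nm outside spectrum support "
                             f"[{self.wavelengths[0]}, {self.wavelengths[-1]}]")
        return float(np.interp(w, self.wavelengths, self.values))


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse {path}: {exc}") from exc
    return df


def read_spectra(path: str | Path, kind: str = "reflectance") -> list[Spectrum]:
    """Read spectra from a delimited text file.

    Column 1 must be the wavelength in nm (named ``wavelength_nm`` by the
    writer, but any name is accepted); each further column is one sample,
    labelled by its header. CSV vs TSV is decided by the file extension.
    """
    path = Path(path)
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a wavelength column and at least one value column")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            rows = list(df.index[df[col].isna() | bad][:5])
            raise ValueError(
                f"{path}: column {col!r} has missing or non-numeric cells at rows {rows}"
            )
        df[col] = coerced
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    order = np.argsort(wl)
    wl = wl[order]
    if np.any(np.diff(wl) == 0):
        dup = wl[:-1][np.diff(wl) == 0]
        raise ValueError(f"{path}: duplicate wavelengths {dup[:5]}")
    out = []
    for col in df.columns[1:]:
        out.append(Spectrum(wl, df[col].to_numpy(dtype=float)[order], kind=kind, label=str(col)))
    return out


def write_spectra(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra sharing one grid to a delimited text file (CSV/TSV by extension)."""
    path = Path(path)
    if not spectra:
        raise ValueError("no spectra to write")
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("all spectra must share one wavelength grid to be written together")
    data = {"wavelength_nm": wl}
    for s in spectra:
        data[s.label or f"sample_{len(data)}"] = s.values
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.12g")


def smooth_spectrum(s: Spectrum, span: float = 0.2) -> Spectrum:
    """Loess smoothing: local quadratic regression with tricube weights.

    ``span`` is the fraction of points in each local window. The curve is
    evaluated at the input wavelengths and clipped at zero (reflectance and
    irradiance are non-negative).
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    n = len(s)
    if n < 10:
        raise ValueError(f"need >= 10 points to smooth, got {n}")
    k = max(int(round(span * n)), 1)
    if k < 5:
        raise ValueError(f"span {span} covers only {k} points per window; need >= 5")
    x = s.wavelengths
    y = s.values
    out = np.empty(n)
    half = k // 2
    for i in range(n):
        lo = max(0, min(i - half, n - k))
        idx = slice(lo, lo + k)
        xw, yw = x[idx], y[idx]
        d = np.abs(xw - x[i])
        dmax = d.max()
        if dmax == 0:
            out[i] = yw.mean()
            continue
        w = (1 - (d / dmax) ** 3) ** 3
        w = np.clip(w, 0, None)
        # local quadratic fit, centred to keep the normal equations well-scaled
        xc = xw - x[i]
        X = np.column_stack([np.ones_like(xc), xc, xc * xc])
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ yw, rcond=None)
        out[i] = beta[0]
    return Spectrum(x.copy(), np.clip(out, 0.0, None), kind=s.kind, label=s.label)


def resample(s: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Linear interpolation onto ``grid``. Never extrapolates."""
    if grid.start < s.wavelengths[0] or grid.stop > s.wavelengths[-1]:
        raise ValueError(
            f"grid [{grid.start}, {grid.stop}] outside spectrum support "
            f"[{s.wavelengths[0]}, {s.wavelengths[-1]}] for {s.label!r}; refusing to extrapolate"
        )
    wl = grid.wavelengths
    vals = np.interp(wl, s.wavelengths, s.values)
    return Spectrum(wl, vals, kind=s.kind, label=s.label)


def average_spectra(spectra: Iterable[Spectrum], label: str | None = None) -> Spectrum:
    """Pointwise arithmetic mean of spectra on one shared grid."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("cannot average an empty list of spectra")
    first = spectra[0]
    for s in spectra[1:]:
        if s.kind != first.kind:
            raise ValueError(f"mixed spectrum kinds: {first.kind} vs {s.kind}")
        if not np.array_equal(s.wavelengths, first.wavelengths):
            raise ValueError("spectra are on different wavelength grids; resample first")
    mean = np.mean([s.values for s in spectra], axis=0)
    return Spectrum(first.wavelengths.copy(), mean, kind=first.kind,
                    label=label if label is not None else first.label)
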