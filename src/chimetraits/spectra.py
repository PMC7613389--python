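"""Spectrum container and plain-text serialization.

A :class:`Spectrum` is the currency passed between the radiative-transfer,
sensor-simulation and regression stages: a strictly increasing wavelength
grid (nm) paired with reflectance values in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def default_grid() -> np.ndarray:
    """High-resolution simulation grid: 400-2500 nm at 1 nm steps."""
    return np.arange(400.0, 2501.0, 1.0)


@dataclass(frozen=True)
class Spectrum:
    """Reflectance (or transmittance) sampled on a wavelength grid.

    Parameters
    ----------
    wavelengths : array of float
        Wavelengths in nm, strictly increasing.
    values : array of float
        Dimensionless reflectance in [0, 1], same length as wavelengths.
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.shape != vals.shape:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
            raise ValueError("reflectance values must lie in [0, 1]")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", np.clip(vals, 0.0, 1.0))

    def __len__(self) -> int:
        return self.wavelengths.size

    def value_at(self, wavelength: float) -> float:
        """Value at the grid point nearest to ``wavelength``."""
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.values[idx])


def spectrum_to_csv(spectrum: Spectrum, path) -> None:
    """Write a two-column CSV (wavelength_nm, reflectance)."""
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "reflectance": spectrum.values}
    ).to_csv(path, index=False)


def spectrum_from_csv(path) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(df["wavelength_nm"].to_numpy(), df["reflectance"].to_numpy())


def batch_to_csv(wavelengths: np.ndarray, matrix: np.ndarray, path, ids=None) -> None:
    """Write many spectra as a wide CSV: wavelength header row, one row per spectrum."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    cols = [f"{w:g}" for w in np.asarray(wavelengths, dtype=float)]
    df = pd.DataFrame(matrix, columns=cols)
    if ids is not None:
        df.insert(0, "id", list(ids))
    df.to_csv(path, index=False)


def batch_from_csv(path) -> tuple[np.ndarray, np.ndarray, list]:
    """Read a wide spectra CSV; returns (wavelengths, matrix, ids)."""
    df = pd.read_csv(path)
    ids: list = []
    if "id" in df.columns:
        ids = df["id"].tolist()
        df = df.drop(columns=["id"])
    wavelengths = np.array([float(c) for c in df.columns])
    return wavelengths, df.to_numpy(dtype=float), ids
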