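"""CHIME-like sensor simulation.

Builds the 210-band / 10 nm Gaussian-SRF band configuration, removes the
water-vapour-contaminated bands (157 retained by default), resamples
high-resolution spectra through the SRFs, computes NDVI and averages pixel
spectra to ESU (plot) level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = [
    "BandGrid",
    "chime_band_grid",
    "DEFAULT_WATER_VAPOUR_WINDOWS",
    "apply_water_vapour_mask",
    "resampling_matrix",
    "resample_spectrum",
    "resample_matrix",
    "ndvi",
    "ndvi_bands",
    "aggregate_esu",
]

#: FWHM-to-sigma conversion for a Gaussian: fwhm = 2·sqrt(2·ln 2)·sigma.
FWHM_TO_SIGMA = 2.3548

#: Spectral windows (nm) dropped as water-vapour contaminated.  Chosen inside
#: the canonical 1.4 μm / 1.9 μm / >2.35 μm absorption regions so that exactly
#: 53 of the 210 bands are removed, retaining 157.
DEFAULT_WATER_VAPOUR_WINDOWS = ((1340.0, 1470.0), (1750.0, 2000.0), (2350.0, 2500.0))


@dataclass(frozen=True)
class BandGrid:
    """Sensor band configuration: centers, FWHMs and a keep mask."""

    centers: np.ndarray
    fwhm: np.ndarray
    keep_mask: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        fwhm = np.asarray(self.fwhm, dtype=float)
        keep = np.asarray(self.keep_mask, dtype=bool)
        if not np.all(np.diff(centers) > 0):
            raise ValueError("band centers must be strictly increasing")
        if np.any(fwhm <= 0):
            raise ValueError("fwhm must be positive")
        if not centers.shape == fwhm.shape == keep.shape:
            raise ValueError("centers, fwhm, keep_mask must share shape")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "fwhm", fwhm)
        object.__setattr__(self, "keep_mask", keep)

    @property
    def n_bands(self) -> int:
        return self.centers.size

    @property
    def n_retained(self) -> int:
        return int(self.keep_mask.sum())

    @property
    def retained_centers(self) -> np.ndarray:
        return self.centers[self.keep_mask]

    @property
    def retained_fwhm(self) -> np.ndarray:
        return self.fwhm[self.keep_mask]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"center_nm": self.centers, "fwhm_nm": self.fwhm, "kept": self.keep_mask}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BandGrid":
        df = pd.read_csv(path)
        return cls(
            df["center_nm"].to_numpy(),
            df["fwhm_nm"].to_numpy(),
            df["kept"].to_numpy(dtype=bool),
        )


def chime_band_grid() -> BandGrid:
    """The CHIME-like configuration: 210 bands tiling 400-2500 nm.

    Band centers at 405, 415, ..., 2495 nm with 10 nm FWHM; all bands kept.
    """
    centers = np.arange(405.0, 2500.0, 10.0)
    return BandGrid(centers, np.full(centers.shape, 10.0), np.ones(centers.shape, bool))


def apply_water_vapour_mask(
    grid: BandGrid, windows=DEFAULT_WATER_VAPOUR_WINDOWS
) -> BandGrid:
    """Drop bands whose centers fall inside any of the given nm windows."""
    keep = grid.keep_mask.copy()
    for lo, hi in windows:
        if not (400.0 <= lo <= 2500.0 and 400.0 <= hi <= 2500.0):
            raise ValueError(f"window ({lo}, {hi}) outside [400, 2500] nm")
        keep &= ~((grid.centers >= lo) & (grid.centers <= hi))
    return replace(grid, keep_mask=keep)


def resampling_matrix(highres_wavelengths: np.ndarray, grid: BandGrid) -> np.ndarray:
    """Gaussian-SRF weight matrix W of shape (n_retained, n_highres).

    Row b holds normalized weights w_i = exp(−(λ_i − c_b)² / (2σ_b²)) for the
    highres samples within ±3σ of band b's center; W @ values resamples.
    """
    wl = np.asarray(highres_wavelengths, dtype=float)
    centers = grid.retained_centers
    sigmas = grid.retained_fwhm / FWHM_TO_SIGMA
    dist = wl[None, :] - centers[:, None]
    weights = np.exp(-(dist**2) / (2.0 * sigmas[:, None] ** 2))
    weights[np.abs(dist) > 3.0 * sigmas[:, None]] = 0.0
    support = (weights > 0).sum(axis=1)
    if np.any(support < 3):
        bad = centers[support < 3]
        raise ValueError(
            f"insufficient highres coverage for band(s) centered at {bad} nm"
        )
    return weights / weights.sum(axis=1, keepdims=True)


def resample_spectrum(highres: Spectrum, grid: BandGrid) -> Spectrum:
    """Resample one high-resolution spectrum onto the retained bands."""
    W = resampling_matrix(highres.wavelengths, grid)
    return Spectrum(grid.retained_centers, W @ highres.values)


def resample_matrix(
    highres_wavelengths: np.ndarray, values: np.ndarray, grid: BandGrid
) -> np.ndarray:
    """Resample many spectra at once: values is (n_spectra, n_highres)."""
    W = resampling_matrix(highres_wavelengths, grid)
    return np.asarray(values, dtype=float) @ W.T


def ndvi_bands(grid: BandGrid) -> tuple[int, int]:
    """Indices (into retained bands) of the red/NIR bands nearest 675/865 nm."""
    centers = grid.retained_centers
    red = int(np.argmin(np.abs(centers - 675.0)))
    nir = int(np.argmin(np.abs(centers - 865.0)))
    return red, nir


def ndvi(values: np.ndarray, grid: BandGrid) -> np.ndarray:
    """NDVI = (NIR − red)/(NIR + red) on retained-band reflectance.

    Accepts a single spectrum (1-D over retained bands) or a stack with the
    band axis last.  Pixels with NIR + red = 0 return NaN.
    """
    red_idx, nir_idx = ndvi_bands(grid)
    vals = np.asarray(values, dtype=float)
    red = vals[..., red_idx]
    nir = vals[..., nir_idx]
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), np.nan)
    return out


def aggregate_esu(pixel_spectra) -> Spectrum:
    """Average the spectra of all pixels in an ESU (per-band arithmetic mean)."""
    spectra = list(pixel_spectra)
    if not spectra:
        raise ValueError("aggregate_esu requires at least one pixel spectrum")
    wl = spectra[0].wavelengths
    for sp in spectra[1:]:
        if not np.array_equal(sp.wavelengths, wl):
            raise ValueError("all pixel spectra must share one band grid")
    return Spectrum(wl, np.mean([sp.values for sp in spectra], axis=0))
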