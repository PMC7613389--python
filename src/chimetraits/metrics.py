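"""Goodness-of-fit metrics, prediction-uncertainty summaries and map masking.

Validation statistics are the coefficient of determination R² = 1 −
SS_res/SS_tot, the root mean square error, and the RMSE normalized by the
observed range (max − min) in percent.  Map products carry a per-pixel
coefficient of variation (100·σ/|mean|) and a validity mask driven by an
NDVI bare-soil threshold and, optionally, a CV reliability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricSet",
    "compute_metrics",
    "coefficient_of_variation",
    "TraitMap",
    "mask_map",
]

#: No-data value written into masked cells of exported maps.
NODATA = -9999.0


@dataclass(frozen=True)
class MetricSet:
    """R², RMSE (trait units), nRMSE (% of observed range), sample count."""

    r2: float
    rmse: float
    nrmse: float
    n: int

    @property
    def r2_display(self) -> float:
        """R² floored at 0 for display; the raw value can be negative."""
        return max(self.r2, 0.0)


def compute_metrics(observed, predicted) -> MetricSet:
    """Validation metrics of predictions against observations."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("metrics require at least 2 samples")
    rng = float(obs.max() - obs.min())
    if rng <= 0:
        raise ValueError("observed range is zero; nRMSE undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return MetricSet(
        r2=1.0 - ss_res / ss_tot, rmse=rmse, nrmse=100.0 * rmse / rng, n=obs.size
    )


def coefficient_of_variation(pred_mean, pred_std):
    """Prediction CV in percent: 100·σ/|mean|; NaN where the mean is zero."""
    mean = np.asarray(pred_mean, dtype=float)
    std = np.asarray(pred_std, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mean != 0, 100.0 * std / np.abs(np.where(mean != 0, mean, 1.0)), np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass
class TraitMap:
    """Per-pixel trait estimates with uncertainty and validity layers."""

    estimates: np.ndarray
    cv: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        est = np.asarray(self.estimates, dtype=float)
        cv = np.asarray(self.cv, dtype=float)
        mask = np.asarray(self.valid_mask, dtype=bool)
        if not est.shape == cv.shape == mask.shape:
            raise ValueError("estimate, cv and mask grids must be congruent")
        self.estimates, self.cv, self.valid_mask = est, cv, mask

    def masked_estimates(self) -> np.ndarray:
        out = self.estimates.copy()
        out[~self.valid_mask] = NODATA
        return out


def mask_map(
    trait_map: TraitMap,
    ndvi_grid: np.ndarray,
    ndvi_min: float = 0.3,
    cv_max: float = np.inf,
) -> TraitMap:
    """Invalidate bare-soil and unreliable pixels.

    Pixels with NDVI below ``ndvi_min`` (default 0.3, treated as bare soil)
    or CV above ``cv_max`` (off by default; 20% when reliability masking is
    enabled) are removed from the valid mask.
    """
    ndvi_grid = np.asarray(ndvi_grid, dtype=float)
    if ndvi_grid.shape != trait_map.estimates.shape:
        raise ValueError("NDVI grid shape does not match the trait map")
    valid = (
        trait_map.valid_mask
        & ~(np.nan_to_num(ndvi_grid, nan=-1.0) < ndvi_min)
        & ~(np.nan_to_num(trait_map.cv, nan=np.inf) > cv_max)
    )
    return TraitMap(trait_map.estimates.copy(), trait_map.cv.copy(), valid)
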