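"""Spectral dimensionality reduction before regression.

Principal component analysis at the component counts used throughout the
pipeline (5, 10, 15, 20; any k allowed), plus a "noPCA" identity transform.
Mean-centering only by default — reflectance bands share a common scale and
per-band standardization would inflate masked-edge noise; a flag enables it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["SpectralPCA", "NoPCA", "make_dimred"]


@dataclass
class SpectralPCA:
    """Deterministic PCA wrapper with a fixed sign convention.

    Components are ordered by non-increasing explained variance; each loading
    vector is flipped so its largest-magnitude element is positive.  The model
    is fit on the LUT spectra only and then applied unchanged to validation
    and map spectra.
    """

    n_components: int
    standardize: bool = False

    def fit(self, X: np.ndarray) -> "SpectralPCA":
        X = np.asarray(X, dtype=float)
        if self.n_components > min(X.shape):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n_samples, n_bands)"
            )
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=0) if self.standardize else np.ones(X.shape[1])
        self.scale_ = np.where(self.scale_ > 0, self.scale_, 1.0)
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit((X - self.mean_) / self.scale_)
        loadings = pca.components_
        # sign convention: largest-|.| element of each component positive
        flips = np.sign(loadings[np.arange(len(loadings)), np.argmax(np.abs(loadings), axis=1)])
        self.loadings_ = loadings * flips[:, None]
        self.explained_variance_ = pca.explained_variance_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.mean_.size:
            raise ValueError(
                f"band count {X.shape[-1]} does not match fitted model ({self.mean_.size})"
            )
        return ((X - self.mean_) / self.scale_) @ self.loadings_.T

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return (np.asarray(scores) @ self.loadings_) * self.scale_ + self.mean_

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.loadings_)
        df.insert(0, "row", [f"pc{i+1}" for i in range(len(self.loadings_))])
        mean_row = pd.DataFrame([["mean", *self.mean_]], columns=df.columns)
        pd.concat([mean_row, df]).to_csv(path, index=False)


class NoPCA:
    """Identity transform: regression runs on the raw retained bands."""

    n_components = None

    def fit(self, X):
        self.mean_ = np.asarray(X).mean(axis=0)
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)

    def fit_transform(self, X):
        return self.fit(X).transform(X)

    def inverse_transform(self, scores):
        return np.asarray(scores, dtype=float)


def make_dimred(mode: str, standardize: bool = False):
    """Build a DR stage from a mode name: 'noPCA' or 'PCA<k>' (e.g. PCA10)."""
    if mode.lower() in ("nopca", "none", "identity"):
        return NoPCA()
    if mode.upper().startswith("PCA"):
        k = int(mode[3:])
        return SpectralPCA(n_components=k, standardize=standardize)
    raise ValueError(f"unknown dimensionality-reduction mode {mode!r}")
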