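"""Lookup-table construction.

Draws PROSAIL-PRO input samples from configured probability distributions
(normal parameters truncated by rejection; an optional correlated block drawn
from a truncated multivariate normal), runs the forward model, derives the
four retrieval targets and injects multiplicative Gaussian noise — producing
the regression training LUT.

Default distributions (package defaults, all configurable):

=========  ========  ==============  =================
parameter  family    p1 / p2         truncation
=========  ========  ==============  =================
n_struct   normal    1.4 / 0.14      ≥ 1
cab        normal    41.5 / 8.8      ≥ 0
ccx        normal    7.32 / 1.5      ≥ 0
cant       normal    0.0 / 0.0       ≥ 0
cbp        normal    0.0 / 0.0       ≥ 0
cw         normal    12.92 / 1.91    ≥ 0
cp         uniform   0.0 / 0.001
cbc        uniform   0.003 / 0.006
ala        normal    49.0 / 4.9      [0, 90]
lai        normal    1.77 / 1.4      ≥ 0.05
hot        normal    0.01 / 0.001    ≥ 0
sza        uniform   26 / 30
oza        uniform   0 / 0
raa        uniform   0 / 0
soil       uniform   2 / 4 (integer)
=========  ========  ==============  =================
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rtm import CanopyParams, LeafParams
from .sensor import BandGrid, resample_matrix
from .spectra import default_grid
from . import traits as ta

logger = logging.getLogger(__name__)

__all__ = [
    "PdfSpec",
    "SamplingConfig",
    "default_sampling_config",
    "draw_samples",
    "derive_traits",
    "LookupTable",
    "build_lut",
    "add_relative_noise",
]

LEAF_FIELDS = ("n_struct", "cab", "ccx", "cant", "cbp", "cw", "cp", "cbc")
CANOPY_FIELDS = ("ala", "lai", "hot", "sza", "oza", "raa", "soil_index")
TRAIT_NAMES = ("lcc", "lnc", "ccc", "cnc")


@dataclass(frozen=True)
class PdfSpec:
    """Marginal distribution of one sampler parameter.

    ``family`` is 'uniform' (p1=min, p2=max), 'normal' (p1=μ, p2=σ) or
    'constant' (p1=value).  ``lower``/``upper`` truncate the support.
    """

    name: str
    family: str
    p1: float
    p2: float = 0.0
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "normal", "constant"):
            raise ValueError(f"unknown PDF family {self.family!r}")
        if self.family == "uniform" and self.p1 > self.p2:
            raise ValueError(f"{self.name}: uniform requires p1 <= p2")
        if self.family == "normal" and self.p2 < 0:
            raise ValueError(f"{self.name}: normal requires sigma >= 0")
        if self.lower > self.upper:
            raise ValueError(f"{self.name}: truncation bounds must bracket support")


def _default_pdfs() -> dict[str, PdfSpec]:
    specs = [
        PdfSpec("n_struct", "normal", 1.4, 0.14, lower=1.0),
        PdfSpec("cab", "normal", 41.5, 8.8, lower=0.0),
        PdfSpec("ccx", "normal", 7.32, 1.5, lower=0.0),
        PdfSpec("cant", "normal", 0.0, 0.0, lower=0.0),
        PdfSpec("cbp", "normal", 0.0, 0.0, lower=0.0),
        PdfSpec("cw", "normal", 12.92, 1.91, lower=0.0),
        PdfSpec("cp", "uniform", 0.0, 0.001),
        PdfSpec("cbc", "uniform", 0.003, 0.006),
        PdfSpec("ala", "normal", 49.0, 4.9, lower=0.0, upper=90.0),
        PdfSpec("lai", "normal", 1.77, 1.4, lower=0.05),
        PdfSpec("hot", "normal", 0.01, 0.001, lower=0.0),
        PdfSpec("sza", "uniform", 26.0, 30.0),
        PdfSpec("oza", "uniform", 0.0, 0.0),
        PdfSpec("raa", "uniform", 0.0, 0.0),
        PdfSpec("soil_index", "uniform", 2, 4),
    ]
    return {s.name: s for s in specs}


#: Default correlated block: pigment/water co-variation.  Which parameters
#: co-vary is a package choice; the matrix is fully configurable.
DEFAULT_CORR_PARAMS = ("cab", "ccx", "cw")
DEFAULT_CORR_MATRIX = np.array(
    [
        [1.0, 0.8, 0.4],
        [0.8, 1.0, 0.4],
        [0.4, 0.4, 1.0],
    ]
)


@dataclass
class SamplingConfig:
    """Full sampler configuration: marginals, correlated block, size, seed."""

    pdfs: dict[str, PdfSpec] = field(default_factory=_default_pdfs)
    corr_params: tuple[str, ...] = DEFAULT_CORR_PARAMS
    corr_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_CORR_MATRIX.copy())
    n_samples: int = 2000
    seed: int = 0

    def validate(self) -> None:
        corr = np.asarray(self.corr_matrix, dtype=float)
        k = len(self.corr_params)
        if corr.shape != (k, k):
            raise ValueError("corr_matrix shape must match corr_params")
        if k:
            if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
                raise ValueError("correlation matrix must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(corr).min() <= 0:
                raise ValueError("correlation matrix must be positive-definite")
            for name in self.corr_params:
                if self.pdfs[name].family != "normal":
                    raise ValueError(
                        f"correlated parameter {name!r} must have a normal PDF"
                    )


def default_sampling_config(n_samples: int = 2000, seed: int = 0) -> SamplingConfig:
    return SamplingConfig(n_samples=n_samples, seed=seed)


def _draw_marginal(
    spec: PdfSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    if spec.family == "constant":
        return np.full(n, spec.p1)
    if spec.family == "uniform":
        if spec.name == "soil_index":
            return rng.integers(int(spec.p1), int(spec.p2) + 1, size=n).astype(float)
        return rng.uniform(spec.p1, spec.p2, size=n)
    # normal, truncated by rejection (no probability mass piled on the bounds)
    if spec.p2 == 0:
        return np.full(n, spec.p1)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(spec.p1, spec.p2, size=2 * (n - filled))
        ok = draw[(draw >= spec.lower) & (draw <= spec.upper)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _draw_correlated_block(
    config: SamplingConfig, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Truncated multivariate normal over the correlated parameters.

    Gaussian copula over the marginal normals: draw MVN with the configured
    correlation, scale each column by its marginal μ/σ, and reject rows
    violating any truncation bound.
    """
    specs = [config.pdfs[name] for name in config.corr_params]
    mu = np.array([s.p1 for s in specs])
    sigma = np.array([s.p2 for s in specs])
    lower = np.array([s.lower for s in specs])
    upper = np.array([s.upper for s in specs])
    chol = np.linalg.cholesky(np.asarray(config.corr_matrix, dtype=float))
    out = np.empty((n, len(specs)))
    filled = 0
    while filled < n:
        z = rng.standard_normal((2 * (n - filled), len(specs)))
        x = mu + sigma * (z @ chol.T)
        ok = x[np.all((x >= lower) & (x <= upper), axis=1)]
        take = min(ok.shape[0], n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return {name: out[:, j] for j, name in enumerate(config.corr_params)}


def draw_samples(config: SamplingConfig) -> list[tuple[LeafParams, CanopyParams]]:
    """Draw (LeafParams, CanopyParams) input sets per the configuration.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    columns: dict[str, np.ndarray] = {}
    if config.corr_params:
        columns.update(_draw_correlated_block(config, n, rng))
    for name, spec in config.pdfs.items():
        if name not in columns:
            columns[name] = _draw_marginal(spec, n, rng)
    pairs = []
    for i in range(n):
        leaf = LeafParams(**{f: float(columns[f][i]) for f in LEAF_FIELDS})
        canopy_kwargs = {f: float(columns[f][i]) for f in CANOPY_FIELDS}
        canopy_kwargs["soil_index"] = int(canopy_kwargs["soil_index"])
        pairs.append((leaf, CanopyParams(**canopy_kwargs)))
    return pairs


def derive_traits(leaf: LeafParams, canopy: CanopyParams) -> dict[str, float]:
    """The four retrieval targets implied by one input set.

    lcc = cab; lnc = 1000·cp/4.43 (protein → N); ccc = lcc·lai/100;
    cnc = 10·lnc·lai.  Pure function of the inputs.
    """
    lcc = leaf.cab
    lnc = ta.lnc_from_protein(leaf.cp)
    return {
        "lcc": lcc,
        "lnc": lnc,
        "ccc": ta.ccc_from(lcc, canopy.lai),
        "cnc": ta.cnc_from(lnc, canopy.lai),
    }


@dataclass
class LookupTable:
    """Training LUT: input parameters, derived traits and band spectra.

    ``params`` has one row per record (all leaf + canopy fields), ``traits``
    the four targets, ``spectra`` the (n, n_retained_bands) reflectance
    matrix on ``band_grid``'s retained bands.
    """

    params: pd.DataFrame
    traits: pd.DataFrame
    spectra: np.ndarray
    band_grid: BandGrid

    def __len__(self) -> int:
        return len(self.params)

    def to_csv(self, traits_path, spectra_path) -> None:
        pd.concat([self.params, self.traits], axis=1).to_csv(traits_path, index=False)
        cols = [f"{c:g}" for c in self.band_grid.retained_centers]
        pd.DataFrame(self.spectra, columns=cols).to_csv(spectra_path, index=False)


def build_lut(
    config: SamplingConfig,
    rtm,
    band_grid: BandGrid,
    grid: np.ndarray | None = None,
) -> LookupTable:
    """Sample inputs, run the forward model, resample to sensor bands.

    Records whose forward simulation fails are skipped with a warning; the
    final count is logged.
    """
    if grid is None:
        grid = default_grid()
    pairs = draw_samples(config)
    kept_pairs = []
    spectra_rows = []
    if hasattr(rtm, "canopy_reflectance_batch"):
        highres = rtm.canopy_reflectance_batch(
            [p[0] for p in pairs], [p[1] for p in pairs], grid
        )
        spectra_rows = list(resample_matrix(grid, highres, band_grid))
        kept_pairs = pairs
    else:
        for leaf, canopy in pairs:
            try:
                sp = rtm.canopy_reflectance(leaf, canopy, grid=grid)
                spectra_rows.append(
                    resample_matrix(grid, sp.values[None, :], band_grid)[0]
                )
                kept_pairs.append((leaf, canopy))
            except Exception as exc:  # pragma: no cover - adapter-only path
                warnings.warn(f"forward model failed for one sample: {exc}")
    logger.info("built LUT with %d/%d records", len(kept_pairs), len(pairs))
    params = pd.DataFrame(
        [
            {f: getattr(leaf, f) for f in LEAF_FIELDS}
            | {f: getattr(canopy, f) for f in CANOPY_FIELDS}
            for leaf, canopy in kept_pairs
        ]
    )
    trait_df = pd.DataFrame([derive_traits(lf, cn) for lf, cn in kept_pairs])
    return LookupTable(params, trait_df, np.asarray(spectra_rows), band_grid)


def add_relative_noise(lut: LookupTable, level: float, seed: int) -> LookupTable:
    """Multiplicative Gaussian noise on spectra and traits.

    Each value is multiplied by (1 + ε), ε ~ N(0, level²); reflectance is
    re-clipped to [0, 1] and traits floored at 0.  level=0 is the identity.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if level == 0:
        return LookupTable(
            lut.params.copy(), lut.traits.copy(), lut.spectra.copy(), lut.band_grid
        )
    rng = np.random.default_rng(seed)
    spectra = lut.spectra * (1.0 + rng.normal(0.0, level, size=lut.spectra.shape))
    trait_vals = lut.traits.to_numpy() * (
        1.0 + rng.normal(0.0, level, size=lut.traits.shape)
    )
    return LookupTable(
        lut.params.copy(),
        pd.DataFrame(np.maximum(trait_vals, 0.0), columns=lut.traits.columns),
        np.clip(spectra, 0.0, 1.0),
        lut.band_grid,
    )
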