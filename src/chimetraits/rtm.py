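"""Forward simulation of top-of-canopy reflectance.

Leaf biochemistry and canopy structure are mapped to reflectance through a
pluggable forward-model interface.  Two backends exist:

* ``"surrogate"`` — a fully self-contained analytic model with qualitatively
  correct absorption features (Gaussian absorption coefficients for
  chlorophyll, carotenoids, water, protein and carbon-based constituents, a
  Beer-Lambert canopy closure, and a small library of linear soil ramps).
  Every downstream stage of the pipeline runs offline against it.
* ``"prosail"`` — an adapter for an external PROSAIL-PRO implementation.
  If that library is not importable the adapter raises a
  :class:`ConfigurationError` immediately; there is no silent fallback.

The surrogate's coefficients are configuration defaults of this package,
not claims about PROSPECT-PRO.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import Spectrum, default_grid

__all__ = [
    "LeafParams",
    "CanopyParams",
    "ConfigurationError",
    "SurrogateRTM",
    "ProsailAdapter",
    "get_backend",
    "soil_library",
]


class ConfigurationError(RuntimeError):
    """An RTM backend was requested but cannot be used."""


@dataclass(frozen=True)
class LeafParams:
    """Leaf-level biochemistry and structure.

    Units follow the PROSPECT-PRO convention: ``cab``/``ccx``/``cant`` in
    μg cm⁻², ``cw`` in mg cm⁻², ``cp``/``cbc`` in g cm⁻², ``n_struct``
    dimensionless (≥ 1), ``cbp`` dimensionless brown-pigment content.
    """

    n_struct: float = 1.4
    cab: float = 41.5
    ccx: float = 7.32
    cant: float = 0.0
    cbp: float = 0.0
    cw: float = 12.92
    cp: float = 0.0005
    cbc: float = 0.0045

    def __post_init__(self) -> None:
        for name in ("cab", "ccx", "cant", "cbp", "cw", "cp", "cbc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_struct < 1:
            raise ValueError("n_struct must be >= 1")


@dataclass(frozen=True)
class CanopyParams:
    """Canopy structure, geometry and background.

    ``ala`` average leaf angle (deg), ``lai`` leaf area index (m² m⁻²),
    ``hot`` hot-spot parameter (m m⁻¹), ``sza``/``oza``/``raa`` sun-observer
    geometry (deg), ``soil_index`` ∈ {1..4} selecting a background spectrum.
    ``hot``, ``oza`` and ``raa`` are accepted for the external adapter but
    unused by the surrogate.
    """

    ala: float = 49.0
    lai: float = 1.77
    hot: float = 0.01
    sza: float = 28.0
    oza: float = 0.0
    raa: float = 0.0
    soil_index: int = 3

    def __post_init__(self) -> None:
        if self.lai < 0:
            raise ValueError("lai must be non-negative")
        if not 0 <= self.ala <= 90:
            raise ValueError("ala must be in [0, 90] degrees")
        if not 0 <= self.sza < 90:
            raise ValueError("sza must be in [0, 90) degrees")
        if self.soil_index not in (1, 2, 3, 4):
            raise ValueError("soil_index must be in {1, 2, 3, 4}")


# --- absorption coefficient model -------------------------------------------

#: Gaussian components per constituent: list of (center nm, sigma nm, amplitude
#: per native content unit).  Configurable; these are package defaults.
DEFAULT_ABSORPTION = {
    "cab": [(430.0, 40.0, 0.05), (665.0, 30.0, 0.05)],
    "ccx": [(450.0, 35.0, 0.12), (480.0, 25.0, 0.12)],
    "cw": [(1450.0, 60.0, 0.15), (1940.0, 70.0, 0.15)],
    "cp": [(1510.0, 30.0, 2.0), (2054.0, 40.0, 2.0), (2172.0, 40.0, 2.0)],
    "cbc": [(1730.0, 50.0, 0.30), (2100.0, 80.0, 0.30), (2300.0, 60.0, 0.30)],
}


def _gaussian_sum(grid: np.ndarray, components) -> np.ndarray:
    k = np.zeros_like(grid, dtype=float)
    for center, sigma, amp in components:
        k += amp * np.exp(-((grid - center) ** 2) / (2.0 * sigma**2))
    return k


def soil_library(grid: np.ndarray | None = None) -> list[Spectrum]:
    """Four background soil spectra: linear brightness ramps.

    soil_i(λ) = b_i·(0.08 + 9e-5·(λ−400)) clipped to [0, 1], with brightness
    b = 0.6, 0.8, 1.0, 1.2 for indices 1-4.  All have NDVI < 0.3, so the
    bare-soil masking rule holds for every library member.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    base = 0.08 + 9e-5 * (grid - 400.0)
    return [
        Spectrum(grid, np.clip(b * base, 0.0, 1.0)) for b in (0.6, 0.8, 1.0, 1.2)
    ]


class SurrogateRTM:
    """Self-contained analytic leaf + canopy forward model.

    Leaf level: total absorbance
    ``a(λ) = [cab·k_cab + ccx·k_cx + cw·k_w + 1000·cp·k_p + 1000·cbc·k_cbc] / n_struct``
    with each ``k`` a sum of Gaussians in λ.  Transmittance and reflectance
    are Beer-Lambert attenuated splits of the non-absorbed flux:
    ``T = (1−s)·exp(−a)``, ``R = s·exp(−a)`` with scattering fraction
    ``s = clip(0.45 + 0.05·(n_struct−1), 0, 0.6)``; hence R+T = exp(−a) ≤ 1
    and reflectance decreases monotonically with any absorber content.

    Canopy level: single-layer closure with extinction
    ``k_ext = (0.5 + 0.4·cos ala) / cos sza``;
    ``R_canopy = soil·exp(−k_ext·lai·(1+T_leaf)) + R_leaf·(1−exp(−k_ext·lai))``.
    """

    name = "surrogate"

    def __init__(self, absorption: dict | None = None):
        self.absorption = dict(DEFAULT_ABSORPTION if absorption is None else absorption)
        self._k_cache: dict[bytes, dict[str, np.ndarray]] = {}

    # -- vectorized internals --------------------------------------------
    def _coeffs(self, grid: np.ndarray) -> dict[str, np.ndarray]:
        key = grid.tobytes()
        if key not in self._k_cache:
            self._k_cache[key] = {
                name: _gaussian_sum(grid, comps)
                for name, comps in self.absorption.items()
            }
        return self._k_cache[key]

    def absorbance(self, leaf: LeafParams, grid: np.ndarray) -> np.ndarray:
        k = self._coeffs(grid)
        a = (
            leaf.cab * k["cab"]
            + leaf.ccx * k["ccx"]
            + leaf.cw * k["cw"]
            + 1000.0 * leaf.cp * k["cp"]
            + 1000.0 * leaf.cbc * k["cbc"]
        ) / leaf.n_struct
        return a

    @staticmethod
    def scattering_fraction(n_struct: float) -> float:
        return float(np.clip(0.45 + 0.05 * (n_struct - 1.0), 0.0, 0.6))

    def leaf_optics(
        self, leaf: LeafParams, grid: np.ndarray | None = None
    ) -> tuple[Spectrum, Spectrum]:
        """Leaf reflectance and transmittance on ``grid``."""
        if grid is None:
            grid = default_grid()
        grid = _check_grid(grid)
        a = self.absorbance(leaf, grid)
        s = self.scattering_fraction(leaf.n_struct)
        att = np.exp(-a)
        refl = s * att
        trans = (1.0 - s) * att
        return Spectrum(grid, refl), Spectrum(grid, trans)

    def canopy_reflectance(
        self,
        leaf: LeafParams,
        canopy: CanopyParams,
        soil: Spectrum | None = None,
        grid: np.ndarray | None = None,
    ) -> Spectrum:
        """Top-of-canopy reflectance for one (leaf, canopy) parameter set."""
        if grid is None:
            grid = default_grid()
        grid = _check_grid(grid)
        if soil is None:
            soil = soil_library(grid)[canopy.soil_index - 1]
        if soil.wavelengths.shape != grid.shape or not np.allclose(
            soil.wavelengths, grid
        ):
            raise ValueError("soil spectrum must be defined on the simulation grid")
        refl, trans = self.leaf_optics(leaf, grid)
        k_ext = self._extinction(canopy)
        soil_term = soil.values * np.exp(-k_ext * canopy.lai * (1.0 + trans.values))
        leaf_term = refl.values * (1.0 - np.exp(-k_ext * canopy.lai))
        return Spectrum(grid, np.clip(soil_term + leaf_term, 0.0, 1.0))

    @staticmethod
    def _extinction(canopy: CanopyParams) -> float:
        return (0.5 + 0.4 * np.cos(np.deg2rad(canopy.ala))) / np.cos(
            np.deg2rad(canopy.sza)
        )

    def canopy_reflectance_batch(
        self,
        leaves: list[LeafParams],
        canopies: list[CanopyParams],
        grid: np.ndarray | None = None,
    ) -> np.ndarray:
        """Vectorized canopy reflectance for many parameter sets.

        Returns an (n_samples, n_wavelengths) array.  Functionally identical
        to looping :meth:`canopy_reflectance` with library soils.
        """
        if grid is None:
            grid = default_grid()
        grid = _check_grid(grid)
        k = self._coeffs(grid)
        leaf_mat = np.array(
            [
                [lf.cab, lf.ccx, lf.cw, 1000.0 * lf.cp, 1000.0 * lf.cbc]
                for lf in leaves
            ]
        )
        coeff_mat = np.stack([k["cab"], k["ccx"], k["cw"], k["cp"], k["cbc"]])
        n_struct = np.array([lf.n_struct for lf in leaves])[:, None]
        a = (leaf_mat @ coeff_mat) / n_struct
        s = np.clip(0.45 + 0.05 * (n_struct - 1.0), 0.0, 0.6)
        att = np.exp(-a)
        refl = s * att
        trans = (1.0 - s) * att
        soils = np.stack([sp.values for sp in soil_library(grid)])
        soil_vals = soils[[c.soil_index - 1 for c in canopies]]
        k_ext = np.array([self._extinction(c) for c in canopies])[:, None]
        lai = np.array([c.lai for c in canopies])[:, None]
        out = soil_vals * np.exp(-k_ext * lai * (1.0 + trans)) + refl * (
            1.0 - np.exp(-k_ext * lai)
        )
        return np.clip(out, 0.0, 1.0)


class ProsailAdapter:
    """Adapter for an external PROSAIL-PRO implementation.

    Instantiation fails with :class:`ConfigurationError` when the external
    library is not importable — the pipeline never falls back silently.
    """

    name = "prosail"

    def __init__(self) -> None:
        try:
            import prosail  # noqa: F401
        except ImportError as exc:
            raise ConfigurationError(
                "RTM backend 'prosail' requested but the 'prosail' package is "
                "not installed; install it or use backend='surrogate'"
            ) from exc
        self._prosail = prosail

    def leaf_optics(self, leaf: LeafParams, grid=None):
        raise NotImplementedError(
            "external PROSAIL-PRO leaf-only call not wired; use run_prosail"
        )

    def canopy_reflectance(self, leaf: LeafParams, canopy: CanopyParams, soil=None, grid=None):
        import numpy as _np

        if grid is None:
            grid = default_grid()
        rho = self._prosail.run_prosail(
            n=leaf.n_struct, cab=leaf.cab, car=leaf.ccx, cbrown=leaf.cbp,
            cw=leaf.cw / 1000.0, cm=leaf.cp + leaf.cbc, lai=canopy.lai,
            lidfa=canopy.ala, hspot=canopy.hot, tts=canopy.sza,
            tto=canopy.oza, psi=canopy.raa,
        )
        wl = _np.arange(400.0, 2501.0)
        return Spectrum(grid, _np.interp(grid, wl, rho))


_BACKENDS = {"surrogate": SurrogateRTM, "prosail": ProsailAdapter}


def get_backend(name: str = "surrogate", **kwargs):
    """Instantiate a forward-model backend by name.

    Raises :class:`ConfigurationError` for unknown names or unavailable
    external backends.
    """
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown RTM backend {name!r}; available: {sorted(_BACKENDS)}"
        ) from None
    return cls(**kwargs)


def _check_grid(grid) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 400.0 or grid.max() > 2500.0:
        raise ValueError("wavelength grid must lie within [400, 2500] nm")
    return grid
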