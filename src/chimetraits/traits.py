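"""Trait conversion equations linking field measurements to retrieval targets.

The four targets are leaf/canopy chlorophyll content (LCC, CCC) and
leaf/canopy nitrogen content (LNC, CNC):

* LCC = 8.24·exp(0.0324·SPAD)            [μg cm⁻²], SPAD-meter calibration
* LNC = 10·N_mass·LMA                    [mg cm⁻²], N_mass in %, LMA in g cm⁻²
* CCC = LCC·LAI / 100                    [g m⁻²]
* CNC = 10·LNC·LAI                       [g m⁻²]

All conversions are homogeneous of degree 1 in their content argument.
"""

from __future__ import annotations

import numpy as np

#: SPAD-to-LCC exponential calibration coefficients.
SPAD_COEF_A = 8.24
SPAD_COEF_B = 0.0324

#: Nitrogen-to-protein conversion factor: protein = 4.43 × nitrogen.
N_TO_PROTEIN = 4.43

ESU_COLUMNS = ["esu_id", "spad", "nmass", "lma", "lai", "lcc", "lnc", "ccc", "cnc"]


def spad_to_lcc(spad):
    """Leaf chlorophyll content (μg cm⁻²) from a SPAD reading."""
    spad = np.asarray(spad, dtype=float)
    if np.any(spad < 0):
        raise ValueError("SPAD readings must be non-negative")
    out = SPAD_COEF_A * np.exp(SPAD_COEF_B * spad)
    return float(out) if out.ndim == 0 else out


def lcc_to_spad(lcc):
    """Inverse of :func:`spad_to_lcc` (used when synthesizing SPAD readings)."""
    lcc = np.asarray(lcc, dtype=float)
    out = np.log(lcc / SPAD_COEF_A) / SPAD_COEF_B
    return float(out) if out.ndim == 0 else out


def lnc_from_nmass_lma(nmass, lma):
    """Leaf nitrogen content (mg cm⁻²) from N mass fraction (%) and LMA (g cm⁻²)."""
    nmass = np.asarray(nmass, dtype=float)
    lma = np.asarray(lma, dtype=float)
    if np.any(nmass < 0) or np.any(lma < 0):
        raise ValueError("nmass and lma must be non-negative")
    out = 10.0 * nmass * lma
    return float(out) if out.ndim == 0 else out


def ccc_from(lcc, lai):
    """Canopy chlorophyll content (g m⁻²) = LCC (μg cm⁻²) × LAI / 100."""
    out = np.asarray(lcc, dtype=float) * np.asarray(lai, dtype=float) / 100.0
    return float(out) if out.ndim == 0 else out


def cnc_from(lnc, lai):
    """Canopy nitrogen content (g m⁻²) = 10 × LNC (mg cm⁻²) × LAI."""
    out = 10.0 * np.asarray(lnc, dtype=float) * np.asarray(lai, dtype=float)
    return float(out) if out.ndim == 0 else out


def lnc_from_protein(cp):
    """Leaf nitrogen content (mg cm⁻²) from protein content cp (g cm⁻²).

    N = protein / 4.43, converted from g to mg.
    """
    out = 1000.0 * np.asarray(cp, dtype=float) / N_TO_PROTEIN
    return float(out) if out.ndim == 0 else out


def protein_from_lnc(lnc):
    """Protein content (g cm⁻²) from leaf nitrogen content (mg cm⁻²)."""
    out = N_TO_PROTEIN * np.asarray(lnc, dtype=float) / 1000.0
    return float(out) if out.ndim == 0 else out
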