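#!/usr/bin/env python
"""Build the training lookup table.

Samples 2000 leaf/canopy parameter sets from the configured distributions
(correlated pigment/water block included), simulates top-of-canopy
reflectance with the surrogate forward model, resamples to the 157 retained
CHIME-like bands, derives the four retrieval targets and adds 5% relative
noise.  Writes the LUT tables under results/.
"""

import logging
from pathlib import Path

from chimetraits.workflows import RunConfig, run_build_lut, save_config

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

OUT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    cfg = RunConfig(lut_size=2000, lut_seed=0, noise_level=0.05, noise_seed=1)
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    lut = run_build_lut(cfg)
    # the spectra matrix is several MB; it goes to scratch/, the summary
    # tables to results/
    lut.to_csv(SCRATCH / "lut_traits.csv", SCRATCH / "lut_spectra.csv")
    lut.band_grid.to_csv(OUT / "band_grid.csv")
    save_config(cfg, OUT / "lut_config.yaml")
    summary = lut.traits.describe().loc[["mean", "std", "min", "max"]].round(4)
    summary.to_csv(OUT / "lut_trait_summary.csv")
    print(f"LUT: {len(lut)} records x {lut.band_grid.n_retained} bands")
    print(summary)
    print(f"tables written to {SCRATCH}/lut_*.csv, summary to {OUT}/lut_trait_summary.csv")


if __name__ == "__main__":
    main()
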