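#!/usr/bin/env python
"""Train and validate the standard hybrid (HYB) models.

Fits one GP regression per trait x PCA configuration on the noised LUT and
scores it against the synthetic-campaign ESUs.  Writes a metrics table in
the trait x DR layout under results/.  Uses a 500-record LUT so the sweep
runs in minutes on one CPU.
"""

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from chimetraits.workflows import RunConfig, run_build_lut, run_synth, run_train

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = RunConfig(lut_size=500, noise_level=0.05, gpr_restarts=2)
    OUT.mkdir(exist_ok=True)
    lut = run_build_lut(cfg)
    table, spectra = run_synth(cfg)
    rows = []
    for trait in ("lcc", "lnc", "ccc", "cnc"):
        for dr in ("PCA5", "PCA10", "PCA15", "PCA20"):
            res = run_train(
                dataclasses.replace(cfg, trait=trait, dr_mode=dr),
                lut, table, spectra, method="hyb",
            )
            m = res["metrics"]
            rows.append({"trait": trait, "dr": dr, "r2": round(m.r2_display, 3),
                         "rmse": round(m.rmse, 4), "nrmse_pct": round(m.nrmse, 2),
                         "n": m.n})
    report = pd.DataFrame(rows)
    report.to_csv(OUT / "hyb_metrics.csv", index=False)
    print(report.to_string(index=False))
    print(f"\nwritten to {OUT}/hyb_metrics.csv")


if __name__ == "__main__":
    main()
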