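"""Diffusion-law analysis of the three membrane systems on synthetic data.

Generates z-scan diffusion-time grids for ground truths matching the three
studied GUV compositions (pure-POPC free diffusion; a fluid C1P18-containing
membrane with positive t0; the fast and slow populations of a gel-forming
C1P16 membrane), runs the full svzFCS stage on each, and tabulates the
recovered diffusion laws and confinement calls.

Writes results/fcs_laws.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from memdomain.fcs import classify_confinement, diffusion_law_from_series
from memdomain.synthetic import (OpticsSpec, SyntheticTruth,
                                 gen_diffusion_time_grid)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SYSTEMS = {
    # label: (D_eff um^2/s, t0 ms, kind)
    "POPC": (6.46, 0.00, "free"),
    "POPC:C1P18": (3.45, 1.14, "domain"),
    "POPC:C1P16 fast": (4.10, -0.92, "meshwork"),
    "POPC:C1P16 slow": (0.61, 94.4, "domain"),
}
WAISTS = (0.20, 0.25, 0.30, 0.35, 0.40)

rows = []
optics = [OpticsSpec(waist_w0=w) for w in WAISTS]
for i, (label, (d, t0, kind)) in enumerate(SYSTEMS.items()):
    truth = SyntheticTruth(d_eff=d, t0=t0, kind=kind)
    series = gen_diffusion_time_grid(truth, optics, n_vesicles=5,
                                     noise_cv=0.05, seed=SEED * 100 + i)
    law = diffusion_law_from_series(series)
    call = classify_confinement(law)
    rows.append({"system": label, "d_true": d, "t0_true": t0,
                 "d_eff": law.d_eff, "se_d_eff": law.se_d_eff,
                 "t0": law.t0, "se_t0": law.se_t0, "classification": call})
    print(f"{label:>16s}: D_eff = {law.d_eff:5.2f} +/- {law.se_d_eff:.2f} "
          f"um^2/s (true {d:5.2f}), t0 = {law.t0:6.2f} +/- {law.se_t0:.2f} ms "
          f"(true {t0:6.2f}) -> {call}")

df = pd.DataFrame(rows)
df.to_csv(OUT / "fcs_laws.csv", index=False)
print(f"\nwrote {OUT / 'fcs_laws.csv'}")
print("Free diffusion shows t0 ~ 0; nanodomain trapping shows t0 > 0; "
      "barrier meshworks show t0 < 0.")
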