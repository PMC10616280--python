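"""Detectability of a second diffusing population in autocorrelation curves.

Two populations with well-separated diffusion times (0.61 vs 94 ms scales,
ratio ~150, like a fluid phase coexisting with a gel phase) should be
detected as 2-population curves, while populations with similar times
(ratio 1.2) merge into one apparent component.  Measures both rates over
replicate noisy curves.

Writes results/population_selection.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from memdomain.fcs import select_population_model
from memdomain.synthetic import ACFModelParams, default_lag_grid, gen_acf_curve

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
N_REP = 60

CASES = {
    "separated (0.61 / 94 ms)": ([0.61, 94.0], 2),
    "similar (1.0 / 1.2 ms)": ([1.0, 1.2], 1),
}

lags = default_lag_grid(150)
rows = []
for label, (tau_d, expected) in CASES.items():
    hits = 0
    for rep in range(N_REP):
        curve = gen_acf_curve(ACFModelParams(10.0, tau_d, [0.5, 0.5]), lags,
                              noise_scale=0.02, seed=SEED * 10000 + rep)
        hits += select_population_model(curve) == expected
    rate = 100.0 * hits / N_REP
    rows.append({"case": label, "expected_populations": expected,
                 "correct_pct": rate, "n_replicates": N_REP})
    print(f"{label:>26s}: expected {expected} population(s), "
          f"correct in {rate:.1f}% of {N_REP} replicates")

pd.DataFrame(rows).to_csv(OUT / "population_selection.csv", index=False)
print(f"\nwrote {OUT / 'population_selection.csv'}")
print("Close diffusion times are indistinguishable on the autocorrelation "
      "curve and merge into a single apparent population.")
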