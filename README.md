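# memdomain

Detection and characterization of lipid nano- and microdomains in model
membranes, combining three views of the same physics:

1. **Diffusion-law analysis (svzFCS).** On giant unilamellar vesicles
   (GUVs), fluorescence correlation spectroscopy measures the diffusion
   time `τ_d` of labelled lipids through the focal spot.  Scanning the spot
   axially (z-scan) and fitting `τ_d(z)` with a parabola removes membrane
   positioning error; repeating at 5–6 beam waists `ω` yields the diffusion
   law

       τ_d = ω² / (4 D_eff) + t₀

   whose intercept diagnoses the membrane's lateral organisation:
   `t₀ ≈ 0` free diffusion, `t₀ > 0` transient trapping in nanodomains,
   `t₀ < 0` meshwork barriers.  Autocorrelation curves are fitted with a
   one- or two-population 2D lateral diffusion model
   `G(τ) = (1/N) Σ_k f_k (1 + τ/τ_dk)⁻¹`, with an F-test-based selector
   between the two.

2. **Vesicle Monte Carlo.** A closed, dynamically triangulated,
   self-avoiding two-component membrane (N vertices, tether lengths in
   `[l_min, 1.7 l_min]`) evolves by Metropolis vertex moves and bond flips.
   The energy is the Gompper–Kroll discretization of the Helfrich bending
   energy with per-vertex rigidity κ (27.3 k_BT matrix lipid; 32.6 or
   96.3 k_BT for fluid- or gel-like domain lipid) plus a nearest-neighbour
   attraction `W = −w · #(domain–domain bonds)` between domain vertices.

3. **Surface domain quantification.** On simulated meshes and on
   (synthetic or real) confocal z-stacks of GUVs, domains are segmented as
   connected regions — of domain-type vertices, or of surface points
   lacking fluorescence along centre-to-surface rays — and characterized by
   Fiji-style descriptors `circularity = 4π·area/perimeter²` and
   `roundness = 4·area/(π·major_axis²)` after a Lambert equal-area
   projection.  Domains are called nanodomains below 250 nm of maximal
   extent and microdomains from 300 nm; coverage histograms and their
   overlap select the attraction strength `w` that best matches reference
   data.

All inputs are synthetic with known ground truth (module
`memdomain.synthetic`), so every stage is validated by parameter recovery.

## Worked example

```python
from memdomain.synthetic import SyntheticTruth, OpticsSpec, gen_diffusion_time_grid
from memdomain.fcs import diffusion_law_from_series, classify_confinement

truth = SyntheticTruth(d_eff=3.45, t0=1.14, kind="domain")
optics = [OpticsSpec(waist_w0=w) for w in (0.20, 0.25, 0.30, 0.35, 0.40)]
series = gen_diffusion_time_grid(truth, optics, n_vesicles=5, noise_cv=0.05, seed=7)
law = diffusion_law_from_series(series)
print(f"D_eff = {law.d_eff:.2f} +/- {law.se_d_eff:.2f} um^2/s, "
      f"t0 = {law.t0:.2f} +/- {law.se_t0:.2f} ms -> {classify_confinement(law)}")
```

prints

```
D_eff = 3.40 +/- 0.04 um^2/s, t0 = 0.94 +/- 0.07 ms -> domain_confined
```

i.e. the pipeline recovers the planted diffusion coefficient and a
significantly positive intercept, classifying the membrane as
domain-confined.

The numbered drivers under `analysis/` run the full study on synthetic
data and write tables to `results/`:

```bash
python analysis/01_fcs_diffusion_laws.py    # diffusion laws of 4 systems
python analysis/02_population_selection.py  # 1- vs 2-population detectability
python analysis/03_vesicle_mc.py            # MC mixing/clustering + energies
python analysis/04_image_domains.py         # GUV stack segmentation + shapes
python analysis/05_w_selection.py           # coverage-histogram w selection
```

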