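# phenopipe

An analysis pipeline for high-throughput plant-imaging platforms. It
turns the three raw data streams such platforms produce — projected
shoot areas in pixels (two side views and one top view per plant),
automated pot weighing/watering logs, and a greenhouse temperature
record — into genetics-ready quantitative traits for a recombinant
inbred line (RIL) population grown under two watering regimes, and runs
the downstream genetic analysis (heritability, single-marker QTL scan
with permutation thresholds, allele-group bootstrap curves).

It is written for quantitative geneticists and phenomics researchers who
need a tested, reproducible path from pixel counts to QTLs, and it ships
a full synthetic-platform simulator with known ground truth so that every
stage can be validated end to end.

## What the pipeline computes

1. **Imaging geometry.** Side-view pixels convert to mm with a fixed
   pixel size (`side.coeff` = 0.5156 mm px⁻¹); the top-view pixel size
   depends on plant height via the side-view centre of mass,
   `top.coeff = top.slope·cm.pix + top.offset`
   (0.0001097 mm px⁻², 0.2899 mm px⁻¹). Projected areas scale with the
   squared pixel size.

2. **Calibration.** Destructive-harvest samples relate areas to dry
   *Biomass* (g), fresh *Plant weight* (g) and planimeter *Leaf area*
   (mm²) through the full second-order model
   `Y ~ side + top + side² + top² + side:top` and all 32 sub-models,
   compared by BIC; one shared model per trait is applied to both
   watering treatments.

3. **Thermal time.** All rates and durations are expressed at 20 °C
   using a modified Johnson temperature response
   `F(T) = A·T·exp(−ΔH_A/RT) / (1 + exp(−ΔH_A/RT)^{α(1−T/T0)})` with
   α = 3.5 for developmental processes; durations are integrated over
   the logged temperature series into equivalent days at 20 °C (d₂₀).

4. **Growth curves.** Per plant and trait, candidate growth models
   (linear, exponential, 3-parameter logistic, and richer sigmoids) are
   fitted by self-started nonlinear least squares and compared by BIC.
   For the logistic `V(t) = V_final / (1 + e^{−K(t−t0)})`, `t0` is the
   inflexion (vegetative→reproductive transition, Tx) and `K` the
   maximum relative growth rate (K_RGR). Averages over the 35–50 d₂₀
   window give Growth_AVE, RGR, LER_AVE, RER.

5. **Water use.** Pot-weight differences between waterings, corrected
   for modelled plant weight and for soil evaporation measured on
   artificial-plant pots, give transpiration. A Van Genuchten
   water-release curve fitted to pressure-chamber data converts soil
   water content to soil water potential Ψ (MPa). Derived traits:
   TR (g d₂₀⁻¹), TR_area (g mm⁻² d₂₀⁻¹), WUE = ΔBiomass/transpiration
   (g g⁻¹), and relative responses (Variable_D − Variable_WW)/(Ψ_D − Ψ_WW).

6. **Genetics.** Per treatment: variance components and broad-sense
   heritability h² = σ²_G/(σ²_G + σ²_e/r) on a line-mean basis; a
   single-marker scan (trait ~ covariates + marker, F statistic) with a
   genome-wide threshold from 1000 permutations of the phenotypes; and
   bootstrap mean growth curves per allele class.

## Worked example

```python
from phenopipe import (SimulationConfig, simulate_experiment,
                       run_pipeline, PipelineConfig, qc_report)

cfg = SimulationConfig(seed=42, n_lines=40, n_reps=2)
data = simulate_experiment(cfg)          # virtual platform experiment
result = run_pipeline(data, PipelineConfig(), seed=42)
print(qc_report(result))
```

prints (abridged):

```
Pipeline QC report
========================================
n_plants                         160
n_failures                       0
n_nonconverged_fits              0
...
--- drought ---
trait                       mean±SD                (min–max)     h2%         P
Growth_AVE         0.1226 ±   0.0295 (  0.06196–   0.1958)    35.0      0.09
LER_AVE              1156 ±      281 (    579.4–     1823)    34.3     0.095
TR                  29.93 ±       10 (    13.19–    55.25)    46.6     0.026
WUE              0.004275 ± 0.000788 (  0.00242– 0.006394)    43.6     0.038
--- well_watered ---
Growth_AVE         0.2951 ±    0.122 (   0.1024–   0.6985)    20.6      0.24
TR                  76.73 ±       29 (    25.92–    157.7)    25.0      0.18
WUE              0.003833 ±  0.00048 ( 0.003049– 0.005045)    51.6     0.012
```

Reading it: droughted plants grow at ~0.12 g d₂₀⁻¹ versus ~0.30 g d₂₀⁻¹
well-watered, transpire ~30 g d₂₀⁻¹ versus ~77 g d₂₀⁻¹, and WUE is
~0.004 g biomass per g water in both regimes; heritabilities of the
derived traits span 0–52%. By construction WUE × TR = Growth_AVE for
every plant.

The same workflow is available from the shell:

```bash
phenopipe simulate --out exp/ --seed 1            # write the five CSVs + truth/
phenopipe run-all --data exp/ --out run/ --seed 1 # run all stages, QC report
phenopipe report --run run/
```

## Data layout

A simulated (or real, if formatted identically) experiment directory
contains `images.csv` (plant_id, day, side_area_px, top_area_px,
cm_pix), `pot_logs.csv` (plant_id, treatment, time_d, weight_before_g,
weight_after_g, water_added_g, is_artificial), `temperature.csv`
(timestamp_h, temp_C), `calibration.csv` (harvest areas + measured
traits), `water_release.csv` (pot, theta, psi_MPa), `genotypes.csv`
(line_id, marker, call A/B) and `marker_map.csv`. Simulator ground truth
lives under `truth/` and is never read by the analysis. See
`docs/methods.md` for the model details and design choices.
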