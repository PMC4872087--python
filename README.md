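# readerscreen

Analysis and simulation toolkit for ligand-discovery screening against
methyl-lysine reader proteins (e.g. the Spindlin1 Tudor-like domain reading
H3K4me3). The package implements the quantitative chain behind a five-readout
orthogonal screening platform:

- **Alpha** (bead-proximity chemiluminescence): plate QC (Z'-factor,
  signal/background), percent inhibition, 4PL IC50 fitting, TruHits quench
  counter-screening, and hook-point detection in cross-titration matrices.
- **Fluorescence polarization (FP)**: intensity-to-mP conversion, G-factor
  calibration, the specific-binding correction chain
  (P_M, P_I → F_B, P_NS, P_S), probe K_D fitting, and displacement IC50s.
- **Fluorescent thermal shift (FTSA/DSF)**: Boltzmann melt-curve fitting,
  ΔT_m, and a coupled unfolding–binding thermodynamic model that converts a
  ligand-dosing T_m series into a binding constant.
- **Biolayer interferometry (BLI)**: 1:1 Langmuir sensorgram models, global
  (k_a, k_d, R_max) fitting with K_D = k_d/k_a, report-point displacement,
  dissociation-rate shifts, and regeneration QC.
- **CETSA**: immunoblot band-intensity normalization, aggregation-temperature
  (T_agg) fitting, and ligand-induced ΔT_agg.

Every readout has a seeded generative simulator that emits the canonical
table the matching analyzer consumes plus a ground-truth record, so the whole
pipeline is testable end to end without instrument data. A three-species
competitive-equilibrium solver (receptor + probe + competitor) underpins the
displacement assays.

## Worked example

Simulate an Alpha displacement plate at the platform's Spindlin1 conditions
(15 nM receptor, 30 nM biotin-H3K4me3 probe with K_D 250 nM, competitor
calibrated to an apparent IC50 of 117.5 nM), then recover the IC50:

```python
import numpy as np
from readerscreen import (EquilibriumSpec, competitor_kd_for_ic50,
                          half_displacement_dose, simulate_displacement_plate)
from readerscreen.pipelines import analyze_alpha_ic50

kd_comp = competitor_kd_for_ic50(15e-9, 30e-9, 250e-9, 117.5e-9)
spec = EquilibriumSpec(15e-9, 30e-9, 250e-9, kd_competitor=kd_comp)
plate, truth = simulate_displacement_plate(
    "alpha", spec, np.geomspace(1e-9, 1e-5, 12), seed=7)
res = analyze_alpha_ic50(plate)
print(half_displacement_dose(spec))   # 1.175e-07  (theoretical IC50, M)
print(res["fit"].ic50)                # 1.0953e-07 (fitted from noisy plate)
print(res["qc"]["z_prime"])           # 0.9269
print(res["qc"]["signal_to_background"])  # 637.86
```

Kinetics from simulated sensorgrams (truth k_a = 9.43e4 /M/s,
k_d = 1.35e-3 /s, so K_D = 14.32 nM):

```python
from readerscreen import simulate_bli
from readerscreen.pipelines import analyze_bli_kinetics

sgs, ref, _ = simulate_bli(9.43e4, 1.35e-3, 1.0,
                           [12.5e-9, 25e-9, 50e-9, 100e-9, 200e-9, 400e-9],
                           seed=7)
r = analyze_bli_kinetics(sgs, ref)
print(r["ka"])        # 95234.7
print(r["kd_rate"])   # 1.33206e-03
print(r["kd_eq_M"])   # 1.39871e-08
```

The same stages are available from the command line, driven either by flags
or a schema-validated JSON config:

```
readerscreen simulate --kind ftsa --seed 7 --out results/sim
readerscreen ftsa --melt results/sim/melt.csv --protein-total "3.88 uM"
readerscreen qc --plate plate.csv          # exit status 1 if Z' <= 0.5
```

## Layout

| Module | Contents |
| --- | --- |
| `readerscreen.core_quant` | plate statistics, 4PL, hook detection |
| `readerscreen.equilibrium` | 1:1 and competitive solvers, hyperbola fit |
| `readerscreen.fp` | mP conversions, correction chain, K_D/IC50 fits |
| `readerscreen.ftsa` | melt fitting, dosing model, K_D from T_m series |
| `readerscreen.bli` | Langmuir models, global kinetic fit, QC |
| `readerscreen.cetsa` | normalization, T_agg fitting, ΔT_agg |
| `readerscreen.simulate` | seeded generators + ground-truth records |
| `readerscreen.pipelines` / `runner` / `cli` | stage orchestration and CLI |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
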