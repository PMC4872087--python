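# Methods

Model assumptions, parameter conventions, numerical choices and known
limitations of the `readerscreen` toolkit.

## Binding equilibria

All displacement readouts reduce to the three-species equilibrium

    R + P ⇌ RP   (K_P)        R + C ⇌ RC   (K_C)

with mass balance on receptor R, labeled probe P and unlabeled competitor C.
The solver reduces the system to a single equation in free receptor and
root-finds with bracketing on [0, R_total] (`scipy.optimize.brentq`), which
converges for any physical input without a starting guess. The 1:1 special
case uses the numerically stable form of the quadratic (computing the smaller
root via the product of roots) to avoid cancellation.

*Accuracy*: agreement with an independent damped fixed-point oracle is at
machine precision (~1e-16 scaled) over concentrations and K_Ds spanning
1e-12–1e-3 M. For near-stoichiometric, very tight binding the *free* species
are obtained by subtraction from totals, so their relative error grows like
eps·(total/free)²; bound-species concentrations remain accurate.

Apparent IC50s are *conditions-dependent*: `half_displacement_dose` returns
the competitor dose halving probe occupancy, and `competitor_kd_for_ic50`
inverts it, so a reported IC50 can be mapped to the competitor K_D that
produces it at given receptor/probe concentrations. No Cheng–Prusoff
conversion is applied anywhere.

## Plate statistics (Alpha)

- Percent inhibition I = 100·(1 − (A_I − μ_min)/(μ_max − μ_min)), unclipped
  so QC can see out-of-range wells. Affine-invariant by construction.
- Percent quench uses the same normalization against TruHits controls.
- Z' = 1 − 3·(SD_max + SD_min)/|μ_max − μ_min| with sample SDs (ddof = 1);
  gate defaults to Z' > 0.5.
- The 4PL is fitted on log10 concentration with variable slope; replicates
  are averaged per dose, initialization from the half-range crossing. Flat
  series and IC50s outside the titrated range are flagged, never silently
  returned.
- Hook detection reports the concentration of the per-line raw maximum when
  any later point drops by more than 10% of that maximum; monotone lines
  return `None`.

## Fluorescence polarization

P = (I_S − G·I_P)/(I_S + G·I_P)·1000 mP; background (protein
autofluorescence) is subtracted channel-wise at intensity level, because mP
is nonlinear in the intensities. Total intensity defaults to 2·I_P + I_S
(the plate-reader convention this pipeline was built around). The correction
chain applies, in order: F_B = (P_M − P_D*)/(P_D*R − P_D*),
P_NS = (P_I − P_D*)·(1 − F_B), P_S = P_M − P_NS; P_S + P_NS = P_M holds
exactly.

Probe K_D fitting defaults to the one-site hyperbola against **total**
receptor concentration, reproducing the conventional plate analysis. When
probe ≈ K_D this overestimates K_D by roughly half the probe concentration
(≈ +5 nM at 10 nM probe / 31 nM K_D); the `depletion_corrected=True` mode
fits the exact 1:1 bound fraction instead and removes the bias. After
baseline subtraction, noise-driven slightly negative responses are clipped
to 0 (the hyperbola's domain).

Reference defaults follow the platform: P_D* = 25 mP, P_D*R = 225 mP,
G = 0.91.

## FTSA (thermal shift)

Two-state unfolding N ⇌ U coupled to native-state binding N + L ⇌ NL.

- K_U(T) from Gibbs–Helmholtz with ΔH_U [kJ/mol] at the reference melt T_r
  and ΔCp_U [kJ/(mol·K)].
- K_b(T) from the van't Hoff relation anchored at K_b(T₀) with ΔH_b and
  optional ΔCp_b.
- Dosing relation (at T_m, half the protein is unfolded):
  L_t = (K_U − 1)·(1/K_b + M_t/(2·K_U)). `predict_tm` inverts it by
  bracketed root finding; `unfolded_fraction` solves the full three-species
  system independently and confirms f_U(T_m) = 0.5 to ≤1e-6.

Defaults (all configurable, all echoed in reports): ΔH_U estimated from the
reference curve's Boltzmann steepness via van't Hoff if not given,
ΔCp_U = 8 kJ/(mol·K), ΔH_b = −42 kJ/mol, ΔCp_b = 0, reporting temperature
T₀ = 37 °C. The reported K_D depends materially on T₀ and on the assumed
enthalpies — these are explicit assumptions, not fitted quantities.

Melt curves are fitted with a 6-parameter Boltzmann (midpoint, steepness,
linear pre/post baselines) after truncating at the global maximum (standard
handling of post-transition dye loss). Initialization is robust to
multiplicative noise: a smoothed half-crossing for the midpoint and the
quartile-crossing width for the steepness. Flat traces (dye-only controls)
and monotone-decreasing traces return explicit no-transition results.

## BLI

1:1 Langmuir: R(t) = R_eq·(1 − e^(−k_obs·t)) with k_obs = k_a·c + k_d and
R_eq = R_max·c/(c + k_d/k_a) in association; first-order decay in
dissociation. Global fitting shares (k_a, k_d, R_max) across curves, rates
searched in log space, with the dissociation initial value anchored at the
true association-phase boundary (not the last sampled point). K_D = k_d/k_a
is derived, never stored. Curves whose dissociation decays < 5% are flagged:
k_d is then poorly constrained. Preprocessing: buffer-reference subtraction
on an interpolated common grid (removes shared drift exactly), then
re-zeroing on the late-baseline mean.

## CETSA

Band intensities are normalized per membrane (min–max to 0–100%, or relative
to the lowest-temperature sample); both modes are invariant under positive
rescaling, so blot exposure does not bias the curve. A decreasing Boltzmann
sigmoid yields T_agg; monotone-increasing data are rejected as
wrong-orientation, flat data return no-transition. Replicate membranes are
fitted independently and averaged per condition.

## Simulators

Each simulator draws all randomness from `numpy.random.default_rng(seed)`
and returns a `SimTruth` record; the same seed regenerates output
bit-identically. `stream_seeds` fans a master seed into independent
sub-stream seeds (all < 2³¹). Default noise models: Alpha and CETSA 5% CV
multiplicative log-normal (mean-1 parameterization), FP 1 mP additive
Gaussian, FTSA 2% CV log-normal, BLI 0.01 nm additive Gaussian plus optional
shared linear drift mirrored in the reference trace.

What they emulate: equilibrium-limited well signals, bead-capacity hook
attenuation min(1, capacity/total) per bead species, the FP intensity pair
rendered through the G-factor, the coupled-equilibrium melt signal with
linear dye baselines, phase-structured sensorgrams, and blot-scaled
aggregation curves. What they do **not** emulate: binding kinetics on the
plate (incubation-time effects), inner-filter and singlet-oxygen chemistry,
mass-transport limitation in BLI, aggregation kinetics, pipetting and
edge-position effects, or detector saturation.

## Known limitations

- **FTSA Boltzmann-midpoint skew.** With ΔCp_U ≠ 0 the simulated melt is
  asymmetric, and the symmetric Boltzmann's midpoint carries a small
  dose-dependent bias (≈ +0.005 to +0.04 °C at ΔCp_U = 8 kJ/(mol·K)). Chained
  through the dosing fit this contributes ≈1% K_D error even on noiseless
  curves; at ΔCp_U = 0 the chain inverts to ≈0.01%. Fitting T_m series
  generated directly by `predict_tm` is exact at any ΔCp_U.
- **Post-peak dye decay.** Enabling `post_peak_decay` in the FTSA simulator
  shifts the truncated fit's T_m by up to ≈+0.2 °C at strong decay; the
  default simulation uses flat unfolded baselines.
- **FP total-receptor K_D bias** of ≈ +probe/2 when probe ≈ K_D (see above);
  use the depletion-corrected mode when the probe is not in trace excess.
- **BLI identifiability**: jointly rescaling all analyte concentrations by λ
  rescales the fitted k_a by 1/λ (k_obs is unchanged), so concentration
  accuracy limits k_a accuracy; and with < 5% dissociation decay k_d is
  reported but flagged unreliable.
- The 4PL IC50 of a simulated displacement curve is an approximation: the
  exact competitive-equilibrium curve is not logistic, so fitted IC50s agree
  with the theoretical half-displacement dose to a few percent, not exactly.
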