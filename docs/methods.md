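# Methods

This note documents the models implemented in `peptiport`, their
assumptions, the defaults that matter, and what the synthetic-data
generators do and do not emulate.

## Protonation speciation (`peptide_chem`)

Ionizable groups are treated as independent titratable sites. The
protonated fraction of a group with acid constant pKa at a given pH is the
Henderson–Hasselbalch expression f = 1/(1 + 10^(pH−pKa)); a microstate's
fraction is the product of its per-group probabilities, which is exactly
the Boltzmann weight 10^Σ(pKa−pH) over protonated sites after
normalization. Site–site coupling (shifted pKa of one group when another is
charged) is deliberately not modelled; the microstate reasoning used to
interpret transport data is a product-of-states argument, and coupling
corrections are small compared with the integer charge/proton differences
the analysis relies on.

pKa defaults: His 6.0, Glu 4.1, Lys 10.5 (the values the transport
interpretation is anchored to); Asp 3.9, Cys 8.3, Arg 12.5, Tyr 10.1 from a
standard biochemistry table; α-amino 8.0 and α-carboxyl 3.1 when termini
are enabled. All are per-peptide overridable.

Termini are **off by default**. Between pH ~4.5 and ~7.5 both termini of a
dipeptide are essentially fully charged and cancel as a zwitterionic pair,
so they change neither the net charge nor the proton bookkeeping of
transport between a pH-5 compartment and a pH-7.2 cytosol. Enabling them
(`include_termini=True`) gives full titration curves, at the cost of
expanding the state space 4-fold.

Monoisotopic [M+H]+ values are the sum of residue masses
(`pyteomics.mass.std_aa_mass`), water (18.010565 Da), one proton
(1.007276 Da) and any configured heavy-isotope shifts, reported to four
decimals — the precision used to match dipeptide ions in SIM/MRM lists.

## Transport stoichiometry (`stoichiometry`)

For a transported microstate, z is its net side-chain charge, h the
protons released on re-equilibration at cytosolic pH, and r = h/z the
protons per translocated elementary charge.

* **ideal** mode (default): h counts one full proton per group that entered
  protonated and has pKa < pH_cyt. This yields the integer predictions
  (Lys–Ala 0, His–Ala/His–Ser/Glu–Lys⁺ 1, His–Glu⁺ 2) that classify
  substrates.
* **equilibrium** mode: h sums the fractional release 1 − f(pKa, pH_cyt)
  over groups entering protonated, and *subtracts* f(pKa, pH_cyt) for
  groups entering deprotonated (protonation on arrival consumes a cytosolic
  proton). It converges to ideal mode as pH_cyt − pKa → ∞ and is provided
  as a physically symmetric refinement.

Sign conventions: positive r means cytosolic acidification. At the trace
level inward (cation-influx) currents are negative; z here is the species
charge itself, so a −300 nA current carried by a z = +1 species is
consistent.

Ensembles: a transport-weighted mixture reports Σw·z, Σw·h and their
ratio. An electroneutral, proton-carrying species (the His–Glu zwitterion)
adds protons without current, which is how measured ratios can exceed any
single-species r.

## Thermodynamics (`thermo`)

Convention: Δψ = ψ_cyt − ψ_lum, fixed everywhere and property-tested. A
"positive-inside" (lumen-positive) lysosome has Δψ < 0 under this
convention. Worked sign table for a cation at equal concentrations:

| situation         | Δψ    | zFΔψ | ΔG(lum→cyt) | direction |
|-------------------|-------|------|-------------|-----------|
| lumen positive    | < 0   | < 0  | < 0         | export    |
| lumen negative    | > 0   | > 0  | > 0         | import    |

Equilibrium accumulation of a species of charge z is exp(−zFΔψ/RT);
ΔG(lum→cyt) = RT·ln(c_cyt/c_lum) + zFΔψ. Concentrations are treated as
activities (ideal solution). Default temperature 293.15 K (room-temperature
recordings). The lysosomal membrane-potential magnitude is a configuration
parameter; it has no universally agreed value and nothing in the package
depends on a specific default.

Total-substrate accumulation for a titratable peptide transported in a
subset of its microstates: fractions on each side are pinned by the local
pH, each transported species is driven toward its own Nernst ratio ρ_i, and
the zero-net-flux total ratio under equal per-species rate constants is

    T_cyt/T_lum = Σ_i f_i(pH_lum) / Σ_i f_i(pH_cyt)/ρ_i.

With one transported species this is f_lum/f_cyt · ρ — e.g. transporting
only protonated His–Ala between pH 5.0 and pH 7.2 at Δψ = 0 concentrates
total peptide 15.3-fold in the cytosol, the "proton carried on the
substrate" coupling of a uniporter to the pH gradient. With several
transported species the individual Nernst equilibria are generally
incompatible, which is why the implementation uses the flux-balance steady
state; an explicit relaxation oracle (`equilibrate_numerically`) verifies
the closed form in the tests.

## Kinetics (`kinetics`)

Michaelis–Menten and competitive-inhibition models with unweighted
nonlinear least squares (lmfit, single deterministic start): v_max
initialised at the largest response magnitude, K_M at the dose nearest
half of it, K_M bounded to [min positive dose/10, max dose×10]. Responses
keep their native sign; fitting runs on magnitudes and the sign is
restored. Competitive (not mixed or noncompetitive) inhibition is assumed
because co-applied dipeptides compete for the single substrate site; K_I
inversion from fractional inhibition is the exact algebra
K_I = K_M·I·(1−φ)/((K_M+S)·φ), with φ = 1 ("abolished") returning a
flagged lower bound of 0. Initial rates are ordinary least-squares slopes
over an explicit window (≥5 samples). Weighting schemes and Hill-type
cooperativity are out of scope.

## Thermal shifts (`thermal_shift`)

Two-state unfolding with ΔCp = 0: ΔG(T) = ΔH(1 − T/T_m), unfolded fraction
K/(1+K), sloped linear native/unfolded baselines (real fluorescence ratios
drift). Defaults: grid 20–95 °C at 0.25 °C, ΔH 400 kJ·mol⁻¹, ratio noise
sd 0.002 (intrinsic-fluorescence ratios are low-noise signals).

T_m extraction, derivative method: the signal is smoothed with the fixed
5-point centred window; the first derivative is smoothed again with a
9-point window and its maximum refined by a quadratic fit over ±3 °C.
(The transition is several °C wide, so the extra ~2 °C kernel cannot
displace the peak; it suppresses grid-scale noise in the argmax.) A trace
whose derivative peak does not exceed the median derivative by 6 robust
standard deviations is flagged featureless, with no T_m — the behaviour
expected of destabilised mutants that show no unfolding transition. The
model-fit method refits the full two-state expression.

K_D from stabilization uses the saturation model
ΔT_m(L) = ΔT_m_max·L/(K_D+L). This is a deliberate simplification of
thermodynamic-coupling treatments: it is identifiable from (L, T_m) pairs
alone and needs no unfolding enthalpy as input. Consequences: K_D values
are apparent at the melting temperature, and agreement with
coupled-equilibrium analyses is expected only within a factor of order
unity. Ligands whose largest shift stays below 0.5 °C (instrument
repeatability scale) are flagged non-binders; a fitted K_D outside the
sampled concentration range is warned about, not rejected.

## Assay analysis (`assay_analysis`)

Evoked current: mean(plateau) − mean(baseline) over explicit,
non-overlapping event windows (≥2 s each); windows are half-open
[start, end) so an epoch boundary sample belongs to the epoch that starts
there. Plateau/baseline windows are annotations, not auto-detected.

Acidification: least-squares slope of the electrode voltage over a ≥10 s
window, divided by the calibration slope (−59 mV per pH unit by default).
The reported rate is positive for acidification; with the negative
calibration slope this means a *falling* electrode trace reads as
acidification, and the synthetic generator renders its traces with the
same convention, keeping generator and analyzer consistent. Whether the
normalized ratio uses mV·s⁻¹ or pH·s⁻¹ is immaterial — the calibration
constant cancels in the normalization. The default initial-slope window is
30 s; the choice only matters if acidification saturates within the epoch.

The ratio statistic r̂(X) = (acid_X/acid_ref)/(I_X/I_ref) requires the
reference substrate in the same cell and a reference current magnitude of
at least ~100 nA — below that the acidification–current proportionality is
unreliable, so the whole cell's ratios are flagged invalid rather than
silently reported. The threshold is a validity flag, not an exclusion of
test substrates. Signs are carried through, so a proton-free substrate can
legitimately show a slightly negative r̂ at the noise floor.

Current→flux: |I|/(|z|F), reported in pmol·s⁻¹; z = 0 is rejected because
electroneutral transport carries no current.

Pyranine processing divides the 415 nm by the 460 nm excitation channel
and normalizes by the mean over the first 25 s after peptide addition (the
window mean is exactly 1 by construction). Initial uptake rates are slopes
after the valinomycin event; rates are reported as percent of a reference
substrate.

Tracer quantification fits a straight calibration line *with* intercept
(blank signal) through ≥4 standards per analyte, interpolates sample areas
to pmol, flags out-of-range samples as extrapolated, converts to rates via
the incubation duration, and reports the released-product molar ratio
(equimolar release of both residues is the signature of complete
intracellular cleavage). Chromatographic peak integration is out of scope;
areas are inputs.

## Synthetic data (`synthetic_data`)

All generators are pure functions of (config, seed) via independent
`numpy` `SeedSequence` streams; reruns are byte-identical, ground truth is
always returned alongside the data, and zero-noise runs make every
pipeline exact.

* **Dual recording**: four substrates (His–Ala reference, His–Ser,
  Lys–Ala, cationic His–Glu) applied for 60 s each with 30 s baselines at
  10 Hz; plateau currents a few hundred nA (Michaelis–Menten at a 10 mM
  dose with K_M 2.6 mM), Gaussian current noise 5 nA, drift
  0.02 nA·s⁻¹. Proton influx r·|I|/F is integrated into pH through a
  single lumped coupling constant κ = 3.2×10⁸ pH·mol⁻¹ (buffering capacity
  × volume; chosen to give ~10⁻³ pH·s⁻¹ at a 300 nA, r = 1 epoch — the
  scale at which electrode recordings resolve acidification), rendered in
  mV at −59 mV/pH with 0.05 mV noise. κ is not separately identifiable and
  the ratio statistic cancels it; the tests exploit exactly that.
* **Pyranine liposomes**: one trace per substrate plus a protein-free
  control; after the valinomycin event the normalized ratio declines with
  initial slope equal to the configured Michaelis–Menten rate, saturating
  with τ = 600 s; channels carry 0.2% multiplicative noise. The dye
  response is linearized around the assay pH — the full pKa-shaped
  response and ionophore kinetics are not emulated, so only
  normalized/relative quantities are meaningful.
* **Tracer**: complete cleavage by default (product ratio exactly 1 in
  truth), 1.32 pmol·s⁻¹ for 20 min, a 2% injected fraction placing samples
  mid-calibration (standards 0.5–100 pmol), 3% multiplicative area noise,
  mock samples at blank level.
* **Melt titrations**: T_m(L) from the saturation model (apo 40 °C,
  ΔT_m_max 12 °C, K_D 318 µM, eight concentrations 0–10 mM); either full
  melt curves or direct (L, T_m) pairs with 0.3 °C T_m noise, triplicate
  by default — the usual thermal-stability design of three independent
  measurements.
* **Genotype table**: log-normal abundances (CV 30%), n = 5 per genotype,
  default 4-fold knockout increase, a per-sample global scale factor and an
  internal-standard column whose normalization removes that factor
  exactly.

What passing tests on these data do **not** show: robustness to electrode
drift and perfusion artifacts, chromatographic peak-shape effects,
instrument-specific pyranine response curvature, or pKa shifts from the
local protein environment. The generators define clean, seeded versions of
each assay's information content, not replicas of instrument output.

## Numerical choices and degenerate inputs

* Invalid arguments (non-finite pH, negative concentrations, z = 0 flux
  conversion, overlapping windows, zero calibration slope) raise
  `ValueError` with a named diagnostic; degraded-but-valid outcomes
  (sub-threshold reference, non-binder, extrapolated sample,
  under-determined fit) return flagged results instead of raising.
* Fits are deterministic: fixed initialisation, fixed bounds, no
  multi-start.
* Species labels use ASCII charge marks on three-letter residue names
  ("His+–Glu-"), residue 1 before residue 2; termini marks, when modelled,
  are appended in brackets.
* The test and acceptance workloads are sized for interactive runs: 100
  replicates for recovery suites, 10 seeds for the end-to-end dual
  recording, ~10⁴ samples per synthetic trace.

## Known limitations

Tripeptides and longer substrates, site–site pKa coupling, Hill/global
kinetic fits, Bayesian uncertainty, organelle volume/osmotic dynamics, raw
instrument-file parsing and structural rationalization of selectivity are
all out of scope. K_D estimates from thermal shifts are apparent values of
a simplified model (see above) and are not expected to reproduce
coupled-equilibrium analyses of real instrument data exactly.
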