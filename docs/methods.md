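# Methods

This note records the models, numerical choices and validation strategy
behind `tetrafit`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under which assumptions, with
which defaults, and what the tests do and do not demonstrate.

## Sedimentation-equilibrium model

The forward model (`tetrafit.sedeq`) is the ideal, single-phase
equilibrium distribution: every species follows
`c(r) = c(r0)·exp[σ(r²−r0²)/2]` with
`σ = M(1−v̄ρ)ω²/(RT)`. Units are cgs throughout (radii in cm, masses in
g/mol, `R = 8.314×10⁷ erg·mol⁻¹·K⁻¹`, ω from rpm), which keeps σ in
cm⁻² — the AUC convention. Solution non-ideality (second virial
coefficients), meniscus/bottom mass conservation, pressure effects and
time-dependence are deliberately out of scope; the model is the
conventional equilibrium treatment appropriate for dilute (≤ tens of µM)
protein solutions.

Chemical coupling is imposed at the reference radius through mass
action (`c_dimer = c_A²/K_d`; `c_complex = c_A²·c_B₂/K_d` for the 2:2
scheme) and propagates to all radii because the complex v̄ is defined as
the mass-weighted mean of its components. That choice is not merely
conventional: it is the unique definition that makes buoyant masses
additive, `σ_complex = Σ stoich·σ_i`, so the mass-action residual
vanishes identically along the whole radial profile. The test suite
checks this to machine precision. Complex extinction is the sum of the
component extinctions (chromophores are conserved on binding).

K_d is stored and fitted in the dissociation direction. For the 2:2
hetero-complex its units are M², a consequence of treating the two
ligand chains as independent monomers binding a preformed receptor
dimer.

## Global fitting

`tetrafit.fitting` minimizes the unweighted sum of squared absorbance
residuals over all channels jointly (trust-region least squares via
lmfit/SciPy, convergence tolerances 10⁻¹²). Parameterization:

* masses — linear scale, bounds [0.2×, 5×] the initial value, shared
  across channels;
* K_d and reference concentrations — log₁₀ scale (both are positive
  scale parameters spanning decades); default K_d search windows are
  10⁻¹²–10⁻³ M (monomer–dimer) and 10⁻¹⁸–10⁻⁶ M² (2:2);
* baseline — one radially constant offset per channel, default 0 and
  fixed; real absorbance optics have offsets, so it can be floated.

When K_d floats, the optimizer is restarted from 5 log-uniform draws
over the K_d window (seeded, recorded in the result); the best χ² wins.
A fit whose K_d lands within 0.05 log-units of a window edge is flagged
`kd_at_bound` — the signature of data that contain no detectable
association (only a bound, not a value, is supported). A fit in which
every σ is zero (no rotor field, or exact neutral buoyancy) is rejected
up front as non-identifiable rather than returned as a silent
degenerate optimum.

Reference concentrations float per channel even in "association only"
fits: at equilibrium the free concentration at the reference radius
depends on rotor speed, so it cannot be fixed a priori from the loading
concentration without a mass-conservation model, which is out of scope.
Mass and K_d are never floated together in the shipped workflows — the
fix/float pattern is: masses floated for oligomeric-state
determination, K_d floated (masses, v̄, ρ, ε fixed) for energetics.

Chi-square profiling fixes K_d on a log-spaced grid (default 25 points,
±2 decades), re-fits all nuisance parameters at each point, and
interpolates the crossings of χ²_min + Δχ² in log K_d. The Δχ²
threshold defaults to 4.0 and is configurable and reported, since the
"sharp rise" criterion in common use is not standardized; profiles that
cross on one side only return a one-sided bound, and bounds are also
exposed rounded to the nearest decade (as −log₁₀ K_d) because
order-of-magnitude statements are the honest resolution of such data.
Re-fitting all nuisance parameters during profiling is the conservative
choice (bounds can only widen relative to holding them fixed).

Condition series (temperature, NaCl, pH) are fit independently per
condition and summarized either as an apparent single-species mass —
whose decrease with temperature is the classic signature of a weakening
dimer — or as −log₁₀ K_d. Failed conditions are flagged and retained,
never dropped.

## CD reductions

Mean residue ellipticity is `[θ] = θ_obs·MRW/(10·l·c)` (θ_obs in
degrees, l in cm, c in mg/ml), stored in deg·cm²·dmol⁻¹ and printed in
units of 10³ where compact. The fully helical 222-nm reference is
`[θ]₂₂₂ = −40×10³(1−4.6/n)`; the sign is negative (helix minimum) and
the chain-length correction makes the magnitude grow from short
peptides toward the 40×10³ asymptote. Percent helicity is
|measured|/|reference|, clipped at 105% with a warning; helical residue
counts round half-to-even. Two arithmetic notes for users comparing
against literature values computed by hand: the formula gives 35.9×10³
(not 35.8) at n = 45, and 145 residues at 73% helicity span
145×0.73×1.5 = 158.8 Å — small discrepancies against some published
roundings are the formulas' exact outputs, and the package always
reports the latter. `n` is an explicit parameter everywhere (expression
tags can leave an extra residue on a construct, shifting n by one).

T_m extraction smooths the 222-nm melt with a local quadratic
(Savitzky–Golay, default window 5 points) before central-difference
differentiation — "the first derivative of the data" needs a noise
policy — and takes T_m at the derivative extremum. A transition is
declared only when that extremum exceeds 3× the median absolute
derivative (with an absolute floor against floating-point dust), making
"no transition" (a disordered chain) a testable outcome rather than a
qualitative judgment.

## Sequence properties

Charge is the Henderson–Hasselbalch sum over termini and D/E/C/Y/H/K/R
side chains; it is strictly decreasing in pH, so the isoelectric point
is found by bisection on [0, 14] to 10⁻⁴ pH units. The default pKa
scale is the EMBOSS set, with the Sillero scale selectable — pI values
are pKa-scale dependent at the ±0.3 level, which is why the package
treats absolute pI values as indicative rather than as fitted
quantities. Windowed pI profiles (default 28-residue windows every 7
residues) keep only complete windows, reported by 1-based inclusive
start position, so all windows are comparable. Average masses use the
IUPAC average residue-mass table plus one water (18.015 Da);
monoisotopic masses and post-translational modifications are out of
scope. The 230-nm extinction convenience is the flat 900 AU/residue
rule used for Trp-free coiled-coil fragments.

## Synthetic data

The generators (`tetrafit.simulate`) are pure functions of parameters
and seed. Defaults mirror typical acquisition conditions: a 3-mm
column sampled at 6.85–7.15 cm every 0.001 cm; three to four rotor
speeds in the 10–40 krpm range; additive homoscedastic Gaussian
absorbance noise of 0.005 AU (instrument-level noise at moderate OD);
melts on a 0–80 °C grid at 1 °C pitch with van't Hoff two-state
fractions (ΔH order 50 kcal/mol for a small coiled coil) and linear
baselines; CD spectra as linear helix/coil mixtures in which the helix
basis has the canonical 208/222-nm double minimum with its 222-nm depth
pinned exactly to the theoretical fully helical value, and the coil
basis is a documented fixture shape (small positive shoulder near
218 nm, ≈0 at 222 nm, strong negative band below 200 nm) — not a claim
about real coil spectra.

What the generators do **not** emulate: heteroscedastic or correlated
optical noise, meniscus artifacts, detector saturation (simulated
profiles can exceed the linear range of a real absorbance detector near
the cell base), baseline drift, slow equilibration, and aggregation.
Closed-loop tests (simulate → analyze → recover the generating
parameters) therefore demonstrate the correctness and calibration of
the estimators under the stated statistical model, not robustness to
every instrument pathology.

## Validation strategy and problem sizes

The suite validates each reduction against independent oracles:
term-by-term hand sums for charge, fine-grid zero crossings for pI,
Biopython's molecular weights for masses, closed-form log-linearity for
single-species profiles, and generator-known truths for all fits.
Headline checks: noiseless single-species fits recover mass to 10⁻⁶
relative; at 1% noise, within ±5% (the instrumental error level);
monomer–dimer fits on four-speed data at 40 nM truth return K_d well
inside a factor of two; 2:2 fits at 10⁻¹² M² truth recover the decade;
profiles are minimized at the best fit and monotone away from it on
noiseless data; melt T_m is recovered within ±1 °C. Standard problem
sizes — 301-point radial grids, 3–4 speeds, 25-point profiles, 20
replicate recovery runs — keep any single fit well under a second, so
the whole suite runs in seconds on one core.

## Known limitations

Unweighted least squares assumes uniform absorbance noise; strongly
sloped profiles at high OD violate this in real data. The Δχ² = 4
profile threshold is a convention, not a calibrated coverage statement
(coverage depends on the noise model and parameter non-linearity).
Apparent-mass summaries of associating systems are loading- and
speed-dependent diagnostics, not physical masses. The 2:2 scheme fixes
stoichiometry; competing models (e.g. 2:1, indefinite oligomers) must
be compared by the user via their fit statistics.
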