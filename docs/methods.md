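# Methods

`pindyn` implements the quantitative pipeline used to characterize dynamic
allostery in an isolated peptidyl-prolyl isomerase (PPIase) domain: backbone
¹⁵N relaxation analysis by reduced spectral density mapping, cis–trans
isomerization kinetics from exchange spectroscopy (EXSY), amide H/D
exchange, CD thermal melts, and low-affinity ITC. Every analysis stage is
paired with a synthetic-data generator that produces its inputs from known
ground truth, so each fitter carries parameter-recovery tests rather than
relying on deposited experimental tables.

## Reduced spectral density mapping

Backbone amide ¹⁵N relaxation at a single field is modelled by the standard
dipolar + CSA expressions with a two-timescale spectral density

J(ω) = (2/5)[S₀·τc/(1+ω²τc²) + (1−S₀)·τl/(1+ω²τl²)],   1/τl = 1/τc + 1/τe,

where τc is the overall rotational correlation time, S₀ the square order
parameter and τe the internal correlation time. The 2/5 normalization is
carried inside J, so the rigid zero-frequency value is J(0) = (2/5)τc and
conversely τc = 2.5·J(0); all J outputs are quoted in ns/rad.

The mapping from (R1, R2, hNOE) to (Jeff(0), J(ωN), J(ωh)) uses the
high-frequency approximation that lumps J(ωH−ωN), J(ωH) and J(ωH+ωN) into
one effective density at ωh = 0.87·ωH:

- σ = R1·(hNOE−1)·γN/γH (cross-relaxation rate),
- J(ωh) = 4σ/(5d²),
- J(ωN) = (R1 − (7d²/4)·J(ωh)) / (3d²/4 + c²),
- Jeff(0) = (R2 − (d²/8)(3J(ωN)+13J(ωh)) − (c²/2)J(ωN)) / (d²/2 + 2c²/3),

with d the N–H dipolar constant and c² = (Δσ·ωN)²/3. Against the exact
forward model the mapping recovers J(0) to ~0.02% for rigid residues at
τc ≈ 10 ns; the test tolerance of 5% covers the approximation over
τc ∈ [5, 15] ns. Defaults r(N–H) = 1.02 Å and Δσ = −172 ppm follow the
conventions of mainstream relaxation software and are configurable;
gyromagnetic ratios are CODATA values, giving ωN/2π = 71.01 MHz at the
700.33 MHz study field.

τc estimation is a single pass: the mean and *population* standard
deviation of J(0) over all observed residues define a ±0.5σ band; residues
inside the band are re-averaged once and τc = 2.5 × the re-averaged J(0),
with the error 2.5 × its standard error. µs–ms exchange is detected as
ΔJ(0) = J(0) − (2/5)τc, flagged when J(0) exceeds the all-residue mean by
0.5σ. Using the rigid (2/5)τc baseline underestimates ΔJ(0) by
(1−S₀)(1−τl/τc) ≤ 1−S₀, hence ≤ 10% for S₀ ≥ 0.9; the test suite verifies
this bound over an S₀–τe grid.

The companion claim that residues with hNOE > 0.80 must have S₀ > 0.9 is
τe-dependent: the hNOE loses sensitivity to internal motion as τe → 0 (at
τe = 40 ps the S₀ at which hNOE crosses 0.80 is 0.88; at 55 ps it reaches
0.90). The property is therefore tested as a scan over τe ∈ [55, 100] ps,
the regime where the hNOE genuinely resolves internal motion at this field;
for faster internal motion the hNOE threshold does not constrain S₀ and no
such inference should be drawn.

Two-protein comparisons (mutant − wild-type) difference J(ωN), J(ωh) and
hNOE per shared residue, combine errors in quadrature, and flag residues
whose difference both exceeds its combined error and opposes the sign of
the cohort median — the signature of a residue moving against the
systematic trend set by the τc difference.

## EXSY kinetics

Two-site cis↔trans exchange with rates k_CT (cis→trans) and k_TC
(trans→cis) gives, for magnetization starting on the trans diagonal, the
cross/diagonal ratio

ratio(t) = k_TC·(1 − e^(−k_EX·t)) / (k_CT + k_TC·e^(−k_EX·t)),
k_EX = k_CT + k_TC,

which is zero at t = 0, monotone increasing, and asymptotes to the
equilibrium population ratio k_TC/k_CT. Equal auto-relaxation in the two
states cancels exactly in the ratio; the package carries a first-principles
matrix-exponential propagator (including per-state auto-relaxation) as an
independent oracle, and the closed form agrees with it to better than
1e-10 across the mixing-time range. The fit is a global unweighted least
squares of one (k_CT, k_TC) pair across all reporter signals at the
14-point mixing schedule (2–400 ms, with 50 ms and 100 ms duplicated).
Uncertainties are Monte-Carlo: the noise σ is pooled from duplicated
mixing-time points as |a−b|/√2 (falling back to the residual RMS with a
logged warning when no duplicates exist), synthetic data sets are drawn
around the best-fit curve and refit (500 draws by default).

The generator adds Gaussian noise of the stated fraction of the *diagonal*
intensity to both peaks before forming the ratio. At the study's asymptote
(~0.08–0.13) a 2% diagonal noise is a substantial relative error, so
single-realization fits scatter by ~10–15% in k_CT while the 50-seed median
recovers the truth to a few percent — the recovery tests and the
reproduction script therefore report medians over 50 seeds.

## H/D exchange

Peak intensities are taken as the mean over the 3×3 neighbourhood of the
peak center (nine-point averaging). Each residue's series is fitted with a
two-parameter exponential I₀·e^(−kt) without baseline offset (amides
exchange fully on this time scale; an offset variant is deliberately out of
scope). The default sampling grid is 35 sequential spectra of 35 min each
with the first point 10 min after dissolution. A residue whose first
intensity is already within 3× the (user-supplied) noise floor exchanged
within the dead time and is reported `too_fast`; non-convergent fits are
`not_observed`. Rates are reported in h⁻¹.

The mutant − wild-type comparison gates each Δrate on its combined error —
root-sum-square by default, plain sum behind a flag. This is a one-σ gate:
by construction ~32% of truly unchanged residues pass it by chance, which
the false-positive-control test verifies; the gate is a display filter, not
a significance test.

## CD melts

The generator produces a two-state van't Hoff sigmoid between a folded and
an unfolded θ222 baseline (flat baselines by default; the van't Hoff
enthalpy, 300 kJ/mol by default, sets the transition width of ~13 °C on
the 20–80 °C grid). Analysis normalizes the observed curve to percent loss
of helical content, 100·(θ−θ_min)/(θ_max−θ_min), and fits the two-state
sigmoid *renormalized over the observed range* — the model undergoes the
same min/max scaling as the data. This removes the baseline-truncation bias
that a plain sigmoid fit suffers when the midpoint sits near a grid edge
(~0.04 °C at Tm = 62 °C) and makes unbracketed transitions detectable: a
fitted midpoint outside the data range raises an error. A model-free
50%-crossing estimator is kept as a cross-check and agrees with the fit
within 0.2 °C on clean data.

## ITC

The single-site forward model uses the exact quadratic bound-ligand
solution on cell concentrations that account for displacement dilution:
each injection dilutes everything in the constant-volume cell by
(1 − dV/V₀) and the heat of injection i is
ΔH·V₀·(XB_i − XB_{i−1}·(1 − dV_i/V₀)), normalized per mole of injectant
when written to file (µcal). The study geometry — 1.5 µL injections of
10 mM peptide into 200 µL of 0.2 mM protein — puts the Wiseman parameter at
c = n·[cell]/K_D ≈ 0.11 for K_D ≈ 1.8 mM, a featureless near-linear
isotherm in which K_D and ΔH remain identifiable but n does not. The fit
therefore fixes n = 1, fits (ln K_D, ΔH) by least squares, derives ΔS from
ΔG = RT·ln K_D = ΔH − TΔS (cell temperature defaulting to 298.15 K), and
then *recalculates* n by refitting it alone with ΔH and K_D held fixed —
on self-consistent data this returns 1.000, confirming the fixed-n
assumption. A fitted c-value below 0.01 (configurable) raises an
identifiability error, and Monte-Carlo tests verify that the K_D scatter
grows as c decreases.

## Imidazole ¹⁵N lineshape

The slow/fast hydrogen-exchange diagnostic is modelled as a two-site
Bloch–McConnell absorption lineshape: sites at ±Δν/2 with populations
(p_A, p_B), site-to-site rates p_B·k_ex and p_A·k_ex (detailed balance),
and an exchange-free FWHM linewidth. The classifier counts interior local
maxima: two maxima → doublet (slow exchange, strong hydrogen bond), one →
singlet at the population-weighted mean (fast exchange). For equal
populations the doublet coalesces at a total rate k_ex ≈ √2·π·Δν
(site-departure rate π·Δν/√2), which the scan test locates within 1%.

## Synthetic-data defaults and scope

Generator defaults are the study conditions: 700.33 MHz field, τc ≈ 9–10 ns
with S₀ > 0.9 for ordered residues, exchange rates of order k_CT ≈ 40–50
and k_TC ≈ 4–7 s⁻¹ on the 14-point mixing schedule, melts with midpoints
near 49–56 °C on a 20–80 °C grid, and the low-c ITC geometry above. Noise
defaults (2% relaxation and EXSY, 1% H/D, 0.5% of transition amplitude for
CD, 0.5% of the first-injection heat for ITC) are chosen to match the
magnitude of typical reported uncertainties for these experiments; the
source study does not state its noise levels. Times are seconds internally;
H/D rates are reported per hour and J values in ns/rad for figure-friendly
scales.

The generators emulate per-observable Gaussian noise on idealized forward
models. They do not emulate peak overlap, baseline drift, spectrometer
raw-data artefacts, anisotropic diffusion, >2-site exchange or heats of
dilution — so passing recovery tests demonstrates correctness of the
estimators under the stated models, not robustness to every pathology of
real data.

Problem sizes used by the test suite and the reproduction script (100
residues × 25 seeds for τc recovery, 50 seeds for EXSY recovery, 100 seeds
for melt scatter, 250 residues for the H/D false-positive control) are
chosen so the statistical assertions are stable at their stated tolerances
while the whole suite runs in seconds.

## Known limitations

- The reduced mapping inherits the 0.87·ωH high-frequency approximation;
  J(ωh) is accurate only to within that approximation (~2% at this field).
- The ±0.5σ selection is a single pass by design; iterating it would bias
  τc low when many residues carry exchange.
- The EXSY fit assumes equal auto-relaxation between cis and trans; the
  generator can violate this to study the resulting bias, but the fitter
  does not model it.
- Tm and K_D errors are asymptotic fit-covariance or Monte-Carlo estimates;
  no bootstrap over residues/injections is provided.
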