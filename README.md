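# pindyn

Analysis pipeline for protein "dynamic allostery" studies of the kind used
to compare a wild-type peptidyl-prolyl isomerase (PPIase) domain with a
point mutant: backbone ¹⁵N spin-relaxation analysis by reduced spectral
density mapping, cis–trans isomerization kinetics from 2-D exchange
spectroscopy (EXSY), amide H/D exchange rates, CD thermal melts, and
low-affinity single-site ITC. Every stage is paired with a synthetic-data
generator that produces its inputs from known ground truth, so the whole
pipeline is testable by parameter recovery without deposited experimental
tables.

Who it is for: NMR/biophysics practitioners who have per-residue
R1/R2/hNOE tables, EXSY buildup ratios, H/D intensity series, melt curves
or ITC heats, and want the corresponding fitted parameters with honest
uncertainties — plus simulation tools to design such experiments.

## The models at the core

- **Reduced spectral density mapping.** (R1, R2, hNOE) at one field map to
  Jeff(0), J(ωN), J(0.87·ωH) through the standard dipolar+CSA linear
  combinations, with J(ω) = (2/5)[S₀τc/(1+ω²τc²) + (1−S₀)τl/(1+ω²τl²)].
  The overall correlation time comes from τc = 2.5·⟨J(0)⟩ after a single
  ±0.5σ selection pass over all observed J(0); residues with
  J(0) > mean + 0.5σ are flagged as µs–ms exchange-broadened, with excess
  ΔJ(0) = J(0) − (2/5)τc. Residues dominated by overall tumbling fall on
  the locus J(ωN) = J(0)/(1 + 6.25·(ωN·J(0))²).
- **EXSY kinetics.** ratio(t) = k_TC(1−e^(−k_EX t))/(k_CT + k_TC e^(−k_EX t)),
  k_EX = k_CT + k_TC, fitted globally across reporter signals; Monte-Carlo
  errors with the noise σ pooled from duplicated mixing times. A
  matrix-exponential two-site propagator serves as the independent oracle.
- **H/D exchange.** I(t) = I₀e^(−kt) per residue; mutant−wild-type Δrates
  gated on their combined (root-sum-square) error.
- **CD melts.** Loss of helical content 100·(θ−θ_min)/(θ_max−θ_min), with
  the melting midpoint from a two-state van't Hoff sigmoid fit.
- **ITC.** Exact single-site quadratic binding with displacement dilution;
  in the low Wiseman-c regime (c = n[cell]/K_D ≈ 0.1) the stoichiometry is
  fixed to n = 1, and afterwards recalculated with ΔH, ΔS held fixed as a
  self-consistency check.

See `docs/methods.md` for assumptions, defaults, numerical choices and
limitations.

## Worked example

Simulate a 100-residue rigid protein tumbling at τc = 9.8 ns with 2%
measurement noise at a 700.33 MHz spectrometer, then run the mapping:

```sh
$ pindyn simulate --kind relax --out wt_relax.tsv --seed 11 --noise 0.02
$ pindyn jmap --in wt_relax.tsv --mc 100 --seed 1
{
  "tau_c_ns": 9.790533233780106,
  "tau_c_err_ns": 0.01013397768542532,
  "reaveraged_J0_ns_per_rad": 3.916213293512042,
  "n_selected": 36
}
```

The re-averaged J(0) of 3.92 ns/rad converts to τc = 9.79 ns, recovering
the 9.8 ns ground truth within 0.1%; 36 of 100 residues fall inside the
±0.5σ band (for a purely rigid protein with Gaussian noise ~38% is the
expected fraction; real proteins with exchange-broadened outliers keep a
larger share because σ is inflated).

EXSY, from generation to the global three-signal fit:

```sh
$ pindyn simulate --kind exsy --out exsy.tsv --seed 5
$ pindyn exsy --in exsy.tsv --mc 200 --seed 7
{
  "k_CT_per_s": 54.56798661446611,
  "k_CT_err": 10.619823297486773,
  "k_TC_per_s": 6.905778009788799,
  "k_TC_err": 1.1823486057385537,
  "k_EX_per_s": 61.473764624254905,
  "k_EX_err": 10.685438460603043
}
```

The truth behind this data set is k_CT = 51.6 s⁻¹, k_TC = 6.6 s⁻¹; at 2%
diagonal noise a single realization carries the ~20% k_CT uncertainty the
Monte-Carlo error honestly reports (the buildup asymptote k_TC/k_CT ≈ 0.13
is small compared to the noise).

Other stages work the same way (`pindyn melt`, `pindyn itc`,
`pindyn hdx`, `pindyn compare`), and `pindyn run-study --config study.yaml`
chains everything into a single wild-type-vs-mutant JSON report.

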