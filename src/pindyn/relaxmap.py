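"""Reduced spectral density mapping of backbone ¹⁵N relaxation.

Converts per-residue (R1, R2, hNOE) measured at a single field into the
spectral densities Jeff(0), J(ωN) and J(0.87·ωH), estimates the overall
rotational correlation time τc from the residues whose J(0) falls within
±0.5σ of the protein-wide mean, flags µs-ms conformational exchange via the
excess J(0) − Jcalc(0), and builds per-residue difference profiles between
two proteins (mutant − wild-type).

Conventions
-----------
J values carry the 2/5 normalization of the Lipari-Szabo spectral density,
so the rigid zero-frequency limit is J(0) = (2/5)·τc and, conversely,
τc = 2.5·J(0).  Outputs quote J in ns/rad.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .context import SpectrometerContext

__all__ = [
    "ResidueRelaxationRecord",
    "SpectralDensityTriple",
    "TauCEstimate",
    "ExchangeExcess",
    "reduced_spectral_densities",
    "map_table",
    "theoretical_JwN",
    "estimate_tau_c",
    "exchange_excess",
    "hnoe_from_pair",
    "compare_proteins",
]


@dataclass(frozen=True)
class ResidueRelaxationRecord:
    """One residue's relaxation observables with their quoted errors."""

    residue_id: int
    R1: float
    R1_err: float
    R2: float
    R2_err: float
    hNOE: float
    hNOE_err: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.R1) and np.isfinite(self.R2)
                and np.isfinite(self.hNOE)):
            raise ValueError("relaxation observables must be finite")
        if self.R1 <= 0 or self.R2 <= 0:
            raise ValueError("R1 and R2 must be positive")
        if min(self.R1_err, self.R2_err, self.hNOE_err) < 0:
            raise ValueError("errors must be non-negative")
        if self.hNOE > 1.05:
            warnings.warn(
                f"residue {self.residue_id}: hNOE {self.hNOE:.3f} exceeds the "
                "physical steady-state limit for backbone 15N", stacklevel=2)


@dataclass(frozen=True)
class SpectralDensityTriple:
    """Jeff(0), J(ωN), J(0.87ωH) for one residue, in ns/rad."""

    residue_id: int
    J0: float
    J0_err: float
    JwN: float
    JwN_err: float
    Jwh: float
    Jwh_err: float

    def __post_init__(self) -> None:
        if not (self.J0 >= self.JwN >= self.Jwh):
            warnings.warn(
                f"residue {self.residue_id}: spectral densities are not "
                "ordered J0 >= J(wN) >= J(wh); noisy or exchange-broadened "
                "data can produce this", stacklevel=2)


def _map_point(r1: float, r2: float, hnoe: float,
               ctx: SpectrometerContext) -> tuple[float, float, float]:
    """Reduced mapping of one (R1, R2, hNOE) point to (J0, JwN, Jwh) in s/rad.

    Uses the high-frequency approximation that lumps J(ωH−ωN), J(ωH) and
    J(ωH+ωN) into a single density at 0.87·ωH:

        σ      = R1·(hNOE − 1)·γN/γH
        J(ωh)  = 4σ / (5d²)
        J(ωN)  = (R1 − 7·(d²/4)·J(ωh)) / (3d²/4 + c²)
        Jeff(0)= (R2 − (d²/8)(3J(ωN)+13J(ωh)) − (c²/2)J(ωN)) / (d²/2 + 2c²/3)
    """
    d2 = ctx.dipolar_constant**2
    c2 = ctx.csa_constant
    sigma = r1 * (hnoe - 1.0) / ctx.gamma_ratio_HN
    j_wh = 4.0 * sigma / (5.0 * d2)
    j_wn = (r1 - 7.0 * (d2 / 4.0) * j_wh) / (3.0 * d2 / 4.0 + c2)
    j_0 = ((r2 - (d2 / 8.0) * (3.0 * j_wn + 13.0 * j_wh)
            - (c2 / 2.0) * j_wn)
           / (d2 / 2.0 + 2.0 * c2 / 3.0))
    return j_0, j_wn, j_wh


def reduced_spectral_densities(record: ResidueRelaxationRecord,
                               ctx: SpectrometerContext | None = None,
                               mc_draws: int = 500,
                               seed: int = 0) -> SpectralDensityTriple:
    """Map one residue's relaxation record to its spectral density triple.

    Errors are estimated by Monte-Carlo resampling of (R1, R2, hNOE) within
    their quoted Gaussian errors; ``mc_draws = 0`` reports zero errors and
    leaves the point values untouched.
    """
    ctx = ctx or SpectrometerContext()
    j0, jwn, jwh = _map_point(record.R1, record.R2, record.hNOE, ctx)
    errs = (0.0, 0.0, 0.0)
    if mc_draws > 0:
        rng = np.random.default_rng(seed)
        r1 = record.R1 + rng.normal(0.0, record.R1_err, mc_draws)
        r2 = record.R2 + rng.normal(0.0, record.R2_err, mc_draws)
        noe = record.hNOE + rng.normal(0.0, record.hNOE_err, mc_draws)
        draws = np.array([_map_point(a, b, c, ctx)
                          for a, b, c in zip(r1, r2, noe)])
        errs = tuple(np.std(draws, axis=0) * 1e9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ordering warned about downstream
        return SpectralDensityTriple(
            record.residue_id,
            j0 * 1e9, errs[0], jwn * 1e9, errs[1], jwh * 1e9, errs[2])


def map_table(records: list[ResidueRelaxationRecord],
              ctx: SpectrometerContext | None = None,
              mc_draws: int = 500,
              seed: int = 0) -> list[SpectralDensityTriple]:
    """Map a whole relaxation table; one deterministic sub-seed per residue."""
    seeds = np.random.SeedSequence(seed).generate_state(len(records))
    return [reduced_spectral_densities(r, ctx, mc_draws, int(s) % 2**31)
            for r, s in zip(records, seeds)]


def theoretical_JwN(J0, ctx: SpectrometerContext | None = None):
    """Single-correlation-time locus J(ωN) = J(0)/(1 + 6.25·(ωN·J(0))²).

    J0 in ns/rad; result in ns/rad.  Residues whose N-H motion is dominated
    by overall tumbling fall on this curve; fast internal motion pulls
    points below it and µs-ms exchange pushes J(0) beyond it.
    """
    ctx = ctx or SpectrometerContext()
    j0_s = np.asarray(J0, dtype=float) * 1e-9
    out = j0_s / (1.0 + 6.25 * (ctx.omega_N * j0_s) ** 2) * 1e9
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TauCEstimate:
    """Overall correlation time from the ±0.5σ-selected J(0) average."""

    mean_J0_all: float
    sigma_J0: float
    selected_residues: tuple[int, ...]
    reaveraged_J0: float
    reaveraged_J0_err: float
    tau_c: float          # ns
    tau_c_err: float      # ns


def estimate_tau_c(triples: list[SpectralDensityTriple]) -> TauCEstimate:
    """Estimate τc from the residues within mean(J0) ± 0.5σ.

    Single pass: the mean and the population standard deviation are taken
    over all observed J(0); residues within half a standard deviation of
    the mean are re-averaged once, and τc = 2.5 × the re-averaged J(0)
    (rigid zero-frequency conversion).  The error is 2.5 × the standard
    error of the re-averaged mean.
    """
    if len(triples) < 3:
        raise ValueError("at least 3 residues are required to estimate tau_c")
    j0 = np.array([t.J0 for t in triples])
    ids = np.array([t.residue_id for t in triples])
    mean_all = float(np.mean(j0))
    sigma = float(np.std(j0))  # population std over all observed J(0)
    # machine-epsilon slack keeps the zero-variance case well defined
    keep = np.abs(j0 - mean_all) <= 0.5 * sigma + 1e-12 * abs(mean_all)
    if np.count_nonzero(keep) < 3:
        raise ValueError("fewer than 3 residues fall within the +-0.5 sigma "
                         "band; tau_c estimate unstable")
    sel = j0[keep]
    re_mean = float(np.mean(sel))
    re_err = float(np.std(sel, ddof=1) / np.sqrt(sel.size)) if sel.size > 1 else 0.0
    return TauCEstimate(
        mean_J0_all=mean_all,
        sigma_J0=sigma,
        selected_residues=tuple(int(i) for i in ids[keep]),
        reaveraged_J0=re_mean,
        reaveraged_J0_err=re_err,
        tau_c=2.5 * re_mean,
        tau_c_err=2.5 * re_err,
    )


@dataclass(frozen=True)
class ExchangeExcess:
    """Excess zero-frequency density attributable to µs-ms exchange."""

    residue_id: int
    J0: float
    J0_err: float
    J0_calc: float
    delta_J0: float
    is_outlier: bool


def exchange_excess(triples: list[SpectralDensityTriple],
                    estimate: TauCEstimate) -> list[ExchangeExcess]:
    """Per-residue J(0) − Jcalc(0) with the upper +0.5σ outlier flag.

    Jcalc(0) = (2/5)·τc is the rigid zero-frequency value implied by the
    protein's τc; a residue is flagged as exchange-broadened when its J(0)
    exceeds the all-residue mean by more than half the all-residue standard
    deviation.  Downstream comparisons conventionally consider only the
    flagged residues.
    """
    j0_calc = 0.4 * estimate.tau_c
    threshold = estimate.mean_J0_all + 0.5 * estimate.sigma_J0
    return [
        ExchangeExcess(
            residue_id=t.residue_id,
            J0=t.J0,
            J0_err=t.J0_err,
            J0_calc=j0_calc,
            delta_J0=t.J0 - j0_calc,
            is_outlier=t.J0 > threshold,
        )
        for t in triples
    ]


def hnoe_from_pair(I_sat: float, I_ref: float,
                   noise_std: float = 0.0) -> tuple[float, float]:
    """Steady-state hNOE = I_sat/I_ref with first-order error propagation.

    ``noise_std`` is the spectral noise standard deviation applying to both
    intensities; the returned error is
    (noise_std/|I_ref|)·sqrt(1 + hNOE²).
    """
    if noise_std < 0:
        raise ValueError("noise_std must be non-negative")
    if abs(I_ref) <= 3.0 * noise_std or I_ref == 0:
        raise ValueError("reference intensity is consistent with zero within "
                         "noise; hNOE undefined")
    hnoe = I_sat / I_ref
    err = noise_std / abs(I_ref) * np.sqrt(1.0 + hnoe**2)
    return hnoe, err


def compare_proteins(triples_mut: list[SpectralDensityTriple],
                     triples_wt: list[SpectralDensityTriple],
                     hnoe_mut: dict[int, tuple[float, float]] | None = None,
                     hnoe_wt: dict[int, tuple[float, float]] | None = None
                     ) -> pd.DataFrame:
    """Per-residue mutant − wild-type differences ΔJ(ωN), ΔJ(ωh), ΔhNOE.

    Only residues present in both tables are compared; Δ errors are the
    root-sum-square of the pair's errors.  A residue is flagged for a
    quantity when |Δ| exceeds its combined error AND the sign of Δ opposes
    the global median Δ — the signature of a residue moving against the
    systematic trend set by the τc difference between the proteins.
    """
    a = {t.residue_id: t for t in triples_mut}
    b = {t.residue_id: t for t in triples_wt}
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("no shared residues between the two tables")

    rows = []
    for rid in shared:
        ta, tb = a[rid], b[rid]
        row = {
            "residue": rid,
            "dJwN": ta.JwN - tb.JwN,
            "dJwN_err": float(np.hypot(ta.JwN_err, tb.JwN_err)),
            "dJwh": ta.Jwh - tb.Jwh,
            "dJwh_err": float(np.hypot(ta.Jwh_err, tb.Jwh_err)),
        }
        if hnoe_mut and hnoe_wt and rid in hnoe_mut and rid in hnoe_wt:
            (na, ea), (nb, eb) = hnoe_mut[rid], hnoe_wt[rid]
            row["dNOE"] = na - nb
            row["dNOE_err"] = float(np.hypot(ea, eb))
        else:
            row["dNOE"] = np.nan
            row["dNOE_err"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)

    for quantity in ("dJwN", "dJwh", "dNOE"):
        vals = df[quantity]
        errs = df[f"{quantity}_err"]
        med = np.nanmedian(vals) if vals.notna().any() else np.nan
        significant = vals.abs() > errs
        opposes = np.sign(vals) * np.sign(med) < 0
        df[f"{quantity}_flag"] = (significant & opposes).fillna(False)
    return df
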