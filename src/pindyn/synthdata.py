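"""Synthetic-data generators for every stage of the pipeline.

Each generator draws from a known ground truth with controllable Gaussian
noise and a mandatory seed, so that every downstream fitter has
parameter-recovery tests against the truth that produced its input.

Forward models
--------------
* ¹⁵N relaxation: the standard single-field dipolar + CSA expressions with a
  two-timescale (overall tumbling + fast internal motion) spectral density.
* EXSY: first-order two-site cis↔trans kinetics solved exactly by a matrix
  exponential, including per-state auto-relaxation.
* H/D exchange: single exponential intensity decay.
* CD melt: two-state van't Hoff sigmoid between folded/unfolded baselines.
* ITC: exact single-site quadratic binding with displacement dilution.
* Imidazole ¹⁵N lineshape: two-site Bloch-McConnell absorption spectrum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .context import SpectrometerContext

# gas constant, J mol⁻¹ K⁻¹
R_GAS = 8.31446261815324

__all__ = [
    "MotionModel",
    "ExchangeGroundTruth",
    "MeltGroundTruth",
    "ItcGroundTruth",
    "lorentzian_J",
    "relaxation_rates",
    "simulate_relaxation",
    "simulate_exsy_buildup",
    "simulate_hdx_series",
    "simulate_melt",
    "simulate_itc",
    "simulate_two_site_lineshape",
    "PAPER_MIXING_TIMES",
    "HDX_DEFAULT_TIMES_MIN",
]

#: EXSY mixing times in seconds; 50 ms and 100 ms are acquired in duplicate.
PAPER_MIXING_TIMES: tuple[float, ...] = (
    0.002, 0.005, 0.010, 0.015, 0.025, 0.035,
    0.050, 0.050, 0.075, 0.100, 0.100, 0.200, 0.300, 0.400,
)

#: H/D sampling grid: 35 sequential spectra of 35 min each, first usable
#: point 10 min after dissolution (each stamped at its acquisition start).
HDX_DEFAULT_TIMES_MIN: np.ndarray = 10.0 + 35.0 * np.arange(35)


# ---------------------------------------------------------------------------
# relaxation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionModel:
    """Per-residue motional parameters for the relaxation forward model.

    tau_c is the overall rotational correlation time (s), S0 the square
    order parameter scaling the rigid contribution, tau_e the internal
    correlation time (s) and R_ex an optional µs-ms exchange contribution
    added to R2 (s⁻¹).
    """

    tau_c: float
    S0: float = 1.0
    tau_e: float = 0.0
    R_ex: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if not 0.0 < self.S0 <= 1.0:
            raise ValueError("S0 must lie in (0, 1]")
        if self.tau_e < 0:
            raise ValueError("tau_e must be non-negative")
        if self.R_ex < 0:
            raise ValueError("R_ex must be non-negative")

    @property
    def tau_l(self) -> float:
        """Combined correlation time: 1/tau_l = 1/tau_c + 1/tau_e."""
        if self.tau_e == 0.0:
            return 0.0
        return 1.0 / (1.0 / self.tau_c + 1.0 / self.tau_e)


def lorentzian_J(motion: MotionModel, omega) -> np.ndarray | float:
    """Two-timescale spectral density J(ω) in s/rad.

    J(ω) = (2/5)[S0·τc/(1+ω²τc²) + (1−S0)·τl/(1+ω²τl²)].

    At S0 = 1 this is the rigid Lorentzian (2/5)τc/(1+ω²τc²); at ω = 0 it
    reduces to the zero-frequency two-timescale form used to bound the bias
    of rigid-limit exchange estimates.
    """
    omega = np.asarray(omega, dtype=float)
    tc, tl, s0 = motion.tau_c, motion.tau_l, motion.S0
    j = s0 * tc / (1.0 + (omega * tc) ** 2)
    if s0 < 1.0 and tl > 0.0:
        j = j + (1.0 - s0) * tl / (1.0 + (omega * tl) ** 2)
    out = 0.4 * j
    return float(out) if out.ndim == 0 else out


def relaxation_rates(motion: MotionModel, ctx: SpectrometerContext
                     ) -> tuple[float, float, float]:
    """Noise-free (R1, R2, hNOE) for one residue.

    Standard single-field expressions for an amide ¹⁵N relaxed by the N-H
    dipolar interaction and ¹⁵N CSA; R_ex is added to R2.  The hNOE is the
    steady-state value 1 + (γH/γN)·σ/R1 with σ the cross-relaxation rate.
    """
    wN, wH = ctx.omega_N, ctx.omega_H
    d2 = ctx.dipolar_constant**2
    c2 = ctx.csa_constant
    J = lambda w: lorentzian_J(motion, w)  # noqa: E731

    j_n = J(wN)
    j_hmn = J(wH - wN)
    j_h = J(wH)
    j_hpn = J(wH + wN)
    j_0 = J(0.0)

    r1 = (d2 / 4.0) * (j_hmn + 3.0 * j_n + 6.0 * j_hpn) + c2 * j_n
    r2 = ((d2 / 8.0) * (4.0 * j_0 + j_hmn + 3.0 * j_n + 6.0 * j_h + 6.0 * j_hpn)
          + (c2 / 6.0) * (4.0 * j_0 + 3.0 * j_n)
          + motion.R_ex)
    sigma = (d2 / 4.0) * (6.0 * j_hpn - j_hmn)
    hnoe = 1.0 + ctx.gamma_ratio_HN * sigma / r1
    return r1, r2, hnoe


def simulate_relaxation(per_residue: list[MotionModel],
                        ctx: SpectrometerContext | None = None,
                        noise_fraction: float = 0.02,
                        seed: int = 0,
                        residue_ids: list[int] | None = None) -> pd.DataFrame:
    """Generate a per-residue relaxation table (R1, R2, hNOE with errors).

    Gaussian noise of the given fraction is applied multiplicatively to R1
    and R2 and additively (as a fraction of 1) to the hNOE; the quoted
    errors are the corresponding noise standard deviations, emulating the
    duplicate-based Monte-Carlo error estimates of the acquisition protocol.
    """
    if not per_residue:
        raise ValueError("per_residue must not be empty")
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be non-negative")
    ctx = ctx or SpectrometerContext()
    rng = np.random.default_rng(seed)
    if residue_ids is None:
        residue_ids = list(range(1, len(per_residue) + 1))

    rows = []
    for rid, motion in zip(residue_ids, per_residue):
        r1, r2, hnoe = relaxation_rates(motion, ctx)
        e1 = noise_fraction * r1
        e2 = noise_fraction * r2
        en = noise_fraction
        rows.append({
            "residue": rid,
            "R1": r1 + rng.normal(0.0, e1) if e1 else r1,
            "R1_err": e1,
            "R2": r2 + rng.normal(0.0, e2) if e2 else r2,
            "R2_err": e2,
            "NOE": hnoe + rng.normal(0.0, en) if en else hnoe,
            "NOE_err": en,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EXSY
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExchangeGroundTruth:
    """Two-site cis↔trans exchange truth for EXSY buildup generation."""

    k_CT: float
    k_TC: float
    auto_relax_cis: float = 0.0
    auto_relax_trans: float = 0.0
    mixing_times: tuple[float, ...] = PAPER_MIXING_TIMES

    def __post_init__(self) -> None:
        if self.k_CT < 0 or self.k_TC < 0:
            raise ValueError("exchange rates must be non-negative")
        if self.auto_relax_cis < 0 or self.auto_relax_trans < 0:
            raise ValueError("auto-relaxation rates must be non-negative")
        if len(self.mixing_times) == 0:
            raise ValueError("mixing_times must not be empty")

    @property
    def k_EX(self) -> float:
        return self.k_CT + self.k_TC


def _propagator_matrix(truth: ExchangeGroundTruth, t_mix: float) -> np.ndarray:
    """exp(K t) on the (trans, cis) basis including auto-relaxation."""
    k = np.array([
        [-truth.k_TC - truth.auto_relax_trans, truth.k_CT],
        [truth.k_TC, -truth.k_CT - truth.auto_relax_cis],
    ])
    return expm(k * t_mix)


def simulate_exsy_buildup(truth: ExchangeGroundTruth,
                          signals: int | list[str] = 3,
                          noise_fraction: float = 0.02,
                          seed: int = 0) -> pd.DataFrame:
    """Generate EXSY cross/diagonal buildup ratios for several signals.

    Magnetization starts on the trans diagonal; the reported ratio is the
    trans→cis cross peak over the trans diagonal peak, both from the exact
    two-site propagator.  Noise of ``noise_fraction`` times the diagonal
    intensity is added independently to the cross and the diagonal peak
    before forming the ratio, and duplicated mixing times in the schedule
    yield independent replicates for Monte-Carlo error estimation.
    """
    if isinstance(signals, int):
        if signals < 1:
            raise ValueError("signals must be >= 1")
        labels = [f"signal{i + 1}" for i in range(signals)]
    else:
        labels = list(signals)
        if not labels:
            raise ValueError("signals must be >= 1")
    rng = np.random.default_rng(seed)

    rows = []
    for label in labels:
        replicate_count: dict[float, int] = {}
        for t in truth.mixing_times:
            m = _propagator_matrix(truth, t)
            diag, cross = m[0, 0], m[1, 0]
            sigma = noise_fraction * diag
            if sigma:
                cross = cross + rng.normal(0.0, sigma)
                diag = diag + rng.normal(0.0, sigma)
            rep = replicate_count.get(t, 0)
            replicate_count[t] = rep + 1
            rows.append({
                "signal": label,
                "t_mix_s": t,
                "ratio": cross / diag,
                "ratio_err": noise_fraction,
                "replicate": rep,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# H/D exchange
# ---------------------------------------------------------------------------

def simulate_hdx_series(rate: float,
                        I0: float = 1.0,
                        times: np.ndarray | None = None,
                        noise_fraction: float = 0.01,
                        seed: int = 0) -> pd.DataFrame:
    """Exponential H/D intensity decay I(t) = I0·exp(−rate·t).

    ``rate`` is per minute to match the ``times`` grid (minutes); the
    default grid is 35 spectra of 35 min each starting 10 min after
    dissolution.  Noise is Gaussian with standard deviation
    noise_fraction·I0.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    t = np.asarray(HDX_DEFAULT_TIMES_MIN if times is None else times,
                   dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    intensity = I0 * np.exp(-rate * t)
    if noise_fraction:
        intensity = intensity + rng.normal(0.0, noise_fraction * I0, t.size)
    return pd.DataFrame({"t_min": t, "intensity": intensity})


# ---------------------------------------------------------------------------
# CD melt
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeltGroundTruth:
    """Two-state thermal melt truth.

    T_m in °C, vanthoff_slope the van't Hoff enthalpy in kJ/mol controlling
    transition steepness, and the two θ222 baselines in deg·cm²·dmol⁻¹
    (folded more negative for a helical protein).
    """

    T_m: float = 49.4
    vanthoff_slope: float = 300.0
    theta_folded: float = -12000.0
    theta_unfolded: float = -2000.0
    temperature_grid: np.ndarray = field(
        default_factory=lambda: np.arange(20.0, 80.0 + 1e-9, 0.5))

    def __post_init__(self) -> None:
        if self.theta_folded >= self.theta_unfolded:
            raise ValueError("theta_folded must be below theta_unfolded")
        grid = np.asarray(self.temperature_grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("temperature_grid must be strictly increasing")

    def fraction_unfolded(self, T_celsius) -> np.ndarray:
        """Two-state van't Hoff unfolded fraction at temperature(s) in °C."""
        T = np.asarray(T_celsius, dtype=float) + 273.15
        Tm = self.T_m + 273.15
        dh = self.vanthoff_slope * 1e3
        return 1.0 / (1.0 + np.exp((dh / R_GAS) * (1.0 / T - 1.0 / Tm)))


def simulate_melt(truth: MeltGroundTruth,
                  noise: float = 0.005,
                  seed: int = 0) -> pd.DataFrame:
    """Generate a CD melt curve (T in °C, θ222).

    ``noise`` is the Gaussian standard deviation as a fraction of the
    transition amplitude.  Warns if the midpoint is not bracketed by the
    temperature grid.
    """
    grid = np.asarray(truth.temperature_grid, dtype=float)
    if not grid[0] <= truth.T_m <= grid[-1]:
        warnings.warn("melt midpoint is not bracketed by the temperature "
                      "grid", stacklevel=2)
    amp = truth.theta_unfolded - truth.theta_folded
    theta = truth.theta_folded + amp * truth.fraction_unfolded(grid)
    if noise:
        rng = np.random.default_rng(seed)
        theta = theta + rng.normal(0.0, noise * amp, grid.size)
    return pd.DataFrame({"T_C": grid, "theta222": theta})


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ItcGroundTruth:
    """Single-site ITC truth in the low-affinity (low Wiseman c) regime.

    Defaults follow the titration geometry of the study: 1.5 µL injections
    of 10 mM peptide into a 200 µL cell holding 0.2 mM protein.
    """

    K_D: float = 1.81e-3
    delta_H: float = -10e3
    n_sites: float = 1.0
    cell_volume: float = 200e-6
    cell_conc: float = 0.2e-3
    syringe_conc: float = 10e-3
    injection_volumes: tuple[float, ...] = (1.5e-6,) * 20

    def __post_init__(self) -> None:
        for name in ("K_D", "cell_volume", "cell_conc", "syringe_conc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be positive")

    @property
    def c_value(self) -> float:
        """Wiseman c = n·[cell]/K_D; governs isotherm curvature."""
        return self.n_sites * self.cell_conc / self.K_D


def simulate_itc(truth: ItcGroundTruth,
                 noise: float = 0.005,
                 seed: int = 0) -> pd.DataFrame:
    """Per-injection heats (J) from the exact single-site binding model.

    Noise is Gaussian with a standard deviation of ``noise`` times the
    magnitude of the first noise-free injection heat.
    """
    from .stability import single_site_heats  # fitter-side forward model

    heats = single_site_heats(truth)
    if noise:
        rng = np.random.default_rng(seed)
        scale = noise * abs(heats[0]) if heats[0] != 0 else noise
        heats = heats + rng.normal(0.0, scale, heats.size)
    return pd.DataFrame({
        "injection": np.arange(1, len(truth.injection_volumes) + 1),
        "volume_uL": np.asarray(truth.injection_volumes) * 1e6,
        "heat_ucal": heats / 4.184 * 1e6,
    })


# ---------------------------------------------------------------------------
# two-site lineshape
# ---------------------------------------------------------------------------

def simulate_two_site_lineshape(delta_nu: float,
                                k_ex: float,
                                populations: tuple[float, float] = (0.5, 0.5),
                                linewidth: float = 2.0,
                                grid: np.ndarray | None = None
                                ) -> tuple[np.ndarray, np.ndarray, str]:
    """Two-site Bloch-McConnell absorption lineshape and its classification.

    Sites resonate at ±delta_nu/2 Hz; ``k_ex`` is the total exchange rate
    with site-to-site rates k_ab = pB·k_ex and k_ba = pA·k_ex (detailed
    balance).  ``linewidth`` is the exchange-free FWHM in Hz.  Returns
    (frequency grid in Hz, spectrum, "doublet" or "singlet") where the
    class is decided by counting interior local maxima.
    """
    if delta_nu <= 0:
        raise ValueError("delta_nu must be positive")
    if k_ex < 0:
        raise ValueError("k_ex must be non-negative")
    pa, pb = populations
    if not math.isclose(pa + pb, 1.0, rel_tol=1e-9):
        raise ValueError("populations must sum to 1")
    if grid is None:
        half = 3.0 * delta_nu + 10.0 * linewidth
        grid = np.linspace(-half, half, 4001)
    grid = np.asarray(grid, dtype=float)
    nu_a, nu_b = -delta_nu / 2.0, delta_nu / 2.0
    if grid[0] > nu_a or grid[-1] < nu_b:
        raise ValueError("grid must cover both site frequencies")

    r2 = math.pi * linewidth
    k_ab, k_ba = pb * k_ex, pa * k_ex
    wa, wb = 2.0 * math.pi * nu_a, 2.0 * math.pi * nu_b
    w = 2.0 * math.pi * grid

    # Closed-form inverse of the 2x2 Bloch-McConnell matrix per frequency.
    a11 = 1j * (wa - w) - r2 - k_ab
    a22 = 1j * (wb - w) - r2 - k_ba
    det = a11 * a22 - k_ab * k_ba
    # M⁻¹ · p summed over both observables
    ma = (a22 * pa - k_ba * pb) / det
    mb = (a11 * pb - k_ab * pa) / det
    spectrum = -np.real(ma + mb)

    interior = (spectrum[1:-1] > spectrum[:-2]) & (spectrum[1:-1] >= spectrum[2:])
    n_max = int(np.count_nonzero(interior))
    label = "doublet" if n_max >= 2 else "singlet"
    return grid, spectrum, label
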