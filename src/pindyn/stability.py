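"""Thermal stability (CD melts) and substrate binding (ITC).

CD melts at 222 nm are normalized to a loss-of-helical-content percentage,

    loss(T) = 100·(θ_obs − θ_min)/(θ_max − θ_min),

and the denaturation midpoint Tm comes from a two-state van't Hoff sigmoid
fit of the normalized curve (a model-free 50%-crossing estimator is kept as
a cross-check).

ITC isotherms in the low-affinity regime (Wiseman c ≈ 0.1 here) do not
constrain the stoichiometry, so the single-site model is fitted with n
fixed to 1; the stoichiometry is then *recalculated* by refitting n alone
with ΔH and ΔS held at the fitted values — a consistency check that the
fixed-n assumption was self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthdata import ItcGroundTruth, MeltGroundTruth, R_GAS

__all__ = [
    "MeltCurve",
    "BindingFit",
    "loss_of_helical_content",
    "estimate_Tm",
    "tm_by_crossing",
    "single_site_heats",
    "fit_binding",
]


# ---------------------------------------------------------------------------
# CD melt
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeltCurve:
    """A thermal melt: temperatures (°C) and θ222 (deg·cm²·dmol⁻¹)."""

    temperatures: np.ndarray
    theta222: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        y = np.asarray(self.theta222, dtype=float)
        if t.shape != y.shape:
            raise ValueError("temperatures and theta222 must match in shape")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "theta222", y)

    @property
    def theta_max(self) -> float:
        return float(np.max(self.theta222))

    @property
    def theta_min(self) -> float:
        return float(np.min(self.theta222))

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "MeltCurve":
        return cls(table["T_C"].to_numpy(dtype=float),
                   table["theta222"].to_numpy(dtype=float))


def loss_of_helical_content(curve: MeltCurve) -> np.ndarray:
    """Normalize a melt to percent loss of helical content, range [0, 100]."""
    span = curve.theta_max - curve.theta_min
    if span == 0:
        raise ValueError("flat melt curve: theta_max equals theta_min")
    return 100.0 * (curve.theta222 - curve.theta_min) / span


def _unfolded_fraction(T_celsius, Tm, dh_kJ):
    """Two-state van't Hoff unfolded fraction, midpoint Tm (°C)."""
    T = np.asarray(T_celsius, dtype=float) + 273.15
    tm_K = Tm + 273.15
    return 1.0 / (1.0 + np.exp((dh_kJ * 1e3 / R_GAS)
                               * (1.0 / T - 1.0 / tm_K)))


def estimate_Tm(curve: MeltCurve) -> tuple[float, float]:
    """Denaturation midpoint (°C) and its fit error from a sigmoid fit.

    The normalized loss-of-helical-content curve is fitted with the
    two-state van't Hoff sigmoid *renormalized over the observed range*,
    i.e. the model undergoes the same min/max scaling as the data, so the
    fit is free of the baseline-truncation bias near the grid edges.  The
    transition must be bracketed by the temperature range.
    """
    loss = loss_of_helical_content(curve)
    t = curve.temperatures

    def model(tt, tm, dh):
        f = _unfolded_fraction(tt, tm, dh)
        f0 = _unfolded_fraction(t[0], tm, dh)
        f1 = _unfolded_fraction(t[-1], tm, dh)
        return 100.0 * (f - f0) / (f1 - f0)

    tm0 = t[int(np.argmin(np.abs(loss - 50.0)))]
    popt, pcov = curve_fit(model, t, loss, p0=[tm0, 300.0], maxfev=10000)
    tm, _ = popt
    if not t[0] <= tm <= t[-1]:
        raise ValueError("transition not bracketed by the temperature range")
    tm_err = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else 0.0
    return float(tm), tm_err


def tm_by_crossing(curve: MeltCurve) -> float:
    """Model-free midpoint: where the normalized curve crosses 50%.

    Linear interpolation between the bracketing grid points; cross-check
    for the sigmoid-fit estimator (they agree within ~0.2 °C on clean
    two-state data).
    """
    loss = loss_of_helical_content(curve)
    t = curve.temperatures
    above = loss >= 50.0
    if not above.any() or above.all():
        raise ValueError("transition not bracketed by the temperature range")
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    f = (50.0 - loss[i - 1]) / (loss[i] - loss[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingFit:
    """Single-site ITC fit with the stoichiometry handled two ways.

    K_D and ΔH are fitted with n fixed at 1 (low-affinity convention);
    ΔS follows from ΔG = ΔH − TΔS with ΔG = R·T·ln(K_D).  ``n_recalc`` is
    the stoichiometry refitted alone with ΔH and ΔS (hence K_D) held fixed.
    """

    K_D: float
    K_D_err: float
    delta_H: float
    delta_H_err: float
    delta_S: float
    delta_S_err: float
    n_fixed: float
    n_recalc: float
    n_recalc_err: float
    temperature: float
    c_value: float

    @property
    def delta_G(self) -> float:
        """Binding free energy, J/mol (negative for K_D < 1 M)."""
        return R_GAS * self.temperature * np.log(self.K_D)


def _cell_concentrations(schedule: ItcGroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """Protein and ligand cell concentrations after each injection.

    Each injection of volume dV instantaneously mixes into the constant
    cell volume V0 and displaces an equal volume of mixed solution, so
    every species already in the cell is diluted by (1 − dV/V0) and the
    injectant adds X_syr·dV/V0.
    """
    v0 = schedule.cell_volume
    m = schedule.cell_conc
    x = 0.0
    ms, xs = [], []
    for dv in schedule.injection_volumes:
        dil = 1.0 - dv / v0
        m *= dil
        x = x * dil + schedule.syringe_conc * dv / v0
        ms.append(m)
        xs.append(x)
    return np.array(ms), np.array(xs)


def _bound_ligand(m_tot: np.ndarray, x_tot: np.ndarray,
                  kd: float, n: float) -> np.ndarray:
    """Bound-ligand concentration from the exact single-site quadratic."""
    sites = n * m_tot
    b = sites + x_tot + kd
    return (b - np.sqrt(b * b - 4.0 * sites * x_tot)) / 2.0


def single_site_heats(truth: ItcGroundTruth,
                      kd: float | None = None,
                      delta_h: float | None = None,
                      n: float | None = None) -> np.ndarray:
    """Expected heat (J) evolved by each injection.

    heat_i = ΔH·V0·(XB_i − XB_{i−1}·(1 − dV_i/V0)): the change in bound
    ligand inside the cell, corrected for the bound complex carried out in
    the displaced volume.
    """
    kd = truth.K_D if kd is None else kd
    delta_h = truth.delta_H if delta_h is None else delta_h
    n = truth.n_sites if n is None else n
    m_tot, x_tot = _cell_concentrations(truth)
    bound = _bound_ligand(m_tot, x_tot, kd, n)
    v0 = truth.cell_volume
    heats = np.empty(bound.size)
    prev = 0.0
    for i, dv in enumerate(truth.injection_volumes):
        heats[i] = delta_h * v0 * (bound[i] - prev * (1.0 - dv / v0))
        prev = bound[i]
    return heats


def fit_binding(heats: np.ndarray,
                schedule: ItcGroundTruth,
                temperature: float = 298.15,
                min_c_value: float = 0.01) -> BindingFit:
    """Single-site fit of an ITC isotherm with the stoichiometry fixed to 1.

    ``heats`` are per-injection heats in J on the geometry of ``schedule``
    (whose K_D/ΔH/n fields are ignored).  (K_D, ΔH) are fitted by least
    squares; ΔS follows from ΔG = ΔH − TΔS.  The stoichiometry is then
    recalculated by refitting n alone with ΔH and K_D held at the fitted
    values.  Raises when the heats are all zero or the fitted c-value falls
    below ``min_c_value`` (isotherm featureless: K_D unidentifiable).
    """
    heats = np.asarray(heats, dtype=float)
    if heats.size < 10:
        raise ValueError("at least 10 injections are required")
    if np.all(np.abs(heats) < 1e-30):
        raise ValueError("unidentifiable: all heats are zero")

    scale = np.max(np.abs(heats))

    def model(_x, log_kd, dh):
        return single_site_heats(schedule, kd=np.exp(log_kd), delta_h=dh,
                                 n=1.0) / scale

    idx = np.arange(heats.size)
    # start at c = 1 and the enthalpy implied by total heat over cell protein
    dh0 = heats.sum() / (schedule.cell_conc * schedule.cell_volume)
    popt, pcov = curve_fit(model, idx, heats / scale,
                           p0=[np.log(schedule.cell_conc), float(dh0)],
                           maxfev=20000)
    log_kd, dh = popt
    kd = float(np.exp(log_kd))
    kd_err = kd * float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else 0.0
    dh_err = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else 0.0

    c_value = schedule.cell_conc / kd
    if c_value < min_c_value:
        raise ValueError(
            f"unidentifiable: fitted c-value {c_value:.3g} below "
            f"{min_c_value}; the isotherm is featureless at this affinity")

    dg = R_GAS * temperature * np.log(kd)
    ds = (dh - dg) / temperature
    # first-order propagation; ΔG error from the relative K_D error
    dg_err = R_GAS * temperature * (kd_err / kd) if kd > 0 else 0.0
    ds_err = float(np.hypot(dh_err, dg_err)) / temperature

    def model_n(_x, n):
        return single_site_heats(schedule, kd=kd, delta_h=dh, n=n) / scale

    popt_n, pcov_n = curve_fit(model_n, idx, heats / scale, p0=[1.0],
                               maxfev=20000)
    n_recalc = float(popt_n[0])
    n_err = (float(np.sqrt(pcov_n[0, 0]))
             if np.isfinite(pcov_n[0, 0]) else 0.0)

    return BindingFit(
        K_D=kd, K_D_err=kd_err,
        delta_H=float(dh), delta_H_err=dh_err,
        delta_S=float(ds), delta_S_err=ds_err,
        n_fixed=1.0,
        n_recalc=n_recalc, n_recalc_err=n_err,
        temperature=temperature,
        c_value=float(c_value),
    )
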