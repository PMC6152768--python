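"""Spectrometer context: field-dependent constants for backbone ¹⁵N relaxation.

All frequencies are angular (rad/s).  The amide-specific constants default to
the conventions of mainstream relaxation-analysis software: an effective N-H
bond length of 1.02 Å and a ¹⁵N chemical-shift anisotropy of −172 ppm.  Both
are configurable because published analyses differ in these choices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: ¹H gyromagnetic ratio, rad s⁻¹ T⁻¹ (CODATA).
GAMMA_H = 2.6752218744e8
#: ¹⁵N gyromagnetic ratio, rad s⁻¹ T⁻¹ (negative).
GAMMA_N = -2.71261804e7
#: Reduced Planck constant, J s.
HBAR = 1.054571817e-34
#: mu_0 / 4 pi, T² J⁻¹ m³.
MU0_OVER_4PI = 1e-7


@dataclass(frozen=True)
class SpectrometerContext:
    """Field-dependent constants for a single-field ¹⁵N relaxation analysis.

    Parameters
    ----------
    proton_frequency_hz:
        ¹H Larmor frequency of the spectrometer in Hz (default 700.33 MHz).
    r_NH:
        Effective amide N-H bond length in metres.
    delta_sigma:
        ¹⁵N chemical-shift anisotropy in ppm (dimensionless after the 1e-6).
    """

    proton_frequency_hz: float = 700.33e6
    r_NH: float = 1.02e-10
    delta_sigma: float = -172.0

    def __post_init__(self) -> None:
        if self.proton_frequency_hz <= 0:
            raise ValueError("proton_frequency_hz must be positive")
        if self.r_NH <= 0:
            raise ValueError("r_NH must be positive")

    @property
    def omega_H(self) -> float:
        """¹H angular frequency, rad/s."""
        return 2.0 * math.pi * self.proton_frequency_hz

    @property
    def omega_N(self) -> float:
        """¹⁵N angular frequency magnitude, rad/s (≈ omega_H / 9.87)."""
        return self.omega_H * abs(GAMMA_N / GAMMA_H)

    @property
    def omega_h(self) -> float:
        """Effective high-frequency sampling point 0.87·omega_H, rad/s.

        Reduced spectral density mapping lumps the three ¹H-containing
        frequencies (ωH−ωN, ωH, ωH+ωN) into a single effective density
        evaluated at 0.87·ωH.
        """
        return 0.87 * self.omega_H

    @property
    def gamma_ratio_HN(self) -> float:
        """γH/γN, dimensionless and negative (≈ −9.87)."""
        return GAMMA_H / GAMMA_N

    @property
    def dipolar_constant(self) -> float:
        """N-H dipolar coupling constant d = (μ0/4π)·ħ·γH·γN / r³, rad/s.

        Negative because γN < 0; only d² enters the rate expressions.
        """
        return MU0_OVER_4PI * HBAR * GAMMA_H * GAMMA_N / self.r_NH**3

    @property
    def csa_constant(self) -> float:
        """CSA coupling c² prefactor: c² = (Δσ·ωN)²/3, (rad/s)²."""
        return (self.delta_sigma * 1e-6 * self.omega_N) ** 2 / 3.0
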