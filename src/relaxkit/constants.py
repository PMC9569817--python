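"""Physical constants for amide 15N spin relaxation.

Gyromagnetic ratios are CODATA values; the N-H bond length (1.02 Å) and the
15N chemical-shift anisotropy (-172 ppm) are the values conventionally used
for backbone amides in model-free analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Planck constant over 2*pi [J s]
HBAR = 1.054571817e-34
#: mu_0 / (4*pi) [T^2 m^3 J^-1]
MU0_OVER_4PI = 1.0e-7


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants entering the dipolar/CSA relaxation expressions.

    Attributes
    ----------
    gamma_H, gamma_N : float
        Gyromagnetic ratios in rad s^-1 T^-1. gamma_N is negative.
    r_NH : float
        Amide N-H bond length in Angstrom.
    delta_sigma : float
        15N chemical-shift anisotropy in ppm.
    R_gas : float
        Gas constant in kcal mol^-1 K^-1.
    """

    gamma_H: float = 2.6752218744e8
    gamma_N: float = -2.7126180436e7
    r_NH: float = 1.02
    delta_sigma: float = -172.0
    R_gas: float = 1.9872e-3

    def omega_H(self, field_B0: float) -> float:
        """1H Larmor frequency in rad/s (signed) at ``field_B0`` tesla."""
        return self.gamma_H * field_B0

    def omega_N(self, field_B0: float) -> float:
        """15N Larmor frequency in rad/s (signed, negative) at ``field_B0``."""
        return self.gamma_N * field_B0

    def dipolar_d2(self) -> float:
        """Squared dipolar coupling constant d^2 in (rad/s)^2.

        d = (mu0/4pi) * hbar * gamma_H * gamma_N / r_NH^3.
        """
        r = self.r_NH * 1e-10
        d = MU0_OVER_4PI * HBAR * self.gamma_H * self.gamma_N / r**3
        return d * d

    def csa_c2(self, field_B0: float) -> float:
        """Squared CSA coupling constant c^2 = (delta_sigma * omega_N)^2 / 3."""
        c = self.omega_N(field_B0) * self.delta_sigma * 1e-6
        return c * c / 3.0


DEFAULT_CONSTANTS = PhysicalConstants()

#: Static magnetic field of the study conditions [T] (600 MHz 1H).
DEFAULT_FIELD_B0 = 14.1
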