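"""Physical constants and unit helpers.

The beam module works in SI (coulomb, second, centimetre for areal flux);
the chemistry engine works in nanometre / picosecond / electronvolt, the
natural scales of sub-microsecond radiation chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Avogadro constant [1/mol].
AVOGADRO = 6.02214076e23

# Time conversions
NS_PER_MS = 1.0e6
PS_PER_NS = 1.0e3
PS_PER_S = 1.0e12
S_PER_MS = 1.0e-3
S_PER_NS = 1.0e-9

# Length conversions
CM_PER_UM = 1.0e-4
NM_PER_UM = 1.0e3

#: litre in nm^3 (1 dm^3 = (1e8 nm)^3).
NM3_PER_LITRE = 1.0e24


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical constants of the beam arithmetic.

    ``proton_charge`` is the elementary charge in coulomb; the beam
    arithmetic uses 1.6e-19 C.
    """

    proton_charge: float = 1.6e-19

    def __post_init__(self) -> None:
        if self.proton_charge <= 0:
            raise ValueError("proton_charge must be strictly positive")


def rate_constant_nm3_per_ps(k_per_molar_s: float) -> float:
    """Convert a bimolecular rate constant from 1/(M s) to nm^3/ps per pair."""
    return k_per_molar_s * NM3_PER_LITRE / AVOGADRO / PS_PER_S
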