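"""Physical constants and characteristic HL-60 parameters.

All rates are first-order constants in hr^-1 derived from the characteristic
half-lives and doubling time of an exponentially growing HL-60 culture
(mRNA half-life ~2 hr, protein half-life ~10 hr, doubling time 19.5 hr).
"""

import math

AVOGADRO = 6.02214076e23  # 1/mol

#: characteristic mRNA half-life, hr (transcription factors)
MRNA_HALF_LIFE_HR = 2.0
#: characteristic protein half-life, hr
PROTEIN_HALF_LIFE_HR = 10.0
#: HL-60 population doubling time, hr
DOUBLING_TIME_HR = 19.5


def rate_from_half_life(t_half: float) -> float:
    """First-order rate constant (hr^-1) for a process with half-life ``t_half`` hr."""
    if t_half <= 0:
        raise ValueError(f"half-life must be positive, got {t_half}")
    return math.log(2.0) / t_half


def truncate(value: float, decimals: int) -> float:
    """Truncate (round toward zero) to a fixed number of decimal places."""
    factor = 10.0 ** decimals
    return math.trunc(value * factor) / factor


# Characteristic degradation/growth constants as used in the model defaults:
# the conventional two/three-decimal values derived from the half-lives above
# (exact ln(2)/t_half derivations are checked in the test suite).
THETA_M_DEFAULT = 0.34   # hr^-1, mRNA degradation
THETA_P_DEFAULT = 0.07   # hr^-1, protein degradation
MU_DEFAULT = 0.035       # hr^-1, specific growth rate


def cell_volume_liters(diameter_um: float, cytoplasm_fraction: float) -> float:
    """Cytoplasmic volume (L) of a spherical cell of ``diameter_um`` microns."""
    if diameter_um <= 0:
        raise ValueError("cell diameter must be positive")
    if not (0.0 < cytoplasm_fraction <= 1.0):
        raise ValueError("cytoplasm fraction must be in (0, 1]")
    vol_um3 = cytoplasm_fraction * (math.pi / 6.0) * diameter_um ** 3
    return vol_um3 * 1e-15  # 1 um^3 = 1e-15 L
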