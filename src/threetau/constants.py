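"""Physical constants and unit conversions for FFC-NMR relaxometry.

Frequencies are handled in MHz at every public interface; angular
frequencies (rad/s) are internal.  Time constants are seconds internally
and reported in the field's customary units (μs for surface times, ps for
the bulk time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Proton gyromagnetic ratio over 2π, MHz per Tesla.
GAMMA_OVER_2PI = 42.58

#: Electron-to-proton Larmor frequency ratio ωS/ωI (dimensionless).
ELECTRON_PROTON_FREQ_RATIO = 658.21

#: Electronic spin of the Fe3+ / Mn2+ ions assumed responsible for the
#: paramagnetic contribution.
ELECTRON_SPIN = 2.5

#: Thickness of the single adsorbed water layer at a "solid" surface, and
#: equally the distance between oxygen atoms of neighbouring water
#: molecules (metres).
DELTA = 0.27e-9

#: Proton spin density of bulk water, spins/nm³.
N_BULK = 66.6


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the fixed model constants.

    delta is in metres, gamma_over_2pi in MHz/T.
    """

    delta: float = DELTA
    gamma_over_2pi: float = GAMMA_OVER_2PI
    electron_proton_freq_ratio: float = ELECTRON_PROTON_FREQ_RATIO
    electron_spin: float = ELECTRON_SPIN

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.gamma_over_2pi <= 0:
            raise ValueError("delta and gamma_over_2pi must be positive")
        if self.electron_proton_freq_ratio <= 0:
            raise ValueError("electron_proton_freq_ratio must be positive")


CONSTANTS = PhysicalConstants()


def larmor_frequency(field_tesla):
    """Proton Larmor frequency in MHz for a field in Tesla: f = (γ/2π)·B."""
    b = np.asarray(field_tesla, dtype=float)
    if np.any(b < 0):
        raise ValueError("magnetic field must be non-negative")
    out = GAMMA_OVER_2PI * b
    return float(out) if np.isscalar(field_tesla) else out


def field_from_frequency(freq_mhz):
    """Magnetic field in Tesla for a proton Larmor frequency in MHz."""
    f = np.asarray(freq_mhz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = f / GAMMA_OVER_2PI
    return float(out) if np.isscalar(freq_mhz) else out


def omega_rad_per_s(freq_mhz):
    """Angular frequency in rad/s for a frequency in MHz."""
    return 2.0 * np.pi * np.asarray(freq_mhz, dtype=float) * 1e6
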