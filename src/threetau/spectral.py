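"""Spectral densities of the dipolar correlation functions of the 3-Tau model.

Each spin-pair class is assigned a normalised correlation function G(t)
(G(0)=1, non-negative, decaying) and its spectral density

    J(omega) = 2 * Integral_0^inf G(t) cos(omega t) dt     [seconds]

The three families are:

``surface``
    In-layer 2-D diffusive decorrelation with time constant tau_l,
    truncated by desorption to the bulk:  G(t) = exp(-t/tau_d) / (1 + t/tau_l).
    The 1/t long-time tail is the hallmark of two-dimensional diffusion;
    the desorption cutoff keeps J(0) finite (J(0) <= 2 tau_d).

``bulk``
    3-D translational decorrelation with time constant tau_b:
    G(t) = (1 + t/tau_b)^(-3/2).  The t^(-3/2) tail produces the
    characteristic sqrt(omega) departure of J from its zero-frequency
    plateau.  A pure Lorentzian (G = exp(-t/tau_b)) is selectable.

``cross``
    Surface-bulk pair decorrelation.  The relative motion is dominated by
    the faster partner, so the 3-D form is used with the harmonic
    combination 1/tau_c = 1/tau_l + 1/tau_b, truncated by desorption:
    G(t) = exp(-t/tau_d) (1 + t/tau_c)^(-3/2).

The paramagnetic kinds share the proton-motion correlation functions:
``paramagnetic-surface`` aliases ``surface`` and ``paramagnetic-bulk``
aliases ``bulk`` (the ions are fixed in the solid, so the pair motion is
the proton's own).

All correlation functions are completely monotone (mixtures of decaying
exponentials), hence every J is positive and non-increasing in omega.
Both families have closed-form transforms:

    surface:   J = 2 tau_l Re[e^z E1(z)],          z = tau_l (1/tau_d - i omega)
    power-law: J = 4 tau Re[1 - sqrt(pi p tau) erfcx(sqrt(p tau))],
                                                   p = rate_cut - i omega

evaluated with scaled special functions so no regime overflows.
"""

from __future__ import annotations

import numpy as np
from scipy import special

KINDS = ("surface", "bulk", "cross", "paramagnetic-surface", "paramagnetic-bulk")

#: Translational forms available for the bulk/cross families.
BULK_FORMS = ("translational", "lorentzian")

_PSI_ASYMPTOTIC_CUT = 40.0


def _psi(z: np.ndarray) -> np.ndarray:
    """Scaled exponential integral psi(z) = e^z E1(z) for Re z > 0.

    Uses scipy's exp1 for moderate |z| and the asymptotic series
    psi(z) ~ (1/z) sum_k (-1)^k k! / z^k for large |z|, where the direct
    product e^z * E1(z) would overflow.
    """
    z = np.asarray(z, dtype=complex)
    out = np.empty_like(z)
    big = np.abs(z) > _PSI_ASYMPTOTIC_CUT
    small = ~big
    if np.any(small):
        zs = z[small]
        out[small] = np.exp(zs) * special.exp1(zs)
    if np.any(big):
        zb = z[big]
        acc = np.zeros_like(zb)
        term = np.ones_like(zb)
        for k in range(15):
            if k:
                term = term * (-k) / zb
            acc = acc + term
        out[big] = acc / zb
    return out


def _lorentzian_j(omega, tau):
    """J for G(t) = exp(-t/tau): 2 tau / (1 + (omega tau)^2)."""
    omega = np.asarray(omega, dtype=float)
    return 2.0 * tau / (1.0 + (omega * tau) ** 2)


def _surface_j(omega, tau_l, tau_d):
    """Closed-form J for G(t) = exp(-t/tau_d) / (1 + t/tau_l)."""
    omega = np.asarray(omega, dtype=float)
    z = tau_l * (1.0 / tau_d - 1j * omega)
    return 2.0 * tau_l * np.real(_psi(z))


def _powerlaw_j(omega, tau, rate_cut=0.0):
    """J for G(t) = exp(-rate_cut*t) (1 + t/tau)^(-3/2), in closed form.

    With p = rate_cut - i omega (Re p >= 0) the one-sided transform is
    2 tau (1 - sqrt(pi p tau) erfcx(sqrt(p tau))); the scaled erfcx keeps
    every regime finite.  For |p tau| >> 1 the bracket suffers
    cancellation, so the asymptotic expansion in 1/(p tau) is used there.
    """
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    p = rate_cut - 1j * omega
    z2 = p * tau
    out = np.empty(omega.shape, dtype=float)
    big = np.abs(z2) > 1e6
    small = ~big
    if np.any(small):
        z = np.sqrt(z2[small])
        out[small] = 4.0 * tau * np.real(
            1.0 - np.sqrt(np.pi) * z * special.erfcx(z))
    if np.any(big):
        iz2 = 1.0 / z2[big]
        out[big] = 4.0 * tau * np.real(
            0.5 * iz2 - 0.75 * iz2 ** 2 + 1.875 * iz2 ** 3)
    return out


def correlation_function(kind, t, *, tau_l=None, tau_d=None, tau_b=None,
                         bulk_form="translational"):
    """Normalised correlation function G(t) for a spin-pair kind.

    This is the defining object of each spectral density; tests integrate
    it numerically as the independent check on the fused J evaluation.
    """
    t = np.asarray(t, dtype=float)
    kind = _canonical_kind(kind)
    if kind == "surface":
        return np.exp(-t / tau_d) / (1.0 + t / tau_l)
    if kind == "bulk":
        if bulk_form == "lorentzian":
            return np.exp(-t / tau_b)
        return (1.0 + t / tau_b) ** -1.5
    # cross
    tau_c = 1.0 / (1.0 / tau_l + 1.0 / tau_b)
    if bulk_form == "lorentzian":
        return np.exp(-t / tau_d) * np.exp(-t / tau_c)
    return np.exp(-t / tau_d) * (1.0 + t / tau_c) ** -1.5


def _canonical_kind(kind: str) -> str:
    if kind not in KINDS:
        raise ValueError(f"unknown spectral-density kind {kind!r}; expected one of {KINDS}")
    if kind == "paramagnetic-surface":
        return "surface"
    if kind == "paramagnetic-bulk":
        return "bulk"
    return kind


def spectral_density(kind, omega, *, tau_l=None, tau_d=None, tau_b=None,
                     bulk_form="translational"):
    """Spectral density J(omega) in seconds for angular frequency rad/s.

    omega may be a scalar or array; negative omega is a domain error.
    """
    scalar = np.isscalar(omega)
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if np.any(omega < 0):
        raise ValueError("omega must be non-negative")
    if bulk_form not in BULK_FORMS:
        raise ValueError(f"unknown bulk form {bulk_form!r}")
    kind = _canonical_kind(kind)
    if kind == "surface":
        if tau_l is None or tau_d is None:
            raise ValueError("surface kind requires tau_l and tau_d")
        j = _surface_j(omega, tau_l, tau_d)
    elif kind == "bulk":
        if tau_b is None:
            raise ValueError("bulk kind requires tau_b")
        if bulk_form == "lorentzian":
            j = _lorentzian_j(omega, tau_b)
        else:
            j = _powerlaw_j(omega, tau_b)
    else:  # cross
        if tau_l is None or tau_d is None or tau_b is None:
            raise ValueError("cross kind requires tau_l, tau_d and tau_b")
        tau_c = 1.0 / (1.0 / tau_l + 1.0 / tau_b)
        if bulk_form == "lorentzian":
            j = _lorentzian_j(omega, 1.0 / (1.0 / tau_c + 1.0 / tau_d))
        else:
            j = _powerlaw_j(omega, tau_c, rate_cut=1.0 / tau_d)
    j = np.asarray(j, dtype=float)
    return float(j[0]) if scalar else j
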