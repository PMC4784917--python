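"""Debye linear-response closed forms and their frequency limits.

For a weak oscillating field xi(t*) = xi0 cos(2 pi t*) z-hat (xi0 << 1), the
mean magnetization of a relaxing dipole ensemble is the Debye expression

    m_z(t*) = (xi0/3) [cos(2 pi t*) + 2 pi Omega sin(2 pi t*)] / (1 + (2 pi Omega)^2),

the ac-susceptibility result with relaxation time tau_B (Omega = f tau_B).
Its high-frequency limit is A-parameterized, m_z ~ (A/6 pi) sin(2 pi t*),
and its low-frequency expansion carries the in-phase term plus a first
correction proportional to xi0 * Omega — the field-frequency product known
as the slew rate.  These closed forms serve as analytic cross-checks of the
stochastic simulator in the linear regime.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "debye_magnetization",
    "debye_first_harmonic",
    "debye_high_omega",
    "debye_low_omega_expansion",
    "slew_rate",
]

TWO_PI = 2.0 * np.pi


def debye_magnetization(xi0: float, omega: float, t_star) -> np.ndarray | float:
    """Debye magnetization m_z(t*) for a weak drive (valid for xi0 << 1)."""
    if omega <= 0:
        raise ValueError("omega must be positive")
    if xi0 < 0:
        raise ValueError("xi0 must be non-negative")
    w = TWO_PI * omega
    phase = TWO_PI * np.asarray(t_star, dtype=float)
    out = (xi0 / 3.0) * (np.cos(phase) + w * np.sin(phase)) / (1.0 + w**2)
    return float(out) if np.ndim(t_star) == 0 else out


def debye_first_harmonic(xi0: float, omega: float) -> float:
    """First derivative-harmonic a_1 = |F_1| of the Debye magnetization.

    With F_l the window-normalized Fourier coefficient, a sinusoid
    C cos + S sin has |F_1| = sqrt(C^2 + S^2)/2, giving
    a_1 = (xi0/6) / sqrt(1 + (2 pi Omega)^2).
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    w = TWO_PI * omega
    return (xi0 / 6.0) / np.sqrt(1.0 + w**2)


def debye_high_omega(a: float, t_star) -> np.ndarray | float:
    """High-frequency limit m_z ~ (A/6 pi) sin(2 pi t*), valid for Omega > 1.

    The response is out of phase with the drive and depends on the master
    variable alone: the Omega -> infinity asymptote of the full Debye form.
    """
    out = (a / (6.0 * np.pi)) * np.sin(TWO_PI * np.asarray(t_star, dtype=float))
    return float(out) if np.ndim(t_star) == 0 else out


def debye_low_omega_expansion(xi0: float, omega: float, t_star) -> np.ndarray | float:
    """O(Omega) truncation of the Debye form for Omega < 1.

    Binomial expansion of 1/(1 + (2 pi Omega)^2) has no linear term, so to
    first order m_z ~ (xi0/3)[cos(2 pi t*) + 2 pi Omega sin(2 pi t*)]: the
    in-phase response plus a quadrature correction whose amplitude
    (xi0/3) * 2 pi Omega is proportional to the field-frequency product
    (the slew rate).  The remainder relative to the full form is O(Omega^2).
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    w = TWO_PI * omega
    phase = TWO_PI * np.asarray(t_star, dtype=float)
    out = (xi0 / 3.0) * (np.cos(phase) + w * np.sin(phase))
    return float(out) if np.ndim(t_star) == 0 else out


def slew_rate(b0: float, frequency: float) -> float:
    """Field-frequency product B0 * f (T/s up to a factor 2 pi).

    The dimensionless counterpart is xi0 * Omega; either product is
    invariant under the trade-off (B0, f) -> (B0/c, c f).
    """
    if b0 < 0 or frequency < 0:
        raise ValueError("b0 and frequency must be non-negative")
    return b0 * frequency
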