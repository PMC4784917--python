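"""Derivative harmonic spectra of magnetization traces.

MSB instruments detect dm_z/dt inductively, so the working metric is the
*derivative* harmonic: the l-th Fourier coefficient of m_z at integer
multiples of the drive frequency, multiplied by the harmonic number,

    F_l = (1/T_w) * integral over the analysis window of m_z e^{i 2 pi l t*} dt*
    a_l = l * |F_l|

with T_w an integer number of drive periods.  The 1/T_w normalization makes
a_l independent of window length; the complex phase is discarded.  A pure
sinusoid m_z = sin(2 pi t*) has a_1 = 1/2; the saturated square wave
sgn(cos 2 pi t*) has a_l = 2/pi at every odd harmonic.  For a symmetric
drive in steady state the even harmonics vanish (up to Monte-Carlo noise).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MagnetizationTrace

__all__ = ["HarmonicSpectrum", "harmonic_spectrum", "harmonic_ratio", "normalize_curve"]


@dataclass
class HarmonicSpectrum:
    """Harmonic amplitudes a_l = l |F_l| for l = 1 .. l_max.

    ``fourier_abs`` keeps the raw |F_l|; ``amplitude_se`` is a block
    standard error (present when the source trace carried block means).
    """

    l: np.ndarray
    amplitude: np.ndarray
    fourier_abs: np.ndarray
    amplitude_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=int)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.fourier_abs = np.asarray(self.fourier_abs, dtype=float)
        if np.any(self.amplitude < 0):
            raise ValueError("harmonic amplitudes are magnitudes, must be >= 0")

    def __getitem__(self, harmonic: int) -> float:
        idx = np.nonzero(self.l == harmonic)[0]
        if len(idx) == 0:
            raise KeyError(f"harmonic {harmonic} not in spectrum (l_max={self.l.max()})")
        return float(self.amplitude[idx[0]])

    def se(self, harmonic: int) -> float:
        if self.amplitude_se is None:
            raise ValueError("spectrum carries no block standard errors")
        idx = np.nonzero(self.l == harmonic)[0]
        if len(idx) == 0:
            raise KeyError(f"harmonic {harmonic} not in spectrum")
        return float(self.amplitude_se[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "l": self.l,
                "a_l": self.amplitude,
                "a_l_norm": self.amplitude / self.amplitude.max(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _fourier_amplitudes(mz: np.ndarray, n_periods: int, l_max: int) -> np.ndarray:
    """|F_l| for l = 1..l_max via FFT on an integer-period rectangular window."""
    n = len(mz)
    spec = np.fft.rfft(mz) / n
    bins = np.arange(1, l_max + 1) * n_periods
    return np.abs(spec[bins])


def harmonic_spectrum(trace: MagnetizationTrace, l_max: int = 11) -> HarmonicSpectrum:
    """Compute a_l = l |F_l| for l = 1..l_max from a steady-state trace.

    The trace must cover an integer number of drive periods on a uniform
    grid (endpoint excluded), which makes the rectangular-window FFT an
    exact quadrature for the periodic steady state; ``l_max`` must stay
    below the Nyquist limit of the grid.  The ensemble mean is transformed
    (average first, then Fourier); block means, when present, yield a
    jackknife-free block standard error per harmonic.
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    n = len(trace.mz_mean)
    periods = trace.n_periods
    samples_per_period = n / periods
    if abs(samples_per_period - round(samples_per_period)) > 1e-9:
        raise ValueError(
            f"trace length {n} does not cover an integer number of periods ({periods})"
        )
    if l_max * periods >= n // 2:
        raise ValueError(
            f"l_max={l_max} exceeds the Nyquist harmonic of the grid "
            f"({n // (2 * periods)})"
        )
    ls = np.arange(1, l_max + 1)
    f_abs = _fourier_amplitudes(trace.mz_mean, periods, l_max)
    amp = ls * f_abs

    amp_se = None
    if trace.block_mz is not None and trace.block_mz.shape[0] >= 2:
        n_blocks = trace.block_mz.shape[0]
        block_amp = np.empty((n_blocks, l_max))
        for b in range(n_blocks):
            block_amp[b] = ls * _fourier_amplitudes(trace.block_mz[b], periods, l_max)
        amp_se = block_amp.std(axis=0, ddof=1) / np.sqrt(n_blocks)

    return HarmonicSpectrum(l=ls, amplitude=amp, fourier_abs=f_abs, amplitude_se=amp_se)


def harmonic_ratio(spectrum: HarmonicSpectrum, p: int, q: int, atol: float = 1e-12) -> float:
    """Harmonic ratio a_p / a_q, e.g. r_53 = a_5 / a_3.

    Ratios are invariant under any rescaling of the trace, which makes them
    concentration-independent observables.  Raises if a_q is zero to within
    ``atol`` (e.g. a_3 of a pure sinusoid).
    """
    num = spectrum[p]
    den = spectrum[q]
    if den <= atol:
        raise ZeroDivisionError(f"harmonic a_{q} = {den:.3g} is zero; ratio undefined")
    return num / den


def normalize_curve(values: np.ndarray) -> np.ndarray:
    """Divide a harmonic-vs-parameter curve by its maximum (max of output = 1).

    Positive scaling preserves shape and monotonicity; an all-zero (or
    negative) curve has no meaningful normalization and raises.
    """
    values = np.asarray(values, dtype=float)
    m = values.max() if values.size else 0.0
    if not m > 0:
        raise ValueError("cannot normalize a curve with no strictly positive value")
    return values / m
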