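"""Centered Fourier-transform helpers.

The whole package stores both real-space densities and diffraction patterns
with the zero-frequency (DC) sample at the matrix center, index
``(N_p // 2, N_p // 2)``.  The helpers below wrap ``scipy.fft`` so that the
transform of a centered array is again centered, which keeps every mask,
pattern and density on one common grid.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as _sfft


def ft(rho: np.ndarray) -> np.ndarray:
    """Forward 2D Fourier transform, DC-centered in and out.

    Unitary normalization, so the transform preserves the L2 norm
    (``sum |rho|**2 == sum |ft(rho)|**2``).
    """
    return _sfft.fftshift(_sfft.fft2(_sfft.ifftshift(rho), norm="ortho"))


def ift(rho_tilde: np.ndarray) -> np.ndarray:
    """Inverse 2D Fourier transform, DC-centered in and out (unitary)."""
    return _sfft.fftshift(_sfft.ifft2(_sfft.ifftshift(rho_tilde), norm="ortho"))


def point_reflect(a: np.ndarray) -> np.ndarray:
    """Point reflection about the centered origin: a(x) -> a(-x).

    With the origin at index ``N // 2`` the reflected index is ``(-i) mod N``,
    i.e. a flip followed by a one-pixel roll along each axis.
    """
    return np.roll(np.flip(a), (1, 1), axis=(0, 1))


def phase_factor(z: np.ndarray) -> np.ndarray:
    """Unit phasor z/|z|, with the zero-amplitude convention of phase 0."""
    a = np.abs(z)
    out = np.ones_like(z, dtype=complex)
    nz = a > 0
    out[nz] = z[nz] / a[nz]
    return out
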