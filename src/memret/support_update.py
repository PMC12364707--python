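"""Support re-estimation (shrink-wrap) and linear generation schedules.

The support of a reconstruction is re-estimated from the density itself:
the modulus is smoothed with a gaussian kernel of width ``sigma`` and
thresholded at a fraction ``tau`` of its maximum (standard shrink-wrap), or
cut so the support holds exactly a target number of pixels (the
area-targeted variant, which makes error values comparable across a
population).  Smoothing width, threshold and iteration counts are ramped
linearly across generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as _sfft
from scipy.ndimage import fourier_gaussian

__all__ = ["Schedule", "schedule_value", "shrink_wrap", "shrink_wrap_area"]


@dataclass
class Schedule:
    """Linear ramp from ``start`` (generation 1) to ``end`` (generation G)."""

    start: float
    end: float
    G: int

    def __post_init__(self) -> None:
        if self.G <= 1:
            raise ValueError("a schedule needs G > 1 generations")


def schedule_value(s: Schedule, g: int, integer: bool = False) -> float | int:
    """Scheduled value at generation ``g`` (1-based).

    ``start + (end - start) * (g-1)/(G-1)``; iteration counts are rounded
    half-up to an integer.
    """
    if not (1 <= g <= s.G):
        raise ValueError(f"generation {g} outside [1, {s.G}]")
    # endpoints are exact by construction (no rounding drift)
    if g == 1:
        v = float(s.start)
    elif g == s.G:
        v = float(s.end)
    else:
        v = s.start + (s.end - s.start) * (g - 1) / (s.G - 1)
    if integer:
        return int(np.floor(v + 0.5))
    return v


def _smooth_modulus(rho: np.ndarray, sigma_sw: float) -> np.ndarray:
    """Gaussian-smoothed |rho| via Fourier multiplication (periodic wrap)."""
    mod = np.abs(rho)
    if sigma_sw <= 0:
        return mod
    return _sfft.ifft2(fourier_gaussian(_sfft.fft2(mod), sigma_sw)).real


def shrink_wrap(rho: np.ndarray, sigma_sw: float, tau_sw: float) -> np.ndarray:
    """Standard shrink-wrap: threshold the smoothed modulus.

    The new support keeps the pixels where the smoothed modulus is at least
    ``tau_sw`` times its maximum; the argmax always qualifies, so the result
    is never empty.
    """
    if sigma_sw < 0:
        raise ValueError("sigma_sw must be non-negative")
    if not (0 < tau_sw <= 1):
        raise ValueError("tau_sw must satisfy 0 < tau_sw <= 1")
    smoothed = _smooth_modulus(rho, sigma_sw)
    peak = smoothed.max()
    if peak <= 0:
        raise ValueError("degenerate (all-zero) density: support undefined")
    return smoothed >= tau_sw * peak


def shrink_wrap_area(rho: np.ndarray, sigma_sw: float, alpha: int) -> np.ndarray:
    """Area-targeted shrink-wrap: keep exactly ``alpha`` pixels.

    The support is the set of the ``alpha`` largest smoothed-modulus pixels,
    with ties at the cutoff broken deterministically in row-major order (the
    threshold is computed implicitly from the target area).
    """
    if sigma_sw < 0:
        raise ValueError("sigma_sw must be non-negative")
    n_tot = rho.size
    alpha = int(alpha)
    if not (1 <= alpha <= n_tot):
        raise ValueError(f"target area {alpha} outside [1, {n_tot}]")
    smoothed = _smooth_modulus(rho, sigma_sw)
    # stable sort on the negated values: descending by value, row-major ties
    order = np.argsort(-smoothed.ravel(), kind="stable")
    support = np.zeros(n_tot, dtype=bool)
    support[order[:alpha]] = True
    return support.reshape(rho.shape)
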