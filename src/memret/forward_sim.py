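"""Synthetic far-field diffraction: ground-truth densities and patterns.

The forward model of small-angle single-particle CDI is
``I = |FT[rho]|**2`` for a compact complex projected density ``rho``.  This
module builds such densities from projected uniform balls (the same
primitive the reconstruction engine uses to seed its population), simulates
the measured pattern including the detector pathologies of real XFEL data —
a central unmeasured hole, inter-module gap stripes, pixel saturation and
Poisson photon noise — and provides the power normalization that matches a
density's masked Fourier power to the measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._fft import ft
from .data_model import DiffractionData, MPRConfig

__all__ = [
    "SphereSpec",
    "MaskSpec",
    "projected_sphere",
    "random_density",
    "normalize_density",
    "simulate_pattern",
    "two_sphere_density",
]


@dataclass
class SphereSpec:
    """A projected uniform ball: center (row, col), diameter and phase."""

    center: tuple[float, float]
    diameter: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("sphere diameter must be positive")


@dataclass
class MaskSpec:
    """Missing-data pathologies applied to a simulated pattern.

    ``central_shape`` is ``"disk"`` (radius ``central_size`` pixels),
    ``"rectangle"`` (a centered ``central_size x central_size`` square) or
    ``"none"``.  ``gap_stripes`` are ``(orientation, offset, width)`` triples
    with orientation ``"h"`` (rows) or ``"v"`` (columns).  Pixels whose
    intensity exceeds ``saturation_level`` are flagged saturated.
    """

    central_shape: str = "none"
    central_size: float = 0.0
    gap_stripes: Sequence[tuple[str, int, int]] = field(default_factory=list)
    saturation_level: float | None = None

    def __post_init__(self) -> None:
        if self.central_shape not in ("disk", "rectangle", "none"):
            raise ValueError("central_shape must be 'disk', 'rectangle' or 'none'")
        if self.central_size < 0:
            raise ValueError("central_size must be non-negative")
        for orient, _off, width in self.gap_stripes:
            if orient not in ("h", "v"):
                raise ValueError("stripe orientation must be 'h' or 'v'")
            if width < 1:
                raise ValueError("stripe width must be at least one pixel")


def projected_sphere(spec: SphereSpec, n_p: int) -> np.ndarray:
    """Projection of a uniform ball along the beam axis.

    At pixel distance ``r`` from the center the value is
    ``exp(i*phase) * 2*sqrt(R**2 - r**2)`` for ``r <= R = diameter/2`` and 0
    outside — the chord length through a ball, i.e. the optical depth of a
    spherical particle.  Pixels are sampled at their centers.
    """
    rows = np.arange(n_p)[:, None] - spec.center[0]
    cols = np.arange(n_p)[None, :] - spec.center[1]
    r2 = rows**2 + cols**2
    radius = spec.diameter / 2.0
    chord = np.zeros((n_p, n_p))
    inside = r2 <= radius**2
    chord[inside] = 2.0 * np.sqrt(radius**2 - r2[inside])
    return chord * np.exp(1j * spec.phase)


def random_density(cfg: MPRConfig, rng: np.random.Generator) -> np.ndarray:
    """Random starting density: spheres summed inside the initial square.

    ``n_init`` spheres with diameters uniform in ``d_init`` and phases
    uniform in ``phi_init`` are complex-summed; centers are drawn so each
    disk lies fully inside the centered ``sigma_init``-pixel square, keeping
    the guess inside the initial support.  The modulus is then exponentiated
    by ``gamma_init`` (image-processing gamma; <1 flattens the profiles)
    while the phase map is kept.
    """
    if cfg.n_p is None:
        raise ValueError("cfg.n_p must be set before drawing random densities")
    n_p, edge = cfg.n_p, cfg.sigma_init
    if edge > n_p:
        raise ValueError("sigma_init must not exceed the matrix size")
    lo, hi = cfg.d_init  # type: ignore[misc]
    if hi > edge:
        raise ValueError("sphere diameter range exceeds the initial square")
    center = n_p // 2
    half = edge / 2.0
    rho = np.zeros((n_p, n_p), dtype=complex)
    for _ in range(cfg.n_init):
        d = rng.uniform(lo, hi)
        phase = rng.uniform(cfg.phi_init[0], cfg.phi_init[1])
        r = d / 2.0
        # full disk inside the centered square
        cmin, cmax = center - half + r, center + half - r
        cr = rng.uniform(cmin, cmax) if cmax > cmin else 0.5 * (cmin + cmax)
        cc = rng.uniform(cmin, cmax) if cmax > cmin else 0.5 * (cmin + cmax)
        rho += projected_sphere(SphereSpec((cr, cc), d, phase), n_p)
    if cfg.gamma_init != 1.0:
        mod = np.abs(rho)
        ph = np.exp(1j * np.angle(rho))
        rho = np.where(mod > 0, mod**cfg.gamma_init * ph, 0.0)
    return rho


def normalize_density(rho: np.ndarray, data: DiffractionData) -> np.ndarray:
    """Scale ``rho`` so its masked Fourier power matches the measurement.

    The power ratio ``nu = sum(Xi*I) / sum(Xi*|FT[rho]|**2)`` compares the
    partial L2 norms on the known pixels; multiplying the density by
    ``sqrt(nu)`` makes them equal exactly (Parseval fixes the full norm when
    the whole pattern is known).
    """
    xi = data.known_mask
    power = np.sum(np.abs(ft(rho))[xi] ** 2)
    if power <= 0:
        raise ValueError("degenerate density: no Fourier power on known pixels")
    nu = np.sum(data.intensities[xi]) / power
    return np.sqrt(nu) * rho


def simulate_pattern(
    rho_true: np.ndarray,
    masks: MaskSpec | None = None,
    photon_budget: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DiffractionData, np.ndarray]:
    """Simulate the measured pattern of a compact density.

    ``I = |FT[rho_true]|**2`` is rescaled to a total of ``photon_budget``
    photons and Poisson-sampled when a budget is given (noiseless otherwise).
    The central region and gap stripes are marked unknown; pixels above the
    saturation level are marked saturated (and unknown).  Returns the
    pattern and the ground truth.
    """
    rho_true = np.asarray(rho_true, dtype=complex)
    n_p = rho_true.shape[0]
    intensity = np.abs(ft(rho_true)) ** 2
    if photon_budget is not None:
        total = intensity.sum()
        if total > 0:
            intensity *= photon_budget / total
        if rng is None:
            rng = np.random.default_rng()
        intensity = rng.poisson(intensity).astype(float)

    known = np.ones((n_p, n_p), dtype=bool)
    sat = np.zeros((n_p, n_p), dtype=bool)
    if masks is not None:
        c = n_p // 2
        if masks.central_shape == "disk" and masks.central_size > 0:
            rows = np.arange(n_p)[:, None] - c
            cols = np.arange(n_p)[None, :] - c
            known &= rows**2 + cols**2 > masks.central_size**2
        elif masks.central_shape == "rectangle" and masks.central_size > 0:
            h = int(round(masks.central_size / 2))
            known[c - h : c + h, c - h : c + h] = False
        for orient, off, width in masks.gap_stripes:
            if orient == "h":
                known[off : off + width, :] = False
            else:
                known[:, off : off + width] = False
        if masks.saturation_level is not None and np.isfinite(masks.saturation_level):
            sat = intensity > masks.saturation_level
            known &= ~sat
    data = DiffractionData.from_arrays(intensity, known, sat)
    return data, rho_true


def two_sphere_density(n_p: int = 128) -> np.ndarray:
    """Standard compact test object: two projected spheres of unequal size.

    Both spheres sit inside a ~50-pixel region around the matrix center so
    the oversampling condition holds comfortably at the default sizes.
    """
    c = n_p // 2
    rho = projected_sphere(SphereSpec((c - 7.0, c - 9.0), 22.0), n_p)
    rho += projected_sphere(SphereSpec((c + 9.0, c + 7.0), 14.0), n_p)
    return rho
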