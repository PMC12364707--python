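"""Constraint projectors, iterative algorithms and the error functional.

Phase retrieval alternates two constraints on a density ``rho``:

* the *support projector* ``P_S rho = S * rho`` zeroes the density outside
  the boolean support;
* the *modulus projector* ``P_M`` replaces Fourier amplitudes with the
  measured ones, keeping phases.

Error Reduction (ER = ``P_M C_chi P_S``) descends the error monotonically but
stagnates; Hybrid Input-Output (HIO) and Relaxed Averaged Alternating
Reflections (RAAR) trade stability for ergodicity.  The positivity
constraint is generalized to a phase wedge ``[-chi*pi, chi*pi]`` (``chi=0.5``
is classic positivity, ``chi=1`` no constraint).

For patterns with unmeasured gap stripes the modulus projector can clamp
runaway amplitudes with a per-ring statistical upper bound
``U(q)^2 = mu_I(q) + eta * sigma_I(q)`` computed from the known pixels of
each ring (the radial profile and its azimuthal spread).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fft import ft, ift, phase_factor
from .data_model import DiffractionData

__all__ = [
    "RadialBounds",
    "SequencePlan",
    "project_support",
    "apply_phase_constraint",
    "project_modulus",
    "er_iterate",
    "hio_iterate",
    "raar_iterate",
    "run_sequence",
    "compute_error",
    "radial_stats",
    "compute_upper_bounds",
]


@dataclass
class RadialBounds:
    """Per-ring statistics of the known intensities and the derived bound.

    ``ring_index`` maps every pixel to its integer ring (rounded Euclidean
    distance from the DC pixel); ``mu_i``/``sigma_i`` are the per-ring mean
    and population standard deviation of the known intensities; ``valid``
    flags rings with enough trustworthy pixels.  ``upper`` is the per-pixel
    *modulus* bound ``sqrt(mu_I + eta*sigma_I)`` and ``applicable`` marks the
    unknown, unsaturated pixels on valid rings where the bound is enforced.
    """

    ring_index: np.ndarray
    mu_i: np.ndarray
    sigma_i: np.ndarray
    valid: np.ndarray
    upper: np.ndarray | None = None
    applicable: np.ndarray | None = None


@dataclass
class SequencePlan:
    """Iteration counts of one algorithm sequence: IA then ER."""

    n_ia: int
    n_er: int
    ia_kind: str = "HIO"
    beta: float = 0.9

    def __post_init__(self) -> None:
        if self.n_ia < 0 or self.n_er < 0:
            raise ValueError("iteration counts must be non-negative")
        if self.n_ia + self.n_er < 1:
            raise ValueError("a sequence must contain at least one iteration")
        if self.ia_kind not in ("HIO", "RAAR"):
            raise ValueError("ia_kind must be 'HIO' or 'RAAR'")
        if not (0 < self.beta <= 1):
            raise ValueError("beta must satisfy 0 < beta <= 1")


def project_support(rho: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Zero the density outside the support (elementwise S * rho)."""
    if rho.shape != support.shape:
        raise ValueError("density and support must share their shape")
    return np.where(support, rho, 0.0)


def apply_phase_constraint(rho: np.ndarray, chi: float) -> np.ndarray:
    """Zero pixels whose phase falls outside the wedge [-chi*pi, chi*pi].

    chi=1 admits the full complex plane (identity); chi=0.5 on a real-valued
    density zeroes the negative entries, i.e. the classic positivity
    constraint.  Violating pixels are zeroed, mirroring how support
    violations are treated.
    """
    if not (0 < chi <= 1):
        raise ValueError("chi must satisfy 0 < chi <= 1")
    if chi == 1.0:
        return np.asarray(rho, dtype=complex)
    ok = np.abs(np.angle(rho)) <= chi * np.pi
    return np.where(ok, rho, 0.0)


def project_modulus(
    rho: np.ndarray,
    data: DiffractionData,
    bounds: RadialBounds | None = None,
) -> np.ndarray:
    """Impose measured Fourier amplitudes, keeping phases.

    Known pixels take the measured modulus exactly.  Unknown pixels float
    freely unless ``bounds`` is given, in which case unsaturated unknown
    pixels on valid rings are clamped down to the ring's upper bound whenever
    the current amplitude exceeds it.  Zero-amplitude Fourier pixels get
    phase 0 (deterministic convention).
    """
    rt = ft(np.asarray(rho, dtype=complex))
    pf = phase_factor(rt)
    out = rt.copy()
    xi = data.known_mask
    out[xi] = data.modulus[xi] * pf[xi]
    if bounds is not None and bounds.upper is not None:
        clamp = bounds.applicable & (np.abs(rt) > bounds.upper)
        out[clamp] = bounds.upper[clamp] * pf[clamp]
    return ift(out)


def er_iterate(
    rho: np.ndarray,
    support: np.ndarray,
    data: DiffractionData,
    chi: float = 1.0,
    bounds: RadialBounds | None = None,
) -> np.ndarray:
    """One Error-Reduction step: P_M applied to the constrained density."""
    return project_modulus(
        apply_phase_constraint(project_support(rho, support), chi), data, bounds
    )


def hio_iterate(
    rho: np.ndarray,
    support: np.ndarray,
    data: DiffractionData,
    chi: float = 1.0,
    beta: float = 0.9,
    bounds: RadialBounds | None = None,
) -> np.ndarray:
    """One Hybrid Input-Output step (Fienup's feedback update).

    Where the modulus-projected density already satisfies the real-space
    constraints (inside the support with an admissible phase) it is accepted;
    everywhere else the input is pushed away by ``-beta`` times the
    projection.
    """
    if not (0 < beta <= 1):
        raise ValueError("beta must satisfy 0 < beta <= 1")
    rho = np.asarray(rho, dtype=complex)
    rho_m = project_modulus(rho, data, bounds)
    ok = support & (np.abs(np.angle(rho_m)) <= chi * np.pi)
    return np.where(ok, rho_m, rho - beta * rho_m)


def raar_iterate(
    rho: np.ndarray,
    support: np.ndarray,
    data: DiffractionData,
    chi: float = 1.0,
    beta: float = 0.9,
    bounds: RadialBounds | None = None,
) -> np.ndarray:
    """One Relaxed Averaged Alternating Reflections step.

    ``rho' = (beta/2) (R_S R_M rho + rho) + (1-beta) P_M rho`` with
    reflectors ``R = 2P - I``; the real-space projector is the phase-wedge
    constraint composed with the support projector.  ``beta=1`` is the pure
    averaged-alternating-reflections limit.
    """
    if not (0 < beta <= 1):
        raise ValueError("beta must satisfy 0 < beta <= 1")
    rho = np.asarray(rho, dtype=complex)
    pm = project_modulus(rho, data, bounds)
    rm = 2.0 * pm - rho
    ps_rm = apply_phase_constraint(project_support(rm, support), chi)
    rs_rm = 2.0 * ps_rm - rm
    return 0.5 * beta * (rs_rm + rho) + (1.0 - beta) * pm


def run_sequence(
    rho: np.ndarray,
    support: np.ndarray,
    data: DiffractionData,
    plan: SequencePlan,
    chi: float = 1.0,
    bounds: RadialBounds | None = None,
) -> np.ndarray:
    """Run ``n_ia`` ergodic iterations followed by ``n_er`` ER iterations."""
    step = hio_iterate if plan.ia_kind == "HIO" else raar_iterate
    for _ in range(plan.n_ia):
        rho = step(rho, support, data, chi, plan.beta, bounds)
    for _ in range(plan.n_er):
        rho = er_iterate(rho, support, data, chi, bounds)
    return rho


def compute_error(
    rho: np.ndarray, support: np.ndarray, data: DiffractionData
) -> float:
    """Relative Fourier-amplitude misfit of the support-constrained density.

    ``E = sqrt( sum Xi (|FT[S*rho]| - M)^2 / sum Xi M^2 )``.  The L2
    normalization by the measured modulus makes values comparable across
    patterns (a zero density scores exactly 1).
    """
    xi = data.known_mask
    denom = np.sum(data.modulus[xi] ** 2)
    if denom <= 0:
        raise ZeroDivisionError("all known moduli are zero; error undefined")
    amp = np.abs(ft(project_support(rho, support)))
    num = np.sum((amp[xi] - data.modulus[xi]) ** 2)
    return float(np.sqrt(num / denom))


def _ring_index(n_p: int) -> np.ndarray:
    c = n_p // 2
    rows = np.arange(n_p)[:, None] - c
    cols = np.arange(n_p)[None, :] - c
    return np.rint(np.sqrt(rows**2 + cols**2)).astype(int)


def radial_stats(
    data: DiffractionData,
    unknown_ring_fraction_max: float = 0.20,
    saturated_ring_fraction_max: float = 0.05,
) -> RadialBounds:
    """Per-ring mean/std of the known intensities with validity flags.

    Pixels are binned by rounded Euclidean distance from the DC pixel.  A
    ring is valid only if its unknown fraction and saturated fraction stay
    below the configured cutoffs (the statistical extrapolation to the
    unknown pixels is only trustworthy when few are missing) and it contains
    at least one known pixel.  The std is the population one.
    """
    n_p = data.n_p
    ring = _ring_index(n_p)
    n_rings = ring.max() + 1
    flat_ring = ring.ravel()
    xi = data.known_mask.ravel()
    sat = data.saturation_mask.ravel()
    inten = data.intensities.ravel()

    total = np.bincount(flat_ring, minlength=n_rings)
    known = np.bincount(flat_ring, weights=xi.astype(float), minlength=n_rings)
    satn = np.bincount(flat_ring, weights=sat.astype(float), minlength=n_rings)
    s1 = np.bincount(flat_ring, weights=inten * xi, minlength=n_rings)
    s2 = np.bincount(flat_ring, weights=inten**2 * xi, minlength=n_rings)

    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(known > 0, s1 / known, np.nan)
        var = np.where(known > 0, s2 / known - mu**2, np.nan)
    sigma = np.sqrt(np.clip(var, 0.0, None))

    unknown_frac = 1.0 - known / total
    sat_frac = satn / total
    valid = (
        (known >= 1)
        & (unknown_frac <= unknown_ring_fraction_max)
        & (sat_frac <= saturated_ring_fraction_max)
    )
    return RadialBounds(ring_index=ring, mu_i=mu, sigma_i=sigma, valid=valid)


def compute_upper_bounds(
    data: DiffractionData,
    eta: float = 1.5,
    unknown_ring_fraction_max: float = 0.20,
    saturated_ring_fraction_max: float = 0.05,
) -> RadialBounds:
    """Radial upper bounds for unmeasured amplitudes.

    On valid rings the intensity bound is ``mu_I + eta*sigma_I``; it is
    stored as a modulus bound ``U = sqrt(mu_I + eta*sigma_I)`` and applies
    only at unknown, unsaturated pixels (saturated pixels are never
    constrained).
    """
    if eta < 0:
        raise ValueError("eta must be non-negative")
    stats = radial_stats(data, unknown_ring_fraction_max, saturated_ring_fraction_max)
    ring_bound = np.sqrt(np.clip(stats.mu_i + eta * stats.sigma_i, 0.0, None))
    ring_bound = np.where(stats.valid, ring_bound, np.inf)
    stats.upper = ring_bound[stats.ring_index]
    stats.applicable = (
        stats.valid[stats.ring_index]
        & ~data.known_mask
        & ~data.saturation_mask
    )
    stats.upper = np.where(stats.applicable, stats.upper, np.inf)
    return stats
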