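"""Population evolution: initialization, alignment, crossover, selection.

The engine evolves a population of candidate reconstructions over G
generations.  Each generation a new population is bred by a differential-
evolution crossover acting on Fourier tiles, both populations are locally
optimized by sequences of iterative phase-retrieval algorithms interleaved
with shrink-wrap support updates (the *self-improvement*), and an index-wise
selection keeps whichever of parent and offspring reached the lower error.
The phase problem's intrinsic ambiguities (translation, global phase,
conjugate point reflection) are resolved by a masked cross-correlation
alignment before any operation that combines densities.

The conventional multi-start workflow (IPR) is the same machinery with
crossover and selection switched off: every member evolves independently
under the standard shrink-wrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._fft import ft, ift, phase_factor, point_reflect
from .data_model import (
    DiffractionData,
    GenerationMetrics,
    MPRConfig,
    Population,
    Reconstruction,
)
from .forward_sim import normalize_density, random_density
from .projections import (
    RadialBounds,
    SequencePlan,
    compute_error,
    compute_upper_bounds,
    run_sequence,
)
from .support_update import Schedule, schedule_value, shrink_wrap, shrink_wrap_area

logger = logging.getLogger("memret")

__all__ = [
    "AlignmentTransform",
    "CrossoverMap",
    "initialize_population",
    "align",
    "crossover_map",
    "average_moduli",
    "crossover",
    "improve",
    "select",
    "average_reconstruction",
    "complexity",
    "oversampling",
    "collect_metrics",
    "population_table",
    "run_mpr",
]


@dataclass
class AlignmentTransform:
    """Ambiguity-resolving transform: integer shift, global phase, flip.

    Applying it permutes pixels and rotates the global phase only, so the
    Fourier modulus of the density is unchanged.
    """

    shift: tuple[int, int]
    global_phase: float
    conjugate_flip: bool


@dataclass
class CrossoverMap:
    """Boolean Fourier-space tiling that selects the mixed regions."""

    map: np.ndarray
    tile_size: tuple[int, int]
    shift: tuple[float, float]
    rotation: float


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def initialize_population(
    cfg: MPRConfig, data: DiffractionData, rng: np.random.Generator
) -> Population:
    """P random sphere-filled densities, power-normalized, square supports."""
    if cfg.n_p is None:
        cfg.n_p = data.n_p
    n_p, edge = data.n_p, cfg.sigma_init
    c, half = n_p // 2, edge // 2
    support = np.zeros((n_p, n_p), dtype=bool)
    support[c - half : c - half + edge, c - half : c - half + edge] = True
    members = []
    for _ in range(cfg.p):
        rho = normalize_density(random_density(cfg, rng), data)
        err = compute_error(rho, support, data)
        members.append(Reconstruction(rho, support.copy(), err))
    return Population(members)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def _masked_crosscorr(
    rho: np.ndarray, ft_ref: np.ndarray, xi: np.ndarray
) -> np.ndarray:
    """Masked cross-correlation via the convolution theorem."""
    return ift(xi * np.conj(ft(rho)) * ft_ref)


def align(
    rho: np.ndarray,
    support: np.ndarray,
    rho_ref: np.ndarray,
    xi: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, AlignmentTransform]:
    """Transform (rho, S) to overlap a reference density.

    The masked cross-correlation is evaluated for the density and for its
    conjugate point reflection; the candidate with the larger correlation
    peak wins.  The peak position (relative to the matrix center) gives the
    integer shift, the peak's phase the global phase correction.  The
    support undergoes the same flip and shift, without phase.
    """
    if not np.any(np.abs(rho_ref) > 0):
        raise ValueError("degenerate (all-zero) reference density")
    ft_ref = ft(np.asarray(rho_ref, dtype=complex))
    c = rho.shape[0] // 2

    best = None
    for flipped in (False, True):
        cand = np.conj(point_reflect(rho)) if flipped else np.asarray(rho, complex)
        cc = _masked_crosscorr(cand, ft_ref, xi)
        k = np.unravel_index(np.argmax(np.abs(cc)), cc.shape)
        peak = cc[k]
        if best is None or np.abs(peak) > np.abs(best[0]):
            best = (peak, k, flipped, cand)
    peak, k, flipped, cand = best  # type: ignore[misc]
    shift = (int(k[0]) - c, int(k[1]) - c)
    phase = float(np.angle(peak))
    aligned = np.roll(cand, shift, axis=(0, 1)) * np.exp(1j * phase)
    s = point_reflect(support) if flipped else support
    aligned_support = np.roll(s, shift, axis=(0, 1))
    return aligned, aligned_support, AlignmentTransform(shift, phase, flipped)


# ---------------------------------------------------------------------------
# crossover
# ---------------------------------------------------------------------------


def crossover_map(
    t_min: int,
    t_max: int,
    c_p: float,
    n_p: int,
    rng: np.random.Generator,
) -> CrossoverMap:
    """Random rotated tiling of Fourier space with per-tile election.

    Tile height/width are uniform in [t_min, t_max]; the tile lattice is
    rotated by a uniform angle in [0, pi) and shifted by a uniform offset
    within one tile, then rasterized by nearest-neighbor sampling.  Each
    tile is independently elected with probability c_p.
    """
    if not (1 <= t_min <= t_max < n_p):
        raise ValueError("tile sizes must satisfy 1 <= t_min <= t_max < n_p")
    t_x = int(rng.integers(t_min, t_max + 1))
    t_y = int(rng.integers(t_min, t_max + 1))
    theta = float(rng.uniform(0.0, np.pi))
    s_x = float(rng.uniform(0.0, t_x))
    s_y = float(rng.uniform(0.0, t_y))

    c = n_p // 2
    rows = np.arange(n_p)[:, None] - c
    cols = np.arange(n_p)[None, :] - c
    u = np.cos(theta) * rows + np.sin(theta) * cols
    v = -np.sin(theta) * rows + np.cos(theta) * cols
    tiles_r = np.floor((u + s_x) / t_x).astype(int)
    tiles_c = np.floor((v + s_y) / t_y).astype(int)
    # compact pair -> unique tile id
    pair = (tiles_r - tiles_r.min()) * (tiles_c.max() - tiles_c.min() + 1) + (
        tiles_c - tiles_c.min()
    )
    n_tiles = pair.max() + 1
    elected = rng.random(n_tiles) < c_p if c_p > 0 else np.zeros(n_tiles, bool)
    cmap = elected[pair]
    return CrossoverMap(
        map=cmap, tile_size=(t_x, t_y), shift=(s_x, s_y), rotation=theta
    )


def average_moduli(
    pop: Population, reference: Reconstruction, xi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Coherent and incoherent average Fourier moduli of the population.

    After aligning every member to the reference, ``M_dot`` is the modulus
    of the Fourier transform of the mean density (coherent, phase
    cancellation lowers it) and ``M_ddot`` the mean of the individual moduli
    (incoherent).  By the triangle inequality ``M_dot <= M_ddot``
    elementwise, with equality only when all Fourier phases agree.
    """
    acc = None
    mod_acc = None
    for m in pop:
        aligned, _, _ = align(m.density, m.support, reference.density, xi)
        f = ft(aligned)
        acc = f if acc is None else acc + f
        a = np.abs(f)
        mod_acc = a if mod_acc is None else mod_acc + a
    p = len(pop)
    return np.abs(acc) / p, mod_acc / p


def crossover(
    pop: Population,
    cfg: MPRConfig,
    data: DiffractionData,
    m_dot: np.ndarray | None,
    m_ddot: np.ndarray | None,
    rng: np.random.Generator,
) -> Population:
    """Breed a new population by differential-evolution Fourier mixing.

    The new population starts as a copy of the old one.  For each index p,
    three distinct parents a, b, c (all != p) are drawn and aligned to
    member p; inside the elected crossover tiles the new Fourier density is
    ``rho_a + C_w (rho_b - rho_c)``, outside it stays the copy of member p.
    When ``C_a > 0`` parent a's Fourier moduli are first blended with the
    population-average moduli ``(M_dot + M_ddot)/2`` (keeping phases) to
    pin down the weakly constrained low-q modes.  Supports mix everywhere as
    ``S_a OR (S_b AND S_c AND S_p)``.
    """
    p_size = len(pop)
    if p_size < 4:
        raise ValueError("crossover needs a population of at least 4")
    xi = data.known_mask
    t_max = cfg.resolved_t_max() if cfg.n_p else cfg.t_max
    if t_max is None:
        t_max = max(cfg.t_min, data.n_p // 8)
    avg_mod = None
    if cfg.c_a > 0:
        if m_dot is None or m_ddot is None:
            raise ValueError("c_a > 0 requires the average moduli")
        avg_mod = 0.5 * (m_dot + m_ddot)

    new_members = []
    for p in range(p_size):
        target = pop[p]
        choices = [q for q in range(p_size) if q != p]
        a, b, c = rng.choice(choices, size=3, replace=False)
        parents = []
        for q in (a, b, c):
            ar, asup, _ = align(pop[q].density, pop[q].support, target.density, xi)
            parents.append((ar, asup))
        (rho_a, s_a), (rho_b, s_b), (rho_c, s_c) = parents

        fa = ft(rho_a)
        if avg_mod is not None:
            fa = (cfg.c_a * avg_mod + (1.0 - cfg.c_a) * np.abs(fa)) * phase_factor(fa)
        fb, fc = ft(rho_b), ft(rho_c)
        cmap = crossover_map(cfg.t_min, t_max, cfg.c_p, data.n_p, rng)
        f_new = np.where(cmap.map, fa + cfg.c_w * (fb - fc), ft(target.density))
        s_new = s_a | (s_b & s_c & target.support)
        new_members.append(Reconstruction(ift(f_new), s_new))
    return Population(new_members)


# ---------------------------------------------------------------------------
# self-improvement and selection
# ---------------------------------------------------------------------------


def _scheduled(cfg: MPRConfig, g: int) -> tuple[SequencePlan, float, float]:
    """Sequence plan and shrink-wrap parameters at generation g."""
    n_ia = schedule_value(Schedule(cfg.j_ia, 0, cfg.g), g, integer=True)
    n_er = schedule_value(
        Schedule(cfg.j_er, cfg.j_ia + cfg.j_er, cfg.g), g, integer=True
    )
    plan = SequencePlan(n_ia=n_ia, n_er=n_er, ia_kind=cfg.ia_kind, beta=cfg.beta)
    tau_g = schedule_value(Schedule(cfg.tau, cfg.tau_end, cfg.g), g)
    sigma_g = schedule_value(Schedule(cfg.sigma, cfg.sigma_end, cfg.g), g)
    return plan, sigma_g, tau_g


def improve(
    pop: Population,
    pop_new: Population,
    cfg: MPRConfig,
    g: int,
    data: DiffractionData,
    bounds: RadialBounds | None = None,
) -> tuple[Population, Population]:
    """Self-improvement of both populations with fair error evaluation.

    Every member runs R-2 repetitions of [algorithm sequence; standard
    shrink-wrap], then a sequence followed by an area-targeted support
    update to the best member's area (pulls oversized supports out of
    stagnation), then a sequence followed by an update to the evaluation
    area ``alpha_eval = (g/G) alpha_best + (1-g/G) alpha_all`` (interpolating
    from the union of all supports towards the best one), the ER-only
    evaluation sequence, the error evaluation, and a final standard
    shrink-wrap.  Because every error is measured on a support of exactly
    ``alpha_eval`` pixels, parent and offspring errors are comparable in the
    selection step.
    """
    if cfg.r_reps < 2:
        raise ValueError("r_reps must be at least 2")
    if len(pop) != len(pop_new):
        raise ValueError("populations must have equal size")
    plan, sigma_g, tau_g = _scheduled(cfg, g)
    eval_plan = SequencePlan(n_ia=0, n_er=cfg.j_eval, ia_kind=cfg.ia_kind, beta=cfg.beta)

    alpha_best = int(pop.best().support.sum())
    union = np.zeros_like(pop[0].support)
    for m in pop:
        union |= m.support
    alpha_all = int(union.sum())
    frac = g / cfg.g
    alpha_eval = int(np.floor(frac * alpha_best + (1.0 - frac) * alpha_all + 0.5))
    alpha_eval = max(1, alpha_eval)

    for member in list(pop) + list(pop_new):
        rho, s = member.density, member.support
        for _ in range(cfg.r_reps - 2):
            rho = run_sequence(rho, s, data, plan, cfg.chi, bounds)
            s = shrink_wrap(rho, sigma_g, tau_g)
        rho = run_sequence(rho, s, data, plan, cfg.chi, bounds)
        s = shrink_wrap_area(rho, sigma_g, alpha_best)
        rho = run_sequence(rho, s, data, plan, cfg.chi, bounds)
        s = shrink_wrap_area(rho, sigma_g, alpha_eval)
        rho = run_sequence(rho, s, data, eval_plan, cfg.chi, bounds)
        member.error = compute_error(rho, s, data)
        member.eval_area = alpha_eval
        member.density = rho
        member.support = shrink_wrap(rho, sigma_g, tau_g)
    return pop, pop_new


def improve_independent(
    pop: Population,
    cfg: MPRConfig,
    g: int,
    data: DiffractionData,
    bounds: RadialBounds | None = None,
) -> Population:
    """Conventional multi-start update: sequences + standard shrink-wrap only."""
    plan, sigma_g, tau_g = _scheduled(cfg, g)
    for member in pop:
        rho, s = member.density, member.support
        for _ in range(cfg.r_reps):
            rho = run_sequence(rho, s, data, plan, cfg.chi, bounds)
            s = shrink_wrap(rho, sigma_g, tau_g)
        member.density = rho
        member.support = s
        member.error = compute_error(rho, s, data)
        member.eval_area = int(s.sum())
    return pop


def select(pop: Population, pop_new: Population) -> tuple[Population, float]:
    """Index-wise survival of the lower error; strict '<' favors parents on ties."""
    if len(pop) != len(pop_new):
        raise ValueError("populations must have equal size")
    replaced = 0
    members = []
    for old, new in zip(pop, pop_new):
        if new.error < old.error:
            members.append(new)
            replaced += 1
        else:
            members.append(old)
    return Population(members), 100.0 * replaced / len(pop)


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------


def average_reconstruction(
    pop: Population, reference: Reconstruction, data: DiffractionData
) -> Reconstruction:
    """Aligned population mean: mean density, union support, its error."""
    xi = data.known_mask
    acc = None
    union = np.zeros_like(pop[0].support)
    for m in pop:
        aligned, asup, _ = align(m.density, m.support, reference.density, xi)
        acc = aligned if acc is None else acc + aligned
        union |= asup
    density = acc / len(pop)
    err = compute_error(density, union, data)
    return Reconstruction(density, union, err)


def complexity(rho: np.ndarray) -> float:
    """Phase-heterogeneity indicator Gamma = 1 - |sum rho| / sum |rho|.

    0 for a constant-phase (e.g. strictly positive real) density, up to 1
    when contributions cancel completely.
    """
    denom = np.sum(np.abs(rho))
    if denom <= 0:
        raise ValueError("degenerate (all-zero) density")
    # clip rounding noise so the [0, 1] range holds exactly
    return float(min(1.0, max(0.0, 1.0 - np.abs(np.sum(rho)) / denom)))


def oversampling(support: np.ndarray, n_p: int | None = None) -> float:
    """Oversampling ratio O_d = N_p^2 / (support pixel count)."""
    area = int(np.count_nonzero(support))
    if area < 1:
        raise ValueError("empty support: oversampling undefined")
    if n_p is None:
        n_p = support.shape[0]
    return n_p**2 / area


def collect_metrics(
    pop: Population,
    avg_recon: Reconstruction,
    replacement_pct: float,
    g: int,
) -> GenerationMetrics:
    """Assemble the per-generation indicator record."""
    errors = pop.errors
    sums = np.array([np.abs(np.sum(m.density)) for m in pop])
    gammas = np.array([complexity(m.density) for m in pop])
    sum_mean = float(sums.mean())
    rel_std = float(100.0 * sums.std() / sum_mean) if sum_mean > 0 else 0.0
    return GenerationMetrics(
        g=g,
        e_best=float(errors.min()),
        e_mean=float(errors.mean()),
        e_worst=float(errors.max()),
        e_avg_recon=float(avg_recon.error),
        o_d_best=oversampling(pop.best().support),
        replacement_pct=float(replacement_pct),
        density_sum_mean=sum_mean,
        density_sum_rel_std=rel_std,
        gamma_mean=float(gammas.mean()),
        gamma_avg_recon=complexity(avg_recon.density),
    )


def population_table(pop: Population) -> list[dict[str, float]]:
    """Per-member error and oversampling (multi-start scatter diagnostics)."""
    return [
        {
            "p": p,
            "error": float(m.error),
            "oversampling": oversampling(m.support),
        }
        for p, m in enumerate(pop)
    ]


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_mpr(
    data: DiffractionData,
    cfg: MPRConfig,
    return_population: bool = False,
):
    """Full reconstruction: G generations of evolve/improve/select.

    In MPR mode each generation runs average-moduli extraction (when
    ``C_a > 0``), crossover, self-improvement of both populations and
    selection.  In IPR mode crossover and selection are switched off and
    each member evolves independently.  The aligned average reconstruction
    of the last generation is the output; the full metrics trace accompanies
    it.  With a fixed seed the run is bit-reproducible.
    """
    if cfg.n_p is None:
        cfg.n_p = data.n_p
    elif cfg.n_p != data.n_p:
        raise ValueError(f"config n_p={cfg.n_p} does not match data N_p={data.n_p}")
    rng = np.random.default_rng(cfg.seed)
    bounds = (
        compute_upper_bounds(
            data,
            cfg.eta,
            cfg.unknown_ring_fraction_max,
            cfg.saturated_ring_fraction_max,
        )
        if cfg.gap_bounds
        else None
    )
    pop = initialize_population(cfg, data, rng)
    metrics: list[GenerationMetrics] = []
    avg = None
    for g in range(1, cfg.g + 1):
        if cfg.mode == "MPR":
            best = pop.best()
            m_dot = m_ddot = None
            if cfg.c_a > 0:
                m_dot, m_ddot = average_moduli(pop, best, data.known_mask)
            pop_new = crossover(pop, cfg, data, m_dot, m_ddot, rng)
            improve(pop, pop_new, cfg, g, data, bounds)
            pop, replacement = select(pop, pop_new)
        else:
            improve_independent(pop, cfg, g, data, bounds)
            replacement = 0.0
        avg = average_reconstruction(pop, pop.best(), data)
        record = collect_metrics(pop, avg, replacement, g)
        metrics.append(record)
        logger.info("generation %s", record.as_record())
    if return_population:
        return avg, metrics, pop
    return avg, metrics
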