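# Methods

## The reconstruction problem

In small-angle, far-field single-particle coherent diffraction imaging the
detector records intensities `I(q) = |F[rho](q)|^2`, the squared Fourier
modulus of the sample's projected complex density `rho(x)`. The Fourier
phases are lost; they are recoverable only because the sample is compact
(the oversampling condition), which is enforced by a boolean support `S`.
`memret` reconstructs `rho` by minimizing the relative amplitude misfit

    E[rho] = sqrt( sum Xi (|F[S*rho]| - M)^2 / sum Xi M^2 ),

where `M = sqrt(I)` and `Xi` marks the measured, unsaturated pixels. All
transforms are unitary and DC-centered: the zero-frequency sample sits at
matrix index `(N_p//2, N_p//2)` in both spaces, and `sum |rho|^2 = sum
|F[rho]|^2` (Parseval), so with a fully measured pattern the modulus
projector pins the density's L2 norm.

## Projection algorithms

Two projectors implement the constraints. The support projector `P_S rho =
S * rho` (combined with a phase wedge, below). The modulus projector `P_M`
replaces Fourier amplitudes with `M` where `Xi = 1`, keeping phases;
zero-amplitude Fourier pixels get phase 0, a deterministic arbitrary choice.

* **ER** (`P_M C_chi P_S`) descends `E` monotonically but stagnates in local
  minima. The monotonicity guarantee applies to the plain alternating
  projection (`chi = 1`); with an active phase wedge the functional measured
  on `S*rho` alone is no longer the exact descent target.
* **HIO** accepts the modulus-projected density where it satisfies the
  real-space constraints and applies the feedback `rho - beta * P_M rho`
  elsewhere (Fienup's update; the formula is the canonical published one).
* **RAAR** relaxes averaged alternating reflections:
  `rho' = (beta/2)(R_S R_M rho + rho) + (1 - beta) P_M rho`, `R = 2P - I`
  (Luke's form). `beta = 1` is the pure reflect-reflect-average limit.

The positivity constraint is generalized to a phase wedge: pixels whose
phase leaves `[-chi*pi, chi*pi]` are zeroed (like support violations, the
standard positivity-HIO practice, rather than projecting the phase onto the
wedge boundary). `chi = 0.5` is classic positivity for real-valued samples;
`chi = 1` disables the constraint for strongly phase-contrasted objects.

A *sequence* is `j_ia` ergodic iterations (HIO or RAAR) followed by `j_er`
ER iterations. Over the `G` generations `j_ia` ramps linearly to 0 and
`j_er` to `j_ia + j_er`, so the late phase is pure ER; the shrink-wrap
threshold ramps `tau -> 2tau/3` and its smoothing width `sigma -> 0.5 px`.
Linear schedules are evaluated at generation `g` as
`start + (end-start)(g-1)/(G-1)`, iteration counts rounded half-up.

## Support estimation

Standard shrink-wrap smooths `|rho|` with a gaussian of width `sigma`
(applied by Fourier multiplication with periodic wrap — edge effects are
negligible for compact objects) and keeps pixels at or above `tau` times the
smoothed maximum; the argmax always qualifies, so the support is never
empty. Smoothing acts on the modulus because a complex density must be
supported where its magnitude is large. The *area-targeted* variant keeps
exactly `alpha` pixels (the top-`alpha` of the smoothed modulus, cutoff ties
broken deterministically in row-major order); it exists because error values
are only comparable between reconstructions whose supports have the same
pixel count — a looser support always scores a lower error.

## The memetic loop

A population of `P` candidate reconstructions evolves for `G` generations:

1. **Crossover.** A new population starts as a copy of the old one. For each
   index `p`, three distinct parents `a, b, c != p` are drawn, aligned to
   member `p`, and mixed in Fourier space inside randomly elected tiles:
   `rho~_new = rho~_a + C_w (rho~_b - rho~_c)` (differential evolution).
   Tiling (random size in `[t_min, t_max]`, random rotation in `[0, pi)` and
   offset within one tile, nearest-neighbor rasterized, tiles elected with
   probability `C_p`) preserves the local Fourier correlations implied by
   the object's compactness. Supports mix everywhere as
   `S_a OR (S_b AND S_c AND S_p)`.
2. **Self-improvement** of both populations: `R-2` repetitions of
   [sequence; shrink-wrap], then sequence + area-targeted update to the best
   member's area `alpha_best` (pulls oversized supports out of stagnation),
   then sequence + update to the evaluation area
   `alpha_eval = (g/G) alpha_best + (1-g/G) alpha_all` (`alpha_all` = union
   of all parent supports), an ER-only evaluation sequence of `j_eval`
   iterations, the error evaluation — every member's error is thus measured
   on a support of exactly `alpha_eval` pixels — and a final standard
   shrink-wrap.
3. **Selection.** Index-wise, the offspring replaces the parent iff its
   error is strictly lower (strict `<` keeps parents on ties, a stable
   deterministic choice). The *replacement factor* (percentage of indices
   replaced) starts near 50% — parent and offspring populations are
   statistically equivalent random starts — and stabilizes below 50% once
   real structure emerges.

Ambiguities of the phase problem (translation, global phase, conjugate
point reflection) are resolved before any operation that combines densities
by a masked cross-correlation `invF[Xi * conj(F rho) * F rho_ref]`,
evaluated for the density and its conjugate reflection; the larger peak
selects the flip, its position the integer shift, its phase the global
phase. Excluding unmeasured pixels (`Xi`) keeps the bright, unmeasured
central speckle from dominating the alignment. Alignment references: the
crossover aligns parents to member `p` (they replace values in `p`'s
frame); population averages align to the current best member, a choice the
procedure leaves open.

The output is the *average reconstruction* of the final generation — the
aligned mean density with the union of aligned supports — because features
shared across the converged population are exactly the reliably retrieved
ones. Monitoring indicators per generation: best/mean/worst error, error of
the average, oversampling ratio `O_d = N_p^2 / area(S_best)`, replacement
factor, the density-sum statistics `|sum rho|` (mean and relative std
across the population) and the complexity `Gamma = 1 - |sum rho| / sum
|rho|` (0 for constant-phase densities, 1 at total cancellation) which
tracks weakly constrained low-q phase modes.

The conventional multi-start baseline (IPR mode) runs the same machinery
with crossover and selection switched off: each member independently
alternates sequences with standard shrink-wrap. Its per-member
error/oversampling table supports the usual convergence-scatter diagnostics.

## Missing-data handling

Pixels are missing for three reasons: detector-module gap stripes, the
central hole, and saturation. For the gaps, a statistical upper bound is
derived from the radial profile: pixels are binned by rounded Euclidean
distance from the DC pixel; per ring the mean `mu_I` and *population*
standard deviation `sigma_I` of the known intensities give the modulus
bound `U = sqrt(mu_I + eta * sigma_I)` with `eta = 1.5` by default. The
bound is statistical extrapolation, so it is only trusted on rings where at
most 20% of pixels are unknown and at most 5% saturated, and it is never
applied at saturated pixels. The modified modulus projector clamps unknown,
unsaturated pixels on valid rings down to `U` whenever their amplitude
exceeds it, and leaves them free otherwise.

The unmeasured center is instead handled through the crossover: with
`C_a > 0`, parent `a`'s Fourier moduli are blended with the population
average `(M_dot + M_ddot)/2` before mixing, where `M_dot = |F[mean rho]|`
(coherent — an underestimate when phases disagree) and `M_ddot = mean
|F[rho]|` (incoherent — an overestimate, `M_dot <= M_ddot` by the triangle
inequality). This damps the weakly constrained low-q modes that the
ergodic algorithms and the crossover would otherwise amplify.

## Synthetic data

The generator builds compact objects from projected uniform balls: at
distance `r` from the center a ball of diameter `D` contributes the chord
`2 sqrt((D/2)^2 - r^2)` — the optical depth of a spherical particle — times
a constant phase; profiles are deliberately not peak-normalized, so bigger
spheres are brighter. Population starts draw `N_init` such spheres with
diameters uniform in `d_init`, phases in `phi_init`, centers placed so each
disk lies fully inside the centered `Sigma_init` square (border-clipped
placement would leak density outside the initial support); the modulus is
then exponentiated by `gamma_init` (image gamma; <1 flattens contrast) and
the density rescaled so its Fourier power on the known pixels matches the
measurement (`sqrt` of the power ratio — the stated goal, matched partial
L2 norms, then holds exactly).

Simulated patterns are `|F[rho_true]|^2`, optionally rescaled to a photon
budget and Poisson-sampled, with a central disk/rectangle, gap stripes and
a saturation threshold applied as mask pathologies. The generator emulates
the geometry and counting statistics of single-shot patterns but not
detector physics: no read noise, no Ewald-sphere curvature, polarization or
point-spread, and perfectly known masks. Tests passing on these fixtures
demonstrate the optimization machinery, not robustness to calibration
errors in real data.

## Default study conditions and problem sizes

Defaults follow the glossary of engine parameters: `P = 128`, `G = 100`,
`N_init = 5`, `d_init = [0.2, 0.9] * Sigma_init`, `phi_init = [0, 0]`,
`gamma_init = 1`, `C_p = 0.6`, `C_w = 0.4`, `C_a = 0`, `tau_end = 2tau/3`,
`sigma = 2 -> sigma_end = 0.5`, `R = 3`, `chi = 0.5`, `j_ia = j_er = j_eval
= 40`, `beta = 0.9`, `eta = 1.5`, `t_min = 4`, `t_max = N_p/8`. `tau` and
`Sigma_init` have no default — they depend on the object — and must be set.

The bundled test and benchmark conditions use a two-sphere object (diameters
22 and 14 px) inside a ~50 px region of a 128x128 (or 64x64) matrix,
`Sigma_init = 60`, `tau = 0.1`; the verification runs use `P = 16`,
`G = 20`, starting IA iterations 20 (recovery) and `P = 32`, one generation
(replacement-factor statistics, 5 seeds). These sizes keep a full
reconstruction in the minutes range on one CPU core while preserving every
algorithmic ingredient of a full-scale run; `tau = 0.1` suits the bright
compact projected-sphere profiles (experimental patterns typically need
`tau` in the 0.02–0.05 range).

The replacement-factor benchmark verifies the fairness of the selection
step under its stated premise: when parent and offspring populations are
statistically equivalent, each index is a fair coin and replacement
averages 50%. The premise is realized directly — both populations drawn as
independent random initializations, each given one generation of
self-improvement before selection — because on this noiseless, fully
measured desk-scale object the reconstruction essentially converges within
the very first generation, a regime hard experimental patterns never reach
that early. In that over-converged regime crossover-bred offspring are no
longer equivalent to their parents: Fourier-tile mixtures of four aligned
random starts retain a small handicap (measured mean replacement ~36% over
20 seeds) that would be washed out over the many pre-convergence
generations of a realistic run, where the ~50% starting value is the
expected behavior.

## Numerical choices and limitations

* Ring binning uses rounded Euclidean distance; population (not sample)
  std. Both are conventions the bound definition leaves open.
* `alpha_eval` is rounded half-up to an integer pixel count.
* Parent triples are drawn uniformly without replacement from indices
  `!= p`.
* Average moduli are computed once per generation, before the crossover
  loop.
* Crossover-map rotation is rasterized by nearest-neighbor sampling of the
  rotated lattice; rotation angle uniform on `[0, pi)`, offsets uniform
  within one tile (distributions the operator definition leaves open).
* Negative measured intensities are clipped to zero and logged, not
  rejected; binned pixels are known only if all constituents are known,
  saturated if any is.
* Seeded runs are bit-reproducible on a given platform; across BLAS/FFT
  builds results match to rounding.
* The engine is single-process NumPy/SciPy; large patterns (`N_p = 512`,
  `P = 128`) are better served by binning (`bin_pattern`) before
  reconstruction.
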