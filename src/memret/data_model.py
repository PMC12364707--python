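"""Domain containers, file I/O, pattern binning and configuration validation.

A single-shot coherent-diffraction measurement is a square matrix of photon
counts ``I`` together with a boolean mask of pixels whose values can be
trusted (measured and unsaturated) and a mask of saturated pixels.  The
reconstruction engine works on :class:`DiffractionData` instances built from
those three matrices; candidate solutions are :class:`Reconstruction` objects
(a complex density, its boolean support and the stored error value), evolved
in an indexed :class:`Population`.

On disk the pattern lives in HDF5 or NPZ files with datasets/keys
``intensities``, ``known_mask`` and ``saturation_mask`` (the last one
optional).  The schema is our own: the measurement itself does not prescribe
a file format.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import h5py
import numpy as np

logger = logging.getLogger("memret")

__all__ = [
    "DiffractionData",
    "Reconstruction",
    "Population",
    "MPRConfig",
    "GenerationMetrics",
    "ConfigError",
    "FormatError",
    "load_diffraction",
    "save_diffraction",
    "bin_pattern",
    "save_result",
    "load_result",
    "validate_config",
]


class FormatError(ValueError):
    """Raised when an input file does not follow the expected schema."""


class ConfigError(ValueError):
    """Raised when a configuration value is missing or out of bounds."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DiffractionData:
    """A measured diffraction pattern with its pixel classification.

    Attributes
    ----------
    intensities:
        Non-negative photon counts, shape ``(N_p, N_p)``, DC at the center
        pixel ``(N_p//2, N_p//2)``.
    modulus:
        ``sqrt(intensities)``, the Fourier-amplitude target of the modulus
        constraint.
    known_mask:
        True where the intensity is measured *and* unsaturated.  Disjoint
        from ``saturation_mask`` by construction.
    saturation_mask:
        True where the detector pixel clipped; such pixels carry no usable
        amplitude information.
    """

    intensities: np.ndarray
    known_mask: np.ndarray
    saturation_mask: np.ndarray
    modulus: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.known_mask = np.asarray(self.known_mask, dtype=bool)
        self.saturation_mask = np.asarray(self.saturation_mask, dtype=bool)
        shp = self.intensities.shape
        if len(shp) != 2 or shp[0] != shp[1]:
            raise FormatError(f"diffraction pattern must be square, got {shp}")
        for name in ("known_mask", "saturation_mask"):
            if getattr(self, name).shape != shp:
                raise FormatError(f"{name} shape {getattr(self, name).shape} != {shp}")
        if np.any(self.known_mask & self.saturation_mask):
            raise FormatError("known_mask and saturation_mask must be disjoint")
        if not self.known_mask.any():
            raise FormatError("empty known-pixel mask: nothing to constrain")
        if np.any(self.intensities < 0):
            raise FormatError("intensities must be non-negative (clip on load)")
        if self.modulus is None:
            self.modulus = np.sqrt(self.intensities)

    @classmethod
    def from_arrays(
        cls,
        intensities: np.ndarray,
        known_mask: np.ndarray,
        saturation_mask: np.ndarray | None = None,
    ) -> "DiffractionData":
        """Build a pattern from raw arrays, applying the sanitation rules.

        Negative counts (detector calibration artifacts) are clipped to zero
        with a logged count; saturated pixels are forced out of the known set.
        """
        intensities = np.array(intensities, dtype=float)
        known = np.array(known_mask, dtype=bool)
        sat = (
            np.zeros_like(known)
            if saturation_mask is None
            else np.array(saturation_mask, dtype=bool)
        )
        n_neg = int(np.count_nonzero(intensities < 0))
        if n_neg:
            logger.warning("clipped %d negative intensity pixels to zero", n_neg)
            np.clip(intensities, 0.0, None, out=intensities)
        known &= ~sat
        return cls(intensities=intensities, known_mask=known, saturation_mask=sat)

    @property
    def n_p(self) -> int:
        return self.intensities.shape[0]


@dataclass
class Reconstruction:
    """One candidate solution: complex density, boolean support, stored error.

    ``eval_area`` records the support area (pixel count) the stored error was
    evaluated on; the selection step is only fair between reconstructions
    whose errors were measured at the same area.
    """

    density: np.ndarray
    support: np.ndarray
    error: float = math.inf
    eval_area: int | None = None

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=complex)
        self.support = np.asarray(self.support, dtype=bool)
        if self.density.shape != self.support.shape:
            raise ValueError("density and support must share their shape")
        if self.error < 0:
            raise ValueError("error must be non-negative")

    def copy(self) -> "Reconstruction":
        return Reconstruction(
            self.density.copy(), self.support.copy(), self.error, self.eval_area
        )


@dataclass
class Population:
    """Ordered set of reconstructions evolved together."""

    members: list[Reconstruction]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("population must contain at least one member")
        n0 = self.members[0].density.shape
        if any(m.density.shape != n0 for m in self.members):
            raise ValueError("all members must share the matrix size")

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, p: int) -> Reconstruction:
        return self.members[p]

    def __iter__(self):
        return iter(self.members)

    @property
    def errors(self) -> np.ndarray:
        return np.array([m.error for m in self.members])

    def best_index(self) -> int:
        return int(np.argmin(self.errors))

    def best(self) -> Reconstruction:
        return self.members[self.best_index()]


@dataclass
class GenerationMetrics:
    """Per-generation performance indicators of the evolving population."""

    g: int
    e_best: float
    e_mean: float
    e_worst: float
    e_avg_recon: float
    o_d_best: float
    replacement_pct: float
    density_sum_mean: float
    density_sum_rel_std: float
    gamma_mean: float
    gamma_avg_recon: float

    def __post_init__(self) -> None:
        if not (self.e_best <= self.e_mean <= self.e_worst):
            raise ValueError("expected e_best <= e_mean <= e_worst")
        if not (0.0 <= self.replacement_pct <= 100.0):
            raise ValueError("replacement_pct must lie in [0, 100]")

    def as_record(self) -> dict[str, float]:
        return {
            "g": self.g,
            "e_best": self.e_best,
            "e_mean": self.e_mean,
            "e_worst": self.e_worst,
            "e_avg": self.e_avg_recon,
            "o_d": self.o_d_best,
            "replacement_pct": self.replacement_pct,
            "sum_mean": self.density_sum_mean,
            "sum_rel_std": self.density_sum_rel_std,
            "gamma_mean": self.gamma_mean,
            "gamma_avg": self.gamma_avg_recon,
        }


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class MPRConfig:
    """Every tunable parameter of the reconstruction engine.

    Names follow the field's conventional symbols (ascii-fied): ``p`` is the
    population size, ``g`` the number of generations, ``sigma_init`` the edge
    of the initial square support, ``j_ia``/``j_er``/``j_eval`` iteration
    counts of the ergodic, error-reduction and evaluation sequences, ``chi``
    the allowed phase fraction of the complex plane, ``eta`` the width of the
    radial upper bound on unmeasured intensities.
    """

    sigma_init: int
    tau: float
    p: int = 128
    g: int = 100
    n_init: int = 5
    d_init: tuple[float, float] | None = None
    phi_init: tuple[float, float] = (0.0, 0.0)
    gamma_init: float = 1.0
    c_p: float = 0.6
    c_w: float = 0.4
    c_a: float = 0.0
    tau_end: float | None = None
    sigma: float = 2.0
    sigma_end: float = 0.5
    r_reps: int = 3
    chi: float = 0.5
    j_ia: int = 40
    beta: float = 0.9
    j_er: int = 40
    j_eval: int = 40
    eta: float = 1.5
    t_min: int = 4
    t_max: int | None = None
    ia_kind: str = "HIO"
    mode: str = "MPR"
    seed: int = 0
    unknown_ring_fraction_max: float = 0.20
    saturated_ring_fraction_max: float = 0.05
    gap_bounds: bool = False
    n_p: int | None = None

    def as_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["d_init"] = tuple(d["d_init"]) if d["d_init"] is not None else None
        d["phi_init"] = tuple(d["phi_init"])
        return d

    def resolved_t_max(self) -> int:
        if self.t_max is not None:
            return self.t_max
        if self.n_p is None:
            raise ConfigError("t_max defaults to n_p/8 but n_p is not set")
        return max(self.t_min, self.n_p // 8)


_BOUNDS_DOC = {
    "p": "population size must satisfy p >= 4",
    "g": "generation count must satisfy g > 1",
    "n_init": "number of initialization spheres must satisfy n_init >= 1",
    "gamma_init": "initialization gamma must satisfy gamma_init > 0",
    "c_p": "crossover probability must satisfy 0 < c_p <= 1",
    "c_w": "differential weight must satisfy 0 <= c_w <= 2",
    "c_a": "crossover averaging must satisfy 0 <= c_a <= 1",
    "tau": "shrink-wrap threshold must satisfy 0 < tau <= 1",
    "tau_end": "final shrink-wrap threshold must satisfy 0 < tau_end <= 1",
    "sigma": "shrink-wrap smoothing must satisfy sigma >= 0",
    "sigma_end": "final shrink-wrap smoothing must satisfy sigma_end >= 0",
    "r_reps": "sequence repetitions must satisfy r_reps >= 2",
    "chi": "phase-constraint fraction must satisfy 0 < chi <= 1",
    "j_ia": "starting IA iterations must satisfy j_ia > 0",
    "beta": "feedback parameter must satisfy 0 < beta <= 1",
    "j_er": "starting ER iterations must satisfy j_er > 0",
    "j_eval": "evaluation ER iterations must satisfy j_eval > 0",
    "eta": "upper-bound width must satisfy eta >= 0",
    "sigma_init": "initial support edge must satisfy sigma_init >= 1",
}


def _fail(field_name: str) -> None:
    raise ConfigError(f"{field_name}: {_BOUNDS_DOC.get(field_name, 'out of range')}")


def validate_config(raw: Mapping[str, Any]) -> MPRConfig:
    """Validate a key/value mapping and fill in the documented defaults.

    Unknown keys are rejected so typos do not silently fall back to defaults.
    ``sigma_init`` and ``tau`` have no default and must be provided.
    Validation is idempotent: re-validating ``cfg.as_dict()`` reproduces the
    same configuration.
    """
    raw = dict(raw)
    known_fields = {f.name for f in dataclasses.fields(MPRConfig)}
    unknown = set(raw) - known_fields
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    for required in ("sigma_init", "tau"):
        if raw.get(required) is None:
            raise ConfigError(f"{required} has no default and must be provided")

    cfg = MPRConfig(**raw)

    cfg.sigma_init = int(cfg.sigma_init)
    if cfg.sigma_init < 1:
        _fail("sigma_init")
    if cfg.d_init is None:
        cfg.d_init = (0.2 * cfg.sigma_init, 0.9 * cfg.sigma_init)
    cfg.d_init = (float(cfg.d_init[0]), float(cfg.d_init[1]))
    cfg.phi_init = (float(cfg.phi_init[0]), float(cfg.phi_init[1]))
    if cfg.tau_end is None:
        cfg.tau_end = 2.0 * cfg.tau / 3.0

    if cfg.p < 4:
        _fail("p")
    if cfg.g <= 1:
        _fail("g")
    if cfg.n_init < 1:
        _fail("n_init")
    if not cfg.gamma_init > 0:
        _fail("gamma_init")
    if not (0 < cfg.c_p <= 1):
        _fail("c_p")
    if not (0 <= cfg.c_w <= 2):
        _fail("c_w")
    if not (0 <= cfg.c_a <= 1):
        _fail("c_a")
    if not (0 < cfg.tau <= 1):
        _fail("tau")
    if not (0 < cfg.tau_end <= 1):
        _fail("tau_end")
    if cfg.sigma < 0:
        _fail("sigma")
    if cfg.sigma_end < 0:
        _fail("sigma_end")
    if cfg.r_reps < 2:
        _fail("r_reps")
    if not (0 < cfg.chi <= 1):
        _fail("chi")
    if cfg.j_ia <= 0:
        _fail("j_ia")
    if not (0 < cfg.beta <= 1):
        _fail("beta")
    if cfg.j_er <= 0:
        _fail("j_er")
    if cfg.j_eval <= 0:
        _fail("j_eval")
    if cfg.eta < 0:
        _fail("eta")

    lo, hi = cfg.d_init
    if not (0 < lo <= hi <= cfg.sigma_init):
        raise ConfigError(
            "d_init: sphere diameter range must satisfy 0 < lo <= hi <= sigma_init"
        )
    plo, phi_hi = cfg.phi_init
    if not (-math.pi <= plo <= phi_hi <= math.pi):
        raise ConfigError("phi_init: phase range must be within [-pi, pi]")
    if cfg.ia_kind not in ("HIO", "RAAR"):
        raise ConfigError("ia_kind: must be 'HIO' or 'RAAR'")
    if cfg.mode not in ("MPR", "IPR"):
        raise ConfigError("mode: must be 'MPR' or 'IPR'")
    if not (0 <= cfg.unknown_ring_fraction_max <= 1):
        raise ConfigError("unknown_ring_fraction_max: must lie in [0, 1]")
    if not (0 <= cfg.saturated_ring_fraction_max <= 1):
        raise ConfigError("saturated_ring_fraction_max: must lie in [0, 1]")
    if cfg.t_min < 1:
        raise ConfigError("t_min: must satisfy t_min >= 1")
    if cfg.t_max is not None and cfg.t_min > cfg.t_max:
        raise ConfigError("t_min: must satisfy t_min <= t_max")
    if cfg.n_p is not None:
        cfg.n_p = int(cfg.n_p)
        if cfg.sigma_init > cfg.n_p:
            raise ConfigError("sigma_init: must not exceed the matrix size n_p")
        if cfg.t_max is not None and cfg.t_max >= cfg.n_p:
            raise ConfigError("t_max: must satisfy t_max < n_p")
    return cfg


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_DATASETS = ("intensities", "known_mask", "saturation_mask")


def load_diffraction(path: str | Path, dialect: str | None = None) -> DiffractionData:
    """Read a diffraction pattern from an HDF5 or NPZ file.

    ``dialect`` may be ``"HDF5"`` or ``"NPZ"``; if omitted it is inferred from
    the file suffix.  ``saturation_mask`` is optional and defaults to
    all-false.
    """
    path = Path(path)
    if dialect is None:
        dialect = "NPZ" if path.suffix.lower() == ".npz" else "HDF5"
    dialect = dialect.upper()
    if dialect == "NPZ":
        with np.load(path) as f:
            data = {k: f[k] for k in f.files}
    elif dialect == "HDF5":
        with h5py.File(path, "r") as f:
            data = {k: f[k][()] for k in f.keys()}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for name in ("intensities", "known_mask"):
        if name not in data:
            raise FormatError(f"missing dataset {name!r} in {path}")
    return DiffractionData.from_arrays(
        data["intensities"], data["known_mask"], data.get("saturation_mask")
    )


def save_diffraction(
    path: str | Path,
    data: DiffractionData,
    dialect: str | None = None,
    ground_truth: np.ndarray | None = None,
) -> None:
    """Write a diffraction pattern (HDF5 or NPZ, same keys in both)."""
    path = Path(path)
    if dialect is None:
        dialect = "NPZ" if path.suffix.lower() == ".npz" else "HDF5"
    dialect = dialect.upper()
    arrays: dict[str, np.ndarray] = {
        "intensities": data.intensities,
        "known_mask": data.known_mask,
        "saturation_mask": data.saturation_mask,
    }
    if ground_truth is not None:
        arrays["ground_truth"] = np.asarray(ground_truth, dtype=complex)
    if dialect == "NPZ":
        np.savez(path, **arrays)
    elif dialect == "HDF5":
        with h5py.File(path, "w") as f:
            for k, v in arrays.items():
                f.create_dataset(k, data=v)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def bin_pattern(data: DiffractionData, factor: int) -> DiffractionData:
    """Rebin a pattern by an integer factor, conserving photons.

    Each output pixel sums its ``factor x factor`` constituents.  An output
    pixel is known only if *every* constituent is known (measured and
    unmeasured photons are never mixed) and saturated if *any* constituent is.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("binning factor must be a positive integer")
    if factor == 1:
        return data
    n = data.n_p
    if n % factor:
        raise ValueError(f"binning factor {factor} does not divide N_p={n}")
    m = n // factor

    def blocks(a: np.ndarray) -> np.ndarray:
        return a.reshape(m, factor, m, factor)

    intens = blocks(data.intensities).sum(axis=(1, 3))
    known = blocks(data.known_mask).all(axis=(1, 3))
    sat = blocks(data.saturation_mask).any(axis=(1, 3))
    known &= ~sat
    return DiffractionData(intensities=intens, known_mask=known, saturation_mask=sat)


def save_result(
    path: str | Path,
    reconstruction: Reconstruction,
    metrics: Sequence[GenerationMetrics],
    config: MPRConfig | None = None,
) -> None:
    """Write the final reconstruction, the metrics trace and the config.

    The HDF5 file holds the complex density, the boolean support, the scalar
    error and a compound per-generation metrics table; the full configuration
    is stored as a JSON attribute.  A JSONL sidecar (``<path>.metrics.jsonl``)
    duplicates the metrics for quick plotting.
    """
    path = Path(path)
    records = [m.as_record() for m in metrics]
    with h5py.File(path, "w") as f:
        f.create_dataset("density", data=reconstruction.density)
        f.create_dataset("support", data=reconstruction.support)
        f.create_dataset("error", data=float(reconstruction.error))
        if records:
            names = list(records[0].keys())
            dtype = np.dtype([(k, "i8" if k == "g" else "f8") for k in names])
            table = np.array(
                [tuple(r[k] for k in names) for r in records], dtype=dtype
            )
            f.create_dataset("metrics", data=table)
        if config is not None:
            f.attrs["config_json"] = json.dumps(config.as_dict())
    sidecar = path.with_suffix(path.suffix + ".metrics.jsonl")
    with open(sidecar, "w") as fh:
        for r in records:
            fh.write(json.dumps(r) + "\n")


def load_result(
    path: str | Path,
) -> tuple[Reconstruction, list[GenerationMetrics], MPRConfig | None]:
    """Read back a result file written by :func:`save_result`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        recon = Reconstruction(
            density=f["density"][()],
            support=f["support"][()],
            error=float(f["error"][()]),
        )
        metrics: list[GenerationMetrics] = []
        if "metrics" in f:
            for row in f["metrics"][()]:
                metrics.append(
                    GenerationMetrics(
                        g=int(row["g"]),
                        e_best=float(row["e_best"]),
                        e_mean=float(row["e_mean"]),
                        e_worst=float(row["e_worst"]),
                        e_avg_recon=float(row["e_avg"]),
                        o_d_best=float(row["o_d"]),
                        replacement_pct=float(row["replacement_pct"]),
                        density_sum_mean=float(row["sum_mean"]),
                        density_sum_rel_std=float(row["sum_rel_std"]),
                        gamma_mean=float(row["gamma_mean"]),
                        gamma_avg_recon=float(row["gamma_avg"]),
                    )
                )
        config = None
        if "config_json" in f.attrs:
            rawcfg = json.loads(f.attrs["config_json"])
            config = validate_config(rawcfg)
    return recon, metrics, config
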