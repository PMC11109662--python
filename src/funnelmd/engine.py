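"""Langevin toy dynamics with well-tempered metadynamics and RAMD egress.

This is the desk-scale stand-in for solvated-protein MD: a single particle
integrated with the BAOAB Langevin splitting on an analytic potential,
optionally confined by a funnel restraint, with history-dependent Gaussian
bias deposited along one or two collective variables.  Well-tempered
deposition scales each new hill by ``exp(-V(s)/((gamma-1) kB T))`` so the
bias converges to ``-(1 - 1/gamma) F(s)`` and the free-energy surface can
be recovered by the ``gamma/(gamma-1)`` rescaling in :mod:`funnelmd.fes`.

The random-accelerated-MD (RAMD) rule is also implemented here: a constant
artificial force acts on the particle; at every checkpoint the force
direction is kept if the center of mass moved further than a threshold
since the last checkpoint and is re-drawn uniformly on the unit sphere
otherwise (equality re-draws: the criterion is a strict "exceeds").

During a biased run the bias is evaluated from a grid cache that is
refreshed at every deposition; the cache agrees with the exact hill
summation to better than 0.01 kJ/mol at the default resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .funnel import FunnelGeometry, wall_force
from .units import ANGSTROM_PER_NM, FS_PER_PS, KB, KJ_PER_KCAL

__all__ = [
    "ToySystem",
    "MetaDParams",
    "Hill",
    "HillsLog",
    "RamdState",
    "MetadResult",
    "RamdResult",
    "IntegrationError",
    "wt_height",
    "bias_potential",
    "BiasGrid",
    "langevin_metad_run",
    "ramd_update",
    "ramd_egress_run",
    "random_unit_vector",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator encounters a non-finite energy or force."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class ToySystem:
    """A single Langevin particle on an analytic potential.

    ``potential`` must expose ``dim``, ``energy(x) -> float`` and
    ``force(x) -> ndarray`` (see :mod:`funnelmd.synth` for the registered
    presets, each of which documents a stable timestep range).
    """

    potential: object
    mass: float = 40.0          # amu
    friction: float = 5.0       # ps^-1
    temperature: float = 300.0  # K
    timestep: float = 0.004     # ps
    seed: int = 0
    funnel: Optional[FunnelGeometry] = None

    def __post_init__(self) -> None:
        for name in ("mass", "friction", "temperature", "timestep"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def dim(self) -> int:
        return int(self.potential.dim)


@dataclass(frozen=True)
class MetaDParams:
    """Well-tempered deposition schedule.

    Defaults reproduce the funnel-metadynamics protocol used for the
    receptor systems: initial height 1.0 kJ/mol, widths (0.1 nm, 10) for
    (CV1, CV2), a 2 ps deposition period and bias factor 16.
    """

    height0: float = 1.0                       # kJ/mol
    sigma: tuple[float, ...] = (0.1, 10.0)     # per-CV widths
    pace: int = 500                            # steps between depositions
    bias_factor: float = 16.0                  # gamma
    temperature: float = 300.0                 # K

    def __post_init__(self) -> None:
        if not self.height0 > 0:
            raise ValueError("height0 must be positive")
        if not all(s > 0 for s in self.sigma):
            raise ValueError("all sigma must be positive")
        if self.pace < 1:
            raise ValueError("pace must be >= 1")
        if not self.bias_factor > 1:
            raise ValueError("bias_factor must exceed 1")


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian."""

    time: float                  # ps
    center: tuple[float, ...]    # CV-space point
    sigma: tuple[float, ...]     # per-CV widths
    height: float                # kJ/mol (already tempered)
    bias_factor: float           # gamma

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError("hill height must be positive")
        if not all(s > 0 for s in self.sigma):
            raise ValueError("hill sigma must be positive")
        if len(self.center) != len(self.sigma):
            raise ValueError("center and sigma dimensionality differ")


@dataclass
class HillsLog:
    """Time-ordered deposition record of a metadynamics run."""

    hills: list[Hill] = field(default_factory=list)
    cv_names: tuple[str, ...] = ("cv1", "cv2")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [h.time for h in self.hills]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("hill times must be strictly increasing")
        ncv = {len(h.center) for h in self.hills}
        if len(ncv) > 1:
            raise ValueError("hills mix CV dimensionalities")
        gammas = {h.bias_factor for h in self.hills}
        if len(gammas) > 1:
            raise ValueError("bias factor must be constant across the log")

    def __len__(self) -> int:
        return len(self.hills)

    @property
    def n_cv(self) -> int:
        if self.hills:
            return len(self.hills[0].center)
        return len(self.cv_names)

    @property
    def bias_factor(self) -> float:
        if self.hills:
            return self.hills[0].bias_factor
        return float(self.metadata.get("bias_factor", float("nan")))

    @property
    def times(self) -> np.ndarray:
        return np.array([h.time for h in self.hills])


@dataclass(frozen=True)
class RamdState:
    """RAMD bookkeeping, kept in the method's conventional units.

    Defaults are the production values: 16 kcal mol^-1 Å^-1 force, 100 fs
    checkpoint interval and a 0.025 Å displacement threshold.
    """

    force_magnitude: float = 16.0        # kcal mol^-1 Å^-1
    direction: np.ndarray = None         # unit 3-vector
    checkpoint_interval: float = 100.0   # fs
    threshold: float = 0.025             # Å
    last_com: np.ndarray = None          # Å

    def __post_init__(self) -> None:
        if self.direction is None:
            object.__setattr__(self, "direction", np.array([0.0, 0.0, 1.0]))
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))
        if self.last_com is None:
            object.__setattr__(self, "last_com", np.zeros(3))
        object.__setattr__(self, "last_com", np.asarray(self.last_com, dtype=float))
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        for name in ("force_magnitude", "checkpoint_interval", "threshold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MetadResult:
    trajectory: np.ndarray   # (n_records, dim) positions, nm
    times: np.ndarray        # (n_records,) ps
    cv_series: np.ndarray    # (n_records, n_cv)
    hills: HillsLog
    final_position: np.ndarray


@dataclass
class RamdResult:
    egressed: bool
    exit_position: Optional[np.ndarray]
    trajectory: np.ndarray
    times: np.ndarray
    state: RamdState
    n_steps: int


# --------------------------------------------------------------------------
# well-tempered bias machinery
# --------------------------------------------------------------------------

def wt_height(current_bias: float, p: MetaDParams) -> float:
    """Tempered Gaussian height ``height0 * exp(-V / ((gamma-1) kB T))``.

    Equals ``height0`` at zero accumulated bias and decreases strictly with
    the bias already present at the deposition point.
    """
    return p.height0 * math.exp(-current_bias / ((p.bias_factor - 1.0)
                                                 * KB * p.temperature))


def bias_potential(hills, s) -> float:
    """Exact metadynamics bias: sum of Gaussian hills at CV point ``s``.

    ``hills`` may be a :class:`HillsLog` or a plain sequence of
    :class:`Hill`.  Non-negative and additive in hills.
    """
    hill_seq = hills.hills if isinstance(hills, HillsLog) else hills
    s = np.atleast_1d(np.asarray(s, dtype=float))
    total = 0.0
    for h in hill_seq:
        c = np.asarray(h.center)
        if c.shape != s.shape:
            raise ValueError(
                f"CV point of dimension {s.shape[0]} does not match hill "
                f"of dimension {c.shape[0]}")
        z = (s - c) / np.asarray(h.sigma)
        total += h.height * math.exp(-0.5 * float(np.dot(z, z)))
    return total


class BiasGrid:
    """Accumulated bias on a regular CV grid with analytic gradients.

    Hills are painted onto the grid as they are deposited; values and
    gradients between nodes come from multilinear interpolation.  At the
    default resolution (node spacing <= sigma/8) the interpolation error
    stays below 0.01 kJ/mol relative to the exact summation.
    """

    def __init__(self, axes: Sequence[np.ndarray]):
        self.axes = [np.asarray(a, dtype=float) for a in axes]
        if not 1 <= len(self.axes) <= 2:
            raise ValueError("BiasGrid supports 1 or 2 CVs")
        for a in self.axes:
            if a.ndim != 1 or len(a) < 2 or np.any(np.diff(a) <= 0):
                raise ValueError("grid axes must be strictly increasing 1-D arrays")
        self.x0 = [float(a[0]) for a in self.axes]
        self.dx = [float(a[1] - a[0]) for a in self.axes]
        shape = tuple(len(a) for a in self.axes)
        self.values = np.zeros(shape)
        self.grads = [np.zeros(shape) for _ in self.axes]

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def add_hill(self, center, sigma, height: float) -> None:
        zs = [(a - c) / s for a, c, s in zip(self.axes, center, sigma)]
        gaussians = [np.exp(-0.5 * z * z) for z in zs]
        if self.ndim == 1:
            g = height * gaussians[0]
            self.values += g
            self.grads[0] += g * (-zs[0] / sigma[0])
        else:
            g = height * np.outer(gaussians[0], gaussians[1])
            self.values += g
            self.grads[0] += g * (-zs[0] / sigma[0])[:, None]
            self.grads[1] += g * (-zs[1] / sigma[1])[None, :]

    def _locate(self, s):
        out = []
        for d, x in enumerate(s):
            f = (x - self.x0[d]) / self.dx[d]
            i = int(f)
            n = self.values.shape[d]
            if i < 0:
                i, w = 0, 0.0
            elif i >= n - 1:
                i, w = n - 2, 1.0
            else:
                w = f - i
            out.append((i, w))
        return out

    def _interp(self, arr, loc):
        if self.ndim == 1:
            (i, w), = loc
            return (1.0 - w) * arr[i] + w * arr[i + 1]
        (i, u), (j, v) = loc
        return ((1 - u) * (1 - v) * arr[i, j] + u * (1 - v) * arr[i + 1, j]
                + (1 - u) * v * arr[i, j + 1] + u * v * arr[i + 1, j + 1])

    def value(self, s) -> float:
        return float(self._interp(self.values, self._locate(s)))

    def gradient(self, s) -> np.ndarray:
        loc = self._locate(s)
        return np.array([float(self._interp(g, loc)) for g in self.grads])


# --------------------------------------------------------------------------
# identity / axial CV maps for toy systems
# --------------------------------------------------------------------------

class PositionCV:
    """CV = selected Cartesian components of the particle position."""

    def __init__(self, components: Sequence[int] = (0,), dim: int = 1):
        self.components = tuple(components)
        self.dim = dim
        self.n_cv = len(self.components)

    def value(self, x) -> np.ndarray:
        return np.asarray(x, dtype=float)[list(self.components)]

    def jacobian(self, x) -> np.ndarray:
        jac = np.zeros((self.n_cv, self.dim))
        for row, c in enumerate(self.components):
            jac[row, c] = 1.0
        return jac


class AxialCV:
    """CV = projection of the position onto a funnel axis (plus optional
    smooth auxiliary coordinates registered by a preset)."""

    def __init__(self, origin, axis, extra: Optional[Callable] = None,
                 extra_jac: Optional[Callable] = None, dim: int = 3):
        self.origin = np.asarray(origin, dtype=float)
        self.axis = np.asarray(axis, dtype=float)
        self.extra = extra
        self.extra_jac = extra_jac
        self.dim = dim
        self.n_cv = 1 if extra is None else 2

    def value(self, x) -> np.ndarray:
        z = float(np.dot(np.asarray(x) - self.origin, self.axis))
        if self.extra is None:
            return np.array([z])
        return np.array([z, float(self.extra(x))])

    def jacobian(self, x) -> np.ndarray:
        if self.extra is None:
            return self.axis[None, :].copy()
        return np.vstack([self.axis, np.asarray(self.extra_jac(x), dtype=float)])


# --------------------------------------------------------------------------
# integrators
# --------------------------------------------------------------------------

def _baoab_coeffs(sys: ToySystem):
    c1 = math.exp(-sys.friction * sys.timestep)
    c2 = math.sqrt(KB * sys.temperature / sys.mass * (1.0 - c1 * c1))
    return c1, c2


def _check_finite(x, f, step: int) -> None:
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(f))):
        raise IntegrationError(f"non-finite position or force at step {step}")


def langevin_metad_run(
    sys: ToySystem,
    p: Optional[MetaDParams],
    cv_map,
    n_steps: int,
    x0,
    cv_grid: Optional[Sequence[np.ndarray]] = None,
    record_stride: int = 20,
    v0=None,
) -> MetadResult:
    """Integrate BAOAB Langevin dynamics with well-tempered deposition.

    A hill is deposited every ``p.pace`` steps at the instantaneous CV
    point with the tempered height evaluated from the current bias; the
    funnel wall of ``sys.funnel`` (if any) is always active.  Pass
    ``p=None`` for plain unbiased dynamics.  Identical ``(seed, config)``
    give bit-identical output.

    ``cv_grid`` (one strictly increasing array per CV) bounds the bias
    cache; it must span the region the walker can reach along the CVs.
    """
    rng = np.random.default_rng(sys.seed)
    dim = sys.dim
    x = np.array(x0, dtype=float).reshape(dim)
    v = (np.zeros(dim) if v0 is None
         else np.array(v0, dtype=float).reshape(dim))
    dt = sys.timestep
    half_dt = 0.5 * dt
    inv_m = 1.0 / sys.mass
    c1, c2 = _baoab_coeffs(sys)
    pot = sys.potential
    geom = sys.funnel

    biased = p is not None
    if biased:
        if cv_grid is None:
            raise ValueError("cv_grid is required for a biased run")
        if len(cv_grid) != cv_map.n_cv or len(p.sigma) != cv_map.n_cv:
            raise ValueError("cv_grid / sigma dimensionality does not match cv_map")
        cache = BiasGrid(cv_grid)
    hills: list[Hill] = []

    def total_force(pos):
        f = pot.force(pos)
        if geom is not None:
            f = f + wall_force(pos, geom)
        if biased and hills:
            s = cv_map.value(pos)
            dvds = cache.gradient(s)
            f = f - cv_map.jacobian(pos).T @ dvds
        return f

    n_rec = n_steps // record_stride + 1
    traj = np.empty((n_rec, dim))
    times = np.empty(n_rec)
    cvs = np.empty((n_rec, cv_map.n_cv))
    rec = 0

    def record(step):
        nonlocal rec
        traj[rec] = x
        times[rec] = step * dt
        cvs[rec] = cv_map.value(x)
        rec += 1

    f = total_force(x)
    _check_finite(x, f, 0)
    record(0)

    noise = rng.standard_normal((min(n_steps, 20000), dim))
    noise_i = 0
    for step in range(1, n_steps + 1):
        if noise_i >= noise.shape[0]:
            noise = rng.standard_normal((min(n_steps - step + 1, 20000), dim))
            noise_i = 0
        v += half_dt * inv_m * f
        x += half_dt * v
        v = c1 * v + c2 * noise[noise_i]
        noise_i += 1
        x += half_dt * v
        f = total_force(x)
        v += half_dt * inv_m * f

        if biased and step % p.pace == 0:
            s = cv_map.value(x)
            h = wt_height(cache.value(s), p)
            hill = Hill(time=step * dt, center=tuple(float(si) for si in s),
                        sigma=tuple(p.sigma), height=h,
                        bias_factor=p.bias_factor)
            hills.append(hill)
            cache.add_hill(hill.center, hill.sigma, hill.height)
            _check_finite(x, f, step)
        if step % record_stride == 0:
            record(step)
            _check_finite(x, f, step)

    log = HillsLog(
        hills=hills,
        cv_names=tuple(f"cv{i+1}" for i in range(cv_map.n_cv)),
        metadata={
            "bias_factor": p.bias_factor if biased else float("nan"),
            "temperature": sys.temperature,
            "seed": sys.seed,
        },
    )
    return MetadResult(trajectory=traj[:rec], times=times[:rec],
                       cv_series=cvs[:rec], hills=log, final_position=x.copy())


# --------------------------------------------------------------------------
# RAMD
# --------------------------------------------------------------------------

def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Uniform direction on the unit sphere via a normalized Gaussian triple."""
    while True:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def ramd_update(state: RamdState, new_com, rng: np.random.Generator) -> RamdState:
    """Checkpoint rule: keep the force direction only if the COM moved
    strictly further than the threshold since the last checkpoint
    (displacement and threshold in Å); otherwise re-draw it uniformly.
    ``last_com`` is updated either way.
    """
    new_com = np.asarray(new_com, dtype=float)
    displacement = float(np.linalg.norm(new_com - state.last_com))
    if displacement > state.threshold:
        direction = state.direction
    else:
        direction = random_unit_vector(rng)
    return replace(state, direction=direction, last_com=new_com)


def ramd_egress_run(
    sys: ToySystem,
    state: RamdState,
    exit_test: Callable[[np.ndarray], bool],
    max_steps: int,
    x0,
    record_stride: int = 50,
) -> RamdResult:
    """Langevin dynamics plus the randomly re-oriented constant RAMD force.

    The artificial force (kcal mol^-1 Å^-1, converted internally to
    kJ mol^-1 nm^-1) acts along ``state.direction``; the checkpoint rule is
    applied every ``checkpoint_interval`` (fs).  Terminates as soon as
    ``exit_test(position)`` is true or after ``max_steps``.
    Seed-reproducible through ``sys.seed``.
    """
    if sys.dim != 3:
        raise ValueError("RAMD runs require a 3-D toy system")
    rng = np.random.default_rng(sys.seed)
    x = np.array(x0, dtype=float).reshape(3)
    v = np.zeros(3)
    dt = sys.timestep
    half_dt = 0.5 * dt
    inv_m = 1.0 / sys.mass
    c1, c2 = _baoab_coeffs(sys)
    geom = sys.funnel
    f_mag = state.force_magnitude * KJ_PER_KCAL * ANGSTROM_PER_NM  # kJ/mol/nm
    check_every = max(1, round(state.checkpoint_interval / FS_PER_PS / dt))
    state = replace(state, last_com=x * ANGSTROM_PER_NM)

    def total_force(pos, direction):
        f = sys.potential.force(pos) + f_mag * direction
        if geom is not None:
            f = f + wall_force(pos, geom)
        return f

    recs = [x.copy()]
    rec_times = [0.0]
    f = total_force(x, state.direction)
    _check_finite(x, f, 0)
    egressed = False
    step = 0
    for step in range(1, max_steps + 1):
        v += half_dt * inv_m * f
        x += half_dt * v
        v = c1 * v + c2 * rng.standard_normal(3)
        x += half_dt * v
        f = total_force(x, state.direction)
        v += half_dt * inv_m * f

        if step % check_every == 0:
            state = ramd_update(state, x * ANGSTROM_PER_NM, rng)
            f = total_force(x, state.direction)
            _check_finite(x, f, step)
        if step % record_stride == 0:
            recs.append(x.copy())
            rec_times.append(step * dt)
        if exit_test(x):
            egressed = True
            break

    if recs[-1] is not x and (not recs or not np.array_equal(recs[-1], x)):
        recs.append(x.copy())
        rec_times.append(step * dt)
    return RamdResult(
        egressed=egressed,
        exit_position=x.copy() if egressed else None,
        trajectory=np.array(recs),
        times=np.array(rec_times),
        state=state,
        n_steps=step,
    )
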