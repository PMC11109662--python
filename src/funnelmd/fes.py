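"""Free-energy surfaces from hill logs; basins, saddles, convergence, ΔG/Kd.

Well-tempered metadynamics converges to a bias ``V(s) = -(1 - 1/gamma) F(s)``
(up to a constant), so the surface is recovered as
``F(s) = -(gamma/(gamma-1)) V(s)``, shifted so its minimum is zero.

The absolute binding free energy follows the funnel correction: with the
unbound ligand confined to a cylinder of radius ``r_cyl``, the binding
constant is the 1-D integral of the axial potential of mean force ``W(z)``
over the bound region times the cylinder cross-section,

.. math:: K_b = \\pi r_\\mathrm{cyl}^2 \\int_\\mathrm{bound}
          e^{-\\beta (W(z) - W_\\mathrm{unbound})} \\, dz ,

and ``ΔG0 = -kB T ln(Kb C° N_A)`` with the standard concentration C°
(default 1 M) expressed in molecules/nm^3.  ``Kd = C° exp(ΔG0 / RT)``.

Basins and transition states are found on the grid by a watershed flood:
cells are visited in order of increasing free energy and merged by
union-find; the level at which two catchments meet is the minimax (saddle)
value between their minima, and the depth of a basin below its lowest
surrounding saddle is its persistence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .engine import HillsLog
from .funnel import FunnelGeometry
from .units import KB, KJ_PER_KCAL, MOLAR_PER_NM3, kT

__all__ = [
    "FreeEnergySurface",
    "Basin",
    "BindingEstimate",
    "reconstruct_fes",
    "project_to_axis",
    "basin_free_energy_difference",
    "find_basins",
    "saddle_estimate",
    "binding_delta_g",
    "convergence_profile",
    "block_errors",
]


@dataclass
class FreeEnergySurface:
    """Gridded free energy ``W`` over one or two CVs (kJ/mol)."""

    axes: list                 # per-dimension strictly increasing grids
    values: np.ndarray         # kJ/mol
    reference: str = "minimum"  # zeroing convention: "minimum" | "unbound"
    temperature: float = 300.0
    bias_factor: float = float("nan")
    axis_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.axes = [np.asarray(a, dtype=float) for a in self.axes]
        self.values = np.asarray(self.values, dtype=float)
        for a in self.axes:
            if np.any(np.diff(a) <= 0):
                raise ValueError("grid axes must be strictly increasing")
        if self.values.shape != tuple(len(a) for a in self.axes):
            raise ValueError("values shape does not match axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("free-energy values must be finite")
        if not self.axis_names:
            self.axis_names = tuple(f"cv{i+1}" for i in range(len(self.axes)))

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def point(self, index) -> tuple[float, ...]:
        """CV-space coordinates of a grid index."""
        index = np.atleast_1d(np.asarray(index, dtype=int))
        return tuple(float(a[i]) for a, i in zip(self.axes, index))

    def nearest_index(self, point) -> tuple[int, ...]:
        point = np.atleast_1d(np.asarray(point, dtype=float))
        return tuple(int(np.argmin(np.abs(a - x)))
                     for a, x in zip(self.axes, point))


@dataclass
class Basin:
    """A labeled local free-energy minimum with its catchment extent."""

    label: str
    location: tuple[float, ...]     # CV-space coordinates of the minimum
    depth: float                    # kJ/mol below the lowest surrounding saddle
    extent: np.ndarray              # (ndim, 2) CV-space bounding box at the iso-level
    value: float = 0.0              # F at the minimum (surface reference)
    grid_index: tuple[int, ...] = ()
    bound: Optional[bool] = None    # bound/unbound flag from a CV1 threshold

    def __post_init__(self) -> None:
        self.extent = np.asarray(self.extent, dtype=float)
        if self.depth < 0:
            raise ValueError("basin depth must be non-negative")
        for x, (lo, hi) in zip(self.location, self.extent):
            if not lo <= x <= hi:
                raise ValueError("basin location must lie inside its extent")

    def contains(self, point) -> bool:
        point = np.atleast_1d(np.asarray(point, dtype=float))
        return bool(np.all((point >= self.extent[:, 0])
                           & (point <= self.extent[:, 1])))


@dataclass
class BindingEstimate:
    """Standard-state binding free energy and dissociation constant."""

    delta_g: float                 # kcal/mol
    kd: float                      # nM
    uncertainty: float = 0.0       # kcal/mol, standard error on delta_g
    kd_uncertainty: float = 0.0    # nM
    temperature: float = 300.0
    standard_concentration: float = 1.0  # M
    plateau_warning: bool = False
    binding_constant_nm3: float = float("nan")  # pi r^2 * integral, nm^3

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError("kd must be positive")
        implied = self.standard_concentration * 1e9 * math.exp(
            self.delta_g * KJ_PER_KCAL / (KB * self.temperature))
        if abs(implied - self.kd) > 1e-6 * abs(self.kd):
            raise ValueError("kd and delta_g are not mutually consistent under "
                             "kd = C0 * exp(dG / (R T))")


# --------------------------------------------------------------------------
# reconstruction
# --------------------------------------------------------------------------

def _hill_sum_on_grid(hills: HillsLog, axes: Sequence[np.ndarray]) -> np.ndarray:
    axes = [np.asarray(a, dtype=float) for a in axes]
    shape = tuple(len(a) for a in axes)
    v = np.zeros(shape)
    for h in hills.hills:
        gs = [np.exp(-0.5 * ((a - c) / s) ** 2)
              for a, c, s in zip(axes, h.center, h.sigma)]
        if len(axes) == 1:
            v += h.height * gs[0]
        else:
            v += h.height * np.outer(gs[0], gs[1])
    return v


def reconstruct_fes(hills: HillsLog, grid: Sequence[np.ndarray],
                    gamma: Optional[float] = None,
                    temperature: Optional[float] = None,
                    time_average: float = 0.0,
                    n_average: int = 20) -> FreeEnergySurface:
    """Recover the free-energy surface from deposited hills.

    ``F(s) = -(gamma/(gamma-1)) * V_hills(s)`` shifted so min(F) = 0; in
    the ``gamma -> inf`` limit this reduces to ``-V_hills``.  ``gamma``
    defaults to the bias factor recorded in the log.

    With ``time_average`` in (0, 1), the estimate is the mean of
    ``n_average`` aligned reconstructions spread over the final
    ``time_average`` fraction of the run.  The converged well-tempered
    bias still carries a slowly varying residue from the walker's current
    position; averaging over the tail suppresses it (the standard
    time-averaged estimator) without biasing the converged profile.
    """
    if len(hills) == 0:
        raise ValueError("cannot reconstruct a surface from an empty hills log")
    if gamma is None:
        gamma = hills.bias_factor
    if not math.isfinite(gamma) or gamma <= 1:
        raise ValueError("a finite bias factor > 1 is required (pass gamma=...)")
    if temperature is None:
        temperature = float(hills.metadata.get("temperature", 300.0))
    axes = [np.asarray(a, dtype=float) for a in grid]
    if len(axes) != hills.n_cv:
        raise ValueError("grid dimensionality does not match the hills")
    centers = np.array([h.center for h in hills.hills])
    for d, a in enumerate(axes):
        if centers[:, d].min() < a[0] or centers[:, d].max() > a[-1]:
            raise ValueError("grid does not span the hill centers")
    scale = -(gamma / (gamma - 1.0))

    if not 0.0 <= time_average < 1.0:
        raise ValueError("time_average must lie in [0, 1)")
    if time_average == 0.0:
        f = scale * _hill_sum_on_grid(hills, axes)
        f -= f.min()
    else:
        times = hills.times
        t0 = times[-1] * (1.0 - time_average)
        checkpoints = np.linspace(max(t0, times[0]), times[-1], n_average)
        # incremental summation: walk the checkpoints once
        v = np.zeros(tuple(len(a) for a in axes))
        acc = np.zeros_like(v)
        used = 0
        idx = 0
        for t in checkpoints:
            while idx < len(hills) and times[idx] <= t:
                h = hills.hills[idx]
                gs = [np.exp(-0.5 * ((a - c) / s) ** 2)
                      for a, c, s in zip(axes, h.center, h.sigma)]
                v += h.height * (gs[0] if len(axes) == 1
                                 else np.outer(gs[0], gs[1]))
                idx += 1
            fi = scale * v
            acc += fi - fi.min()
            used += 1
        f = acc / used
        f -= f.min()
    return FreeEnergySurface(axes=list(axes), values=f, reference="minimum",
                             temperature=temperature, bias_factor=float(gamma),
                             axis_names=tuple(hills.cv_names))


def project_to_axis(fes: FreeEnergySurface, axis: int = 0) -> FreeEnergySurface:
    """Marginalize a 2-D surface onto one CV by ``-kT ln sum exp(-F/kT)``.

    Used to project the (CV1, CV2) surface onto the axial (COM-distance)
    coordinate before applying the funnel correction.
    """
    if fes.ndim != 2:
        raise ValueError("projection requires a 2-D surface")
    beta = 1.0 / kT(fes.temperature)
    other = 1 - axis
    w = np.gradient(fes.axes[other])
    vals = fes.values if axis == 0 else fes.values.T
    # logsumexp along the marginalized CV, weighted by the grid measure
    a = -beta * vals
    amax = a.max(axis=1, keepdims=True)
    z = np.sum(np.exp(a - amax) * w[None, :], axis=1)
    f = -(amax[:, 0] + np.log(z)) / beta
    f -= f.min()
    return FreeEnergySurface(axes=[fes.axes[axis]], values=f,
                             reference="minimum", temperature=fes.temperature,
                             bias_factor=fes.bias_factor,
                             axis_names=(fes.axis_names[axis],))


def basin_free_energy_difference(fes: FreeEnergySurface, split: float) -> float:
    """Free-energy difference F(right) - F(left) of a 1-D surface split at
    ``split``: ``kT ln(Z_left / Z_right)`` with Z the Boltzmann integrals
    of ``exp(-F/kT)`` over each side (kJ/mol)."""
    if fes.ndim != 1:
        raise ValueError("basin free-energy difference is defined on 1-D surfaces")
    x = fes.axes[0]
    beta = 1.0 / kT(fes.temperature)
    w = np.exp(-beta * (fes.values - fes.values.min()))
    left = np.trapezoid(np.where(x < split, w, 0.0), x)
    right = np.trapezoid(np.where(x >= split, w, 0.0), x)
    if left <= 0 or right <= 0:
        raise ValueError("split leaves an empty side")
    return float(math.log(left / right) / beta)


# --------------------------------------------------------------------------
# basins and saddles (watershed / persistence flood)
# --------------------------------------------------------------------------

def _neighbors(index, shape):
    if len(shape) == 1:
        (i,), (n,) = index, shape
        for d in (-1, 1):
            if 0 <= i + d < n:
                yield (i + d,)
    else:
        (i, j), (n, m) = index, shape
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < n and 0 <= b < m:
                    yield (a, b)


class _Flood:
    """Union-find watershed over grid cells in order of increasing value."""

    def __init__(self, values: np.ndarray):
        self.values = values
        self.shape = values.shape
        self.parent: dict = {}
        self.comp_min: dict = {}     # root -> (value, index) of its minimum
        self.merges: list = []       # (level, saddle_index, kept_root, absorbed_root)

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def run(self):
        order = np.argsort(self.values, axis=None, kind="stable")
        flat_indices = np.unravel_index(order, self.shape)
        cells = list(zip(*[idx.tolist() for idx in flat_indices])) \
            if len(self.shape) > 1 else [(int(i),) for i in order]
        for cell in cells:
            level = float(self.values[cell])
            roots = []
            for nb in _neighbors(cell, self.shape):
                if nb in self.parent:
                    r = self.find(nb)
                    if r not in roots:
                        roots.append(r)
            if not roots:
                self.parent[cell] = cell
                self.comp_min[cell] = (level, cell)
            else:
                roots.sort(key=lambda r: self.comp_min[r])
                keep = roots[0]
                self.parent[cell] = keep
                for other in roots[1:]:
                    self.merges.append((level, cell, keep, other))
                    self.parent[other] = keep
        return self


def find_basins(fes: FreeEnergySurface, depth_min: float = 2.0 * KJ_PER_KCAL,
                cv1_threshold: Optional[float] = None,
                iso_fraction: float = 0.95) -> list[Basin]:
    """Local minima whose depth below the lowest surrounding saddle exceeds
    ``depth_min`` (kJ/mol), sorted deepest-first.

    Minima are grid local minima (8-neighborhood in 2-D); depth is the
    persistence from the watershed flood (the global minimum's depth is
    measured to the surface maximum).  ``extent`` is the bounding box of
    the connected region below ``min + iso_fraction * depth`` around each
    minimum.  If ``cv1_threshold`` is given, basins with CV1 below it are
    flagged bound.
    """
    flood = _Flood(fes.values).run()
    persistence: dict = {root: fes.values.max() - vmin
                         for root, (vmin, _) in flood.comp_min.items()}
    # merges were recorded with the absorbed root losing at `level`
    for level, _, _, absorbed in flood.merges:
        vmin, _ = flood.comp_min[absorbed]
        persistence[absorbed] = min(persistence[absorbed], level - vmin)
    basins = []
    shape = fes.values.shape
    for root, (vmin, min_cell) in flood.comp_min.items():
        depth = persistence[root]
        if depth <= depth_min:
            continue
        # a minimum on the grid boundary is a clipped region, not a basin
        if any(i == 0 or i == n - 1 for i, n in zip(min_cell, shape)):
            continue
        extent = _basin_extent(fes, min_cell, vmin + iso_fraction * depth)
        loc = fes.point(min_cell)
        basins.append(Basin(label="", location=loc, depth=float(depth),
                            extent=extent, value=float(vmin),
                            grid_index=tuple(min_cell)))
    basins.sort(key=lambda b: b.value)
    for i, b in enumerate(basins):
        b.label = f"Minimum {i + 1}"
        if cv1_threshold is not None:
            b.bound = b.location[0] < cv1_threshold
    return basins


def _basin_extent(fes: FreeEnergySurface, seed, level: float) -> np.ndarray:
    """Bounding box of the connected sub-level region containing ``seed``."""
    shape = fes.values.shape
    seen = {tuple(seed)}
    stack = [tuple(seed)]
    while stack:
        cell = stack.pop()
        for nb in _neighbors(cell, shape):
            if nb not in seen and fes.values[nb] <= level:
                seen.add(nb)
                stack.append(nb)
    cells = np.array(sorted(seen))
    extent = []
    for d, a in enumerate(fes.axes):
        lo, hi = cells[:, d].min(), cells[:, d].max()
        extent.append((float(a[lo]), float(a[hi])))
    return np.asarray(extent)


def saddle_estimate(fes: FreeEnergySurface, a: Basin, b: Basin):
    """Transition-state estimate between two basins.

    Returns ``(point, barrier)`` where ``point`` is the CV-space location
    of the minimax saddle on grid paths between the two minima and
    ``barrier = F(saddle) - F(a.location)`` (kJ/mol).  Raises if the
    basins coincide or are not connected on the grid.
    """
    ia, ib = tuple(a.grid_index), tuple(b.grid_index)
    if ia == ib:
        raise ValueError("saddle_estimate requires two distinct basins")
    flood = _Flood(fes.values)
    order = np.argsort(fes.values, axis=None, kind="stable")
    if fes.ndim == 1:
        cells = [(int(i),) for i in order]
    else:
        cells = list(zip(*[idx.tolist()
                           for idx in np.unravel_index(order, fes.values.shape)]))
    for cell in cells:
        roots = []
        for nb in _neighbors(cell, fes.values.shape):
            if nb in flood.parent:
                r = flood.find(nb)
                if r not in roots:
                    roots.append(r)
        if not roots:
            flood.parent[cell] = cell
            flood.comp_min[cell] = (float(fes.values[cell]), cell)
        else:
            keep = min(roots, key=lambda r: flood.comp_min[r])
            flood.parent[cell] = keep
            for other in roots:
                if other != keep:
                    flood.parent[other] = keep
        if ia in flood.parent and ib in flood.parent \
                and flood.find(ia) == flood.find(ib):
            barrier = float(fes.values[cell]) - float(fes.values[ia])
            return fes.point(cell), barrier
    raise ValueError("basins are not connected on the grid")


# --------------------------------------------------------------------------
# binding free energy
# --------------------------------------------------------------------------

def binding_delta_g(
    fes_axial: FreeEnergySurface,
    geom: FunnelGeometry,
    bound_region: tuple[float, float],
    unbound_region: tuple[float, float],
    temperature: Optional[float] = None,
    c0: float = 1.0,
    delta_g_se_kj: float = 0.0,
    plateau_tol: float = 1.0,
) -> BindingEstimate:
    """Funnel-corrected standard-state binding free energy from an axial PMF.

    ``fes_axial`` is a 1-D surface over the axial coordinate z (nm).  The
    unbound region must lie in the cylindrical section (z >= z_cc) where the
    profile is flat; its mean sets the unbound reference.  A plateau whose
    excursion exceeds ``plateau_tol`` (kJ/mol) flags a convergence warning
    on the result rather than raising.
    """
    if fes_axial.ndim != 1:
        raise ValueError("binding_delta_g needs a 1-D axial surface "
                         "(project 2-D surfaces first)")
    if temperature is None:
        temperature = fes_axial.temperature
    z = fes_axial.axes[0]
    w = fes_axial.values
    u_lo, u_hi = unbound_region
    if u_lo < geom.z_cc:
        raise ValueError("unbound region must lie inside the cylinder (z >= z_cc)")
    u_mask = (z >= u_lo) & (z <= u_hi)
    if u_mask.sum() < 2:
        raise ValueError("unbound region contains fewer than 2 grid points")
    w_unbound = float(w[u_mask].mean())
    plateau_warning = bool(np.max(np.abs(w[u_mask] - w_unbound)) > plateau_tol)

    b_lo, b_hi = bound_region
    b_mask = (z >= b_lo) & (z <= b_hi)
    if b_mask.sum() < 2:
        raise ValueError("bound region contains fewer than 2 grid points")
    beta = 1.0 / kT(temperature)
    integrand = np.exp(-beta * (w[b_mask] - w_unbound))
    kb_nm3 = math.pi * geom.r_cyl ** 2 * float(np.trapezoid(integrand, z[b_mask]))

    dg_kj = -kT(temperature) * math.log(kb_nm3 * c0 * MOLAR_PER_NM3)
    dg_kcal = dg_kj / KJ_PER_KCAL
    kd_nm = c0 * 1e9 * math.exp(dg_kj / (KB * temperature))
    se_kcal = delta_g_se_kj / KJ_PER_KCAL
    kd_se = kd_nm * (math.exp(delta_g_se_kj / (KB * temperature)) - 1.0) \
        if delta_g_se_kj else 0.0
    return BindingEstimate(
        delta_g=dg_kcal, kd=kd_nm, uncertainty=se_kcal, kd_uncertainty=kd_se,
        temperature=temperature, standard_concentration=c0,
        plateau_warning=plateau_warning, binding_constant_nm3=kb_nm3,
    )


# --------------------------------------------------------------------------
# convergence and errors
# --------------------------------------------------------------------------

def convergence_profile(hills: HillsLog, window: float,
                        grid: Sequence[np.ndarray],
                        gamma: Optional[float] = None):
    """Maximum FES change between successive time windows.

    For each boundary ``t = 2*window, 3*window, ...`` the surfaces built
    from hills up to ``t`` and up to ``t - window`` are aligned to their
    minima and the max absolute difference is recorded.  A decreasing
    series signals convergence of the sampling.
    Returns ``(boundaries, deltas)`` arrays.
    """
    if len(hills) == 0:
        raise ValueError("empty hills log")
    t_end = hills.hills[-1].time
    if window <= 0 or t_end < 2 * window:
        raise ValueError("need at least two windows: window too large for the run")
    boundaries = np.arange(2 * window, t_end + 1e-9, window)
    deltas = []
    for t in boundaries:
        sub_now = HillsLog([h for h in hills.hills if h.time <= t],
                           cv_names=hills.cv_names, metadata=hills.metadata)
        sub_prev = HillsLog([h for h in hills.hills if h.time <= t - window],
                            cv_names=hills.cv_names, metadata=hills.metadata)
        if len(sub_prev) == 0 or len(sub_now) == 0:
            deltas.append(float("nan"))
            continue
        f_now = reconstruct_fes(sub_now, grid, gamma=gamma)
        f_prev = reconstruct_fes(sub_prev, grid, gamma=gamma)
        deltas.append(float(np.max(np.abs(f_now.values - f_prev.values))))
    return boundaries, np.asarray(deltas)


def block_errors(series, n_blocks: int = 5) -> float:
    """Standard error of the mean from contiguous block averages.

    Robust to autocorrelation at block lengths beyond the correlation
    time; this is how the ± uncertainties on ΔG/Kd are obtained.
    """
    series = np.asarray(series, dtype=float).ravel()
    n = series.size
    if n_blocks < 2 or n_blocks > n:
        raise ValueError("n_blocks must be between 2 and the sample count")
    usable = n - n % n_blocks
    means = series[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(np.std(means, ddof=1) / math.sqrt(n_blocks))
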