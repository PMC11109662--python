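"""Synthetic inputs with machine-readable ground truth.

Everything the pipeline consumes can be generated here without downloads:

* analytic toy potentials whose thermodynamics (basin ΔF, standard-state
  ΔG) are computed by high-accuracy quadrature at construction,
* hill logs consistent with a known free-energy surface (the inverse of
  FES reconstruction), and
* conformational ensembles with planted inter-residue correlation,
  contact, helicity and fluctuation structure.

Every generator is deterministic under a fixed seed and returns its ground
truth as a plain dict so tests consume it directly instead of hand-copied
numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .colvars import StructureModel
from .engine import AxialCV, Hill, HillsLog, MetaDParams, PositionCV, ToySystem
from .ensembles import LabeledEnsemble
from .fes import FreeEnergySurface
from .funnel import FunnelGeometry, funnel_radius
from .units import KJ_PER_KCAL, MOLAR_PER_NM3, kT

__all__ = [
    "ToyPotentialSpec",
    "PlantedEnsembleSpec",
    "make_toy",
    "hills_from_fes",
    "make_ensemble",
    "PRESETS",
    "HELIX_DIHEDRALS",
    "COIL_DIHEDRALS",
]

HELIX_DIHEDRALS = (-57.0, -47.0)   # ideal alpha (phi, psi), degrees
COIL_DIHEDRALS = (-120.0, 120.0)   # extended backbone


# ==========================================================================
# toy potentials
# ==========================================================================

@dataclass(frozen=True)
class ToyPotentialSpec:
    """Named analytic potential plus parameters.

    Presets: ``harmonic``, ``double_well_1d``, ``square_well_axial``,
    ``funnel_trap_3d``, ``two_channel_exit``.  Parameters outside the
    documented stable-integration range raise at construction.
    """

    preset: str
    params: dict = field(default_factory=dict)
    temperature: float = 300.0
    seed: int = 0


class HarmonicPotential:
    """U = k/2 |x|^2.  Stable with the default mass/friction for
    timestep <= 0.01 ps up to k ~ 2000 kJ mol^-1 nm^-2."""

    def __init__(self, k: float = 100.0, dim: int = 1):
        if not 0 < k <= 5000:
            raise ValueError("harmonic k outside the stable range (0, 5000]")
        self.k = k
        self.dim = dim

    def energy(self, x) -> float:
        x = np.asarray(x)
        return 0.5 * self.k * float(np.dot(x, x))

    def force(self, x):
        return -self.k * np.asarray(x, dtype=float)


class DoubleWell1D:
    """Tilted quartic double well: wells near ±x0, barrier at 0.

    ``U(x) = barrier * ((x/x0)^2 - 1)^2 + c x`` with the tilt ``c``
    calibrated at construction (by root finding on the Boltzmann
    quadrature) so that the free-energy difference between the x > 0 and
    x < 0 basins equals ``asymmetry`` exactly at the stated temperature.
    Stable for timestep <= 0.006 ps at barrier <= 50.
    """

    dim = 1

    def __init__(self, barrier: float = 20.0, asymmetry: float = 3.0,
                 x0: float = 0.5, temperature: float = 300.0):
        if not 0 < barrier <= 50:
            raise ValueError("double-well barrier outside the stable range (0, 50]")
        if abs(asymmetry) >= barrier:
            raise ValueError("asymmetry must be smaller than the barrier")
        self.barrier = barrier
        self.x0 = x0
        self.asymmetry = asymmetry
        self.temperature = temperature
        self.tilt = 0.0 if asymmetry == 0 else brentq(
            lambda c: self._delta_f(c) - asymmetry,
            0.0, 4.0 * abs(asymmetry) / x0 + 1.0, xtol=1e-12)

    def _base(self, x):
        return self.barrier * ((x / self.x0) ** 2 - 1.0) ** 2

    def _delta_f(self, tilt: float) -> float:
        x = np.linspace(-2.5 * self.x0, 2.5 * self.x0, 4001)
        u = self._base(x) + tilt * x
        beta = 1.0 / kT(self.temperature)
        w = np.exp(-beta * (u - u.min()))
        z_left = np.trapezoid(np.where(x < 0, w, 0.0), x)
        z_right = np.trapezoid(np.where(x >= 0, w, 0.0), x)
        return math.log(z_left / z_right) / beta

    def energy(self, x) -> float:
        x = float(np.asarray(x).reshape(()))
        return self._base(x) + self.tilt * x

    def force(self, x):
        x = float(np.asarray(x).reshape(()))
        du = self.barrier * 4.0 * ((x / self.x0) ** 2 - 1.0) * x / self.x0 ** 2
        return np.array([-(du + self.tilt)])

    def quadrature_delta_f(self) -> float:
        """Basin ΔF (right minus left, kJ/mol) by direct quadrature."""
        return self._delta_f(self.tilt)


class SquareWellAxial:
    """Ideal square well along the funnel axis: U = -depth on z in [0, L].

    An analysis preset: the discontinuous edges make it unsuitable for
    dynamics (its closed-form ΔG is the oracle for the funnel-corrected
    binding integral), so its ``force`` is defined but identically zero
    away from the edges.
    """

    dim = 3

    def __init__(self, depth: float = 10.0, length: float = 0.5,
                 r_cyl: float = 0.1, z_cc: float = 0.5, alpha: float = 1.1):
        self.depth = depth
        self.length = length
        self.geometry = FunnelGeometry(origin=np.zeros(3),
                                       axis=np.array([0.0, 0.0, 1.0]),
                                       z_cc=z_cc, r_cyl=r_cyl, alpha=alpha)

    def energy(self, x) -> float:
        z = float(np.asarray(x).reshape(3)[2])
        return -self.depth if 0.0 <= z <= self.length else 0.0

    def force(self, x):
        return np.zeros(3)

    def axial_profile(self, z_max: float = 1.5, n: int = 2001):
        z = np.linspace(-0.2, z_max, n)
        w = np.where((z >= 0) & (z <= self.length), -self.depth, 0.0)
        return z, w


class FunnelTrap3D:
    """Gaussian binding well at the funnel origin plus soft axial caps.

    ``U = -depth exp(-|x|^2 / (2 w^2))`` with harmonic caps confining the
    axial coordinate to ``[z_floor, z_cap]`` so a walker cannot wander down
    the cone or up the cylinder forever.  Axisymmetric about the funnel
    axis, so the axial PMF is a 1-D radial quadrature.  Stable for
    timestep <= 0.005 ps at depth <= 40.
    """

    dim = 3

    def __init__(self, depth: float = 20.0, width: float = 0.15,
                 z_floor: float = -0.4, z_cap: float = 1.2,
                 k_cap: float = 2000.0, r_cyl: float = 0.1,
                 z_cc: float = 0.5, alpha: float = 1.1,
                 k_wall: float = 10000.0):
        if not 0 < depth <= 40:
            raise ValueError("funnel-trap depth outside the stable range (0, 40]")
        self.depth = depth
        self.width = width
        self.z_floor = z_floor
        self.z_cap = z_cap
        self.k_cap = k_cap
        self.geometry = FunnelGeometry(origin=np.zeros(3),
                                       axis=np.array([0.0, 0.0, 1.0]),
                                       z_cc=z_cc, r_cyl=r_cyl, alpha=alpha,
                                       k_wall=k_wall)

    def _cap_energy(self, z: float) -> float:
        if z < self.z_floor:
            return 0.5 * self.k_cap * (z - self.z_floor) ** 2
        if z > self.z_cap:
            return 0.5 * self.k_cap * (z - self.z_cap) ** 2
        return 0.0

    def energy(self, x) -> float:
        x = np.asarray(x, dtype=float).reshape(3)
        r2 = float(np.dot(x, x))
        return (-self.depth * math.exp(-r2 / (2.0 * self.width ** 2))
                + self._cap_energy(float(x[2])))

    def force(self, x):
        x = np.asarray(x, dtype=float).reshape(3)
        r2 = float(np.dot(x, x))
        f = -self.depth * math.exp(-r2 / (2.0 * self.width ** 2)) \
            / self.width ** 2 * x
        z = float(x[2])
        if z < self.z_floor:
            f[2] -= self.k_cap * (z - self.z_floor)
        elif z > self.z_cap:
            f[2] -= self.k_cap * (z - self.z_cap)
        return f

    def well_energy_rz(self, rho, z):
        """Potential at cylindrical (rho, z), caps included (vectorized)."""
        rho = np.asarray(rho, dtype=float)
        z = np.asarray(z, dtype=float)
        cap = np.where(z < self.z_floor,
                       0.5 * self.k_cap * (z - self.z_floor) ** 2,
                       np.where(z > self.z_cap,
                                0.5 * self.k_cap * (z - self.z_cap) ** 2, 0.0))
        return -self.depth * np.exp(-(rho ** 2 + z ** 2)
                                    / (2.0 * self.width ** 2)) + cap

    def axial_pmf(self, temperature: float, n_z: int = 601, n_rho: int = 400):
        """W(z) = -kT ln ∫ exp(-βU) 2πρ dρ over the funnel cross-section."""
        beta = 1.0 / kT(temperature)
        z = np.linspace(self.z_floor, self.z_cap, n_z)
        w = np.empty_like(z)
        for i, zi in enumerate(z):
            rmax = funnel_radius(zi, self.geometry)
            rho = np.linspace(0.0, rmax, n_rho)
            integrand = np.exp(-beta * self.well_energy_rz(rho, zi)) \
                * 2.0 * math.pi * rho
            w[i] = -math.log(float(np.trapezoid(integrand, rho))) / beta
        return z, w


class TwoChannelExit:
    """Bounded well surrounded by a barrier ring with two angular gaps.

    A harmonic trap holds the particle near the origin in the xy-plane
    (z is harmonically confined); a Gaussian ring barrier at radius ``r0``
    carries two smooth gaps, a wide one centred at φ = 0 and a narrow one
    at φ = π, so an escaping particle must choose a channel.  Stable for
    timestep <= 0.005 ps at the defaults.
    """

    dim = 3

    def __init__(self, k_trap: float = 20.0, barrier: float = 30.0,
                 r0: float = 0.4, ring_width: float = 0.06,
                 wide_halfwidth: float = 0.6, narrow_halfwidth: float = 0.2,
                 k_z: float = 200.0):
        self.k_trap = k_trap
        self.barrier = barrier
        self.r0 = r0
        self.ring_width = ring_width
        self.wide = wide_halfwidth
        self.narrow = narrow_halfwidth
        self.k_z = k_z

    def _gap(self, phi: float) -> float:
        def wrapped(dphi, hw):
            d = (dphi + math.pi) % (2 * math.pi) - math.pi
            return math.exp(-0.5 * (d / hw) ** 2)
        return 1.0 - wrapped(phi, self.wide) - wrapped(phi - math.pi, self.narrow)

    def energy(self, x) -> float:
        x = np.asarray(x, dtype=float).reshape(3)
        rho = math.hypot(x[0], x[1])
        phi = math.atan2(x[1], x[0])
        ring = self.barrier * max(self._gap(phi), 0.0) \
            * math.exp(-0.5 * ((rho - self.r0) / self.ring_width) ** 2)
        trap = 0.5 * self.k_trap * rho * rho if rho < self.r0 else \
            0.5 * self.k_trap * self.r0 ** 2
        return trap + ring + 0.5 * self.k_z * x[2] ** 2

    def force(self, x):
        # numerical gradient: this preset is used for egress statistics,
        # not energy conservation, so central differences are adequate
        x = np.asarray(x, dtype=float).reshape(3)
        h = 1e-5
        f = np.empty(3)
        for d in range(3):
            xp = x.copy(); xp[d] += h
            xm = x.copy(); xm[d] -= h
            f[d] = -(self.energy(xp) - self.energy(xm)) / (2 * h)
        return f

    @staticmethod
    def channel_of(pos) -> str:
        phi = math.atan2(pos[1], pos[0])
        return "wide" if abs(phi) < math.pi / 2 else "narrow"


def _harmonic_truth(pot: HarmonicPotential, temperature: float) -> dict:
    return {"positional_variance_per_dof": kT(temperature) / pot.k,
            "k": pot.k}


def _square_well_truth(pot: SquareWellAxial, temperature: float) -> dict:
    beta = 1.0 / kT(temperature)
    kb = math.pi * pot.geometry.r_cyl ** 2 * pot.length \
        * math.exp(beta * pot.depth)
    dg_kj = -kT(temperature) * math.log(kb * MOLAR_PER_NM3)
    z, w = pot.axial_profile()
    return {"kb_nm3": kb, "delta_g_kcal": dg_kj / KJ_PER_KCAL,
            "axial_z": z, "axial_w": w,
            "bound_region": (-0.05, pot.length + 0.05),
            "unbound_region": (0.8, 1.4)}


def _funnel_trap_truth(pot: FunnelTrap3D, temperature: float) -> dict:
    z, w = pot.axial_pmf(temperature)
    bound = (pot.z_floor + 0.02, 0.45)
    unbound = (0.8, min(1.15, pot.z_cap - 0.05))
    beta = 1.0 / kT(temperature)
    u_mask = (z >= unbound[0]) & (z <= unbound[1])
    w_u = float(w[u_mask].mean())
    b_mask = (z >= bound[0]) & (z <= bound[1])
    kb = math.pi * pot.geometry.r_cyl ** 2 \
        * float(np.trapezoid(np.exp(-beta * (w[b_mask] - w_u)), z[b_mask]))
    dg_kj = -kT(temperature) * math.log(kb * MOLAR_PER_NM3)
    return {"axial_z": z, "axial_w": w, "bound_region": bound,
            "unbound_region": unbound, "kb_nm3": kb,
            "delta_g_kcal": dg_kj / KJ_PER_KCAL}


PRESETS = {
    "harmonic": HarmonicPotential,
    "double_well_1d": DoubleWell1D,
    "square_well_axial": SquareWellAxial,
    "funnel_trap_3d": FunnelTrap3D,
    "two_channel_exit": TwoChannelExit,
}


def make_toy(spec: ToyPotentialSpec):
    """Instantiate a registered preset as a (ToySystem, ground-truth) pair.

    The ground truth carries the quadrature thermodynamics of the preset
    (basin ΔF, axial PMF, standard-state ΔG where defined) plus the
    default CV map for biased runs.
    """
    if spec.preset not in PRESETS:
        raise ValueError(f"unknown preset {spec.preset!r}; registered: "
                         f"{sorted(PRESETS)}")
    params = dict(spec.params)
    if spec.preset == "double_well_1d":
        params.setdefault("temperature", spec.temperature)
    pot = PRESETS[spec.preset](**params)

    funnel = getattr(pot, "geometry", None)
    sys = ToySystem(potential=pot, temperature=spec.temperature,
                    seed=spec.seed, funnel=funnel,
                    timestep=0.004 if pot.dim == 1 else 0.002,
                    # low friction speeds barrier recrossing on the 1-D
                    # presets, which is what converges the deposition
                    friction=1.0 if pot.dim == 1 else 5.0)

    truth: dict = {"preset": spec.preset, "temperature": spec.temperature}
    if spec.preset == "harmonic":
        truth.update(_harmonic_truth(pot, spec.temperature))
        truth["cv_map"] = PositionCV((0,), dim=pot.dim)
    elif spec.preset == "double_well_1d":
        truth.update({"delta_f_kj": pot.quadrature_delta_f(),
                      "split": 0.0, "tilt": pot.tilt})
        truth["cv_map"] = PositionCV((0,), dim=1)
    elif spec.preset == "square_well_axial":
        truth.update(_square_well_truth(pot, spec.temperature))
        truth["cv_map"] = AxialCV(pot.geometry.origin, pot.geometry.axis)
    elif spec.preset == "funnel_trap_3d":
        truth.update(_funnel_trap_truth(pot, spec.temperature))
        w2 = pot.width ** 2

        def compactness(x):
            return math.exp(-float(np.dot(x, x)) / (2 * w2))

        def compactness_jac(x):
            x = np.asarray(x, dtype=float)
            return -compactness(x) / w2 * x

        truth["cv_map"] = AxialCV(pot.geometry.origin, pot.geometry.axis)
        truth["cv_map_2d"] = AxialCV(pot.geometry.origin, pot.geometry.axis,
                                     extra=compactness,
                                     extra_jac=compactness_jac)
    elif spec.preset == "two_channel_exit":
        truth["channels"] = {"wide": pot.wide, "narrow": pot.narrow}
    return sys, truth


# ==========================================================================
# inverse hills generator
# ==========================================================================

def hills_from_fes(target: FreeEnergySurface, p: MetaDParams, n_hills: int,
                   seed: int = 0, residual_tol: float = 0.25,
                   relevant_range: float = 25.0):
    """Emit hills whose well-tempered sum reconstructs the target surface.

    Greedy matching pursuit on the target grid: each hill is centred near
    the current maximum of the residual ``(1 - 1/gamma)(max F - F) - V``
    (with seeded jitter) and clipped to the height budget, so
    ``reconstruct_fes`` applied to the log recovers the target up to the
    reported residual.  Returns ``(HillsLog, info)`` with
    ``info = {"residual": ..., "warning": bool}``; ``n_hills = 0`` gives
    an empty log and a warning.

    The residual is the half-range of the reconstruction error over the
    thermally relevant region ``F <= min(F) + relevant_range`` (kJ/mol):
    positive Gaussians necessarily overshoot into narrow high-F walls
    steeper than the kernel width, exactly as a real metadynamics bias
    never resolves regions it cannot sample.
    """
    rng = np.random.default_rng(seed)
    gamma = p.bias_factor
    axes = target.axes
    if len(axes) != len(p.sigma):
        raise ValueError("MetaDParams sigma dimensionality does not match target")
    v_target = (1.0 - 1.0 / gamma) * (target.values.max() - target.values)
    v = np.zeros_like(v_target)
    shape = v.shape
    hills: list[Hill] = []
    for i in range(n_hills):
        res = v_target - v
        imax = np.unravel_index(int(np.argmax(res)), shape)
        if res[imax] > 1e-9:
            center = [float(a[j]) + rng.uniform(-0.2, 0.2) * s
                      for a, j, s in zip(axes, imax, p.sigma)]
            center = [min(max(c, a[0]), a[-1]) for c, a in zip(center, axes)]
            height = float(min(p.height0, max(0.7 * res[imax], 1e-9)))
        else:
            center = [float(rng.uniform(a[0], a[-1])) for a in axes]
            height = 1e-9
        hill = Hill(time=2.0 * (i + 1), center=tuple(center),
                    sigma=tuple(p.sigma), height=height, bias_factor=gamma)
        hills.append(hill)
        gs = [np.exp(-0.5 * ((a - c) / s) ** 2)
              for a, c, s in zip(axes, center, p.sigma)]
        v += height * (gs[0] if len(axes) == 1 else np.outer(gs[0], gs[1]))
    res = v_target - v
    relevant = target.values <= target.values.min() + relevant_range
    res = res[relevant]
    residual = float(res.max() - res.min()) / 2.0 if res.size else 0.0
    log = HillsLog(hills=hills,
                   cv_names=tuple(target.axis_names),
                   metadata={"bias_factor": gamma,
                             "temperature": target.temperature,
                             "generator": "hills_from_fes", "seed": seed})
    return log, {"residual": residual,
                 "warning": n_hills == 0 or residual > residual_tol}


# ==========================================================================
# planted ensembles
# ==========================================================================

# idealized backbone geometry (nm / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_CA_CB = 0.1458, 0.1525, 0.1329, 0.1530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_N_CA_CB = 111.2, 116.2, 121.7, 110.5
_OMEGA = 180.0
_D_C_N_CA_CB = 122.5  # improper placing CB


@dataclass(frozen=True)
class PlantedEnsembleSpec:
    """Recipe for an ensemble with planted structure.

    ``helix_prob`` may be a scalar (all residues) or a {resid: p} mapping;
    ``corr_blocks`` is a list of ``(resids_a, resids_b, rho)`` with
    ``rho`` the planted cross-correlation (negative for anti-correlated
    blocks; within-block correlation is ``|rho|`` by the factor-model
    construction); ``contacts`` is a list of ``(res_i, res_j, prob)``
    realized by rigidly translating residue j.  ``fluct_sigma`` is the
    per-component Gaussian amplitude (nm) per atom, scalar or
    ``{resid: sigma}``.
    """

    n_frames: int = 100
    n_residues: int = 24
    resid_start: int = 690
    helix_prob: object = 1.0
    corr_blocks: tuple = ()
    corr_sigma: float = 0.03
    contacts: tuple = ()
    contact_cutoff: float = 0.45
    contact_near: float = 0.6   # fraction of cutoff when in contact
    contact_far: float = 2.2    # fraction of cutoff when apart
    fluct_sigma: object = 0.0
    dihedral_jitter: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_residues < 3:
            raise ValueError("need at least 1 frame and 3 residues")
        probs = ([self.helix_prob] if np.isscalar(self.helix_prob)
                 else list(self.helix_prob.values()))
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("helix probabilities must lie in [0, 1]")
        for _, _, prob in self.contacts:
            if not 0 <= prob <= 1:
                raise ValueError("contact probabilities must lie in [0, 1]")
        for a, b, rho in self.corr_blocks:
            if not -1 <= rho <= 1:
                raise ValueError("planted correlations must lie in [-1, 1]")
            if set(a) & set(b):
                raise ValueError("correlation blocks must be disjoint")


def _nerf_batch(a, b, c, bond, angle_deg, dihedral_deg):
    """Place an atom bonded to c, batched over frames.  ``dihedral_deg``
    may be scalar or per-frame."""
    ang = math.radians(angle_deg)
    dih = np.radians(np.asarray(dihedral_deg, dtype=float))
    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d = np.empty(c.shape)
    cos_t, sin_t = math.cos(ang), math.sin(ang)
    cos_p, sin_p = np.cos(dih), np.sin(dih)
    d = (-bond * cos_t) * bc \
        + (bond * sin_t * cos_p)[..., None] * m \
        - (bond * sin_t * sin_p)[..., None] * n
    return c + d


def _build_backbones(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Batched chain construction from per-frame (φ, ψ) arrays.

    ``phi``/``psi`` are (n_frames, n_residues); φ of the first and ψ of
    the last residue are ignored.  Returns coordinates
    (n_frames, n_residues * 4, 3) for atoms N, CA, C, CB per residue, nm.
    """
    nf, nres = phi.shape
    coords = np.empty((nf, nres * 4, 3))
    # first residue placed in a fixed frame
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords[:, 0] = n0
    coords[:, 1] = ca0
    coords[:, 2] = c0
    coords[:, 3] = _nerf_batch(coords[:, 2], coords[:, 0], coords[:, 1],
                               _B_CA_CB, _A_N_CA_CB, _D_C_N_CA_CB)
    for r in range(1, nres):
        o = 4 * r
        n_prev, ca_prev, c_prev = coords[:, o - 4], coords[:, o - 3], coords[:, o - 2]
        coords[:, o] = _nerf_batch(n_prev, ca_prev, c_prev,
                                   _B_C_N, _A_CA_C_N, psi[:, r - 1])
        coords[:, o + 1] = _nerf_batch(ca_prev, c_prev, coords[:, o],
                                       _B_N_CA, _A_C_N_CA, _OMEGA)
        coords[:, o + 2] = _nerf_batch(c_prev, coords[:, o], coords[:, o + 1],
                                       _B_CA_C, _A_N_CA_C, phi[:, r])
        coords[:, o + 3] = _nerf_batch(coords[:, o + 2], coords[:, o],
                                       coords[:, o + 1],
                                       _B_CA_CB, _A_N_CA_CB, _D_C_N_CA_CB)
    return coords


def _atom_table(spec: PlantedEnsembleSpec, coords0: np.ndarray) -> StructureModel:
    names = ["N", "CA", "C", "CB"]
    elements = ["N", "C", "C", "C"]
    nres = spec.n_residues
    return StructureModel(
        serial=np.arange(1, 4 * nres + 1),
        name=np.array(names * nres),
        resname=np.array(["ALA"] * 4 * nres),
        resid=np.repeat(np.arange(spec.resid_start,
                                  spec.resid_start + nres), 4),
        chain=np.array(["A"] * 4 * nres),
        element=np.array(elements * nres),
        coords=coords0,
        source="synthetic planted ensemble",
    )


def make_ensemble(spec: PlantedEnsembleSpec):
    """Draw a planted ensemble and its ground truth.

    Frames are built residue by residue from per-frame backbone dihedrals
    (helix/coil per the planted probabilities, with Gaussian jitter), then
    perturbed by rigid per-residue displacements carrying the planted
    correlation blocks, rigid translations realizing the planted contacts,
    and finally iid per-atom Gaussian fluctuations.

    The ground truth records the *realized* helix fractions and contact
    occupancies (so estimator checks are exact up to the estimator, not
    binomial sampling), the planted cross-correlations, the expected
    per-atom RMSF, and the residues whose backbone dihedrals are perturbed
    by contact translations (their neighbors included).
    """
    rng = np.random.default_rng(spec.seed)
    nf, nres = spec.n_frames, spec.n_residues
    resids = np.arange(spec.resid_start, spec.resid_start + nres)

    if np.isscalar(spec.helix_prob):
        probs = np.full(nres, float(spec.helix_prob))
    else:
        probs = np.array([float(spec.helix_prob.get(int(r), 1.0))
                          for r in resids])
    is_helix = rng.random((nf, nres)) < probs[None, :]
    jit = spec.dihedral_jitter
    phi = np.where(is_helix, HELIX_DIHEDRALS[0], COIL_DIHEDRALS[0]) \
        + rng.normal(0.0, jit, (nf, nres))
    psi = np.where(is_helix, HELIX_DIHEDRALS[1], COIL_DIHEDRALS[1]) \
        + rng.normal(0.0, jit, (nf, nres))
    coords = _build_backbones(phi, psi)

    # planted per-residue correlated displacements (factor model):
    # residues in block A move with +sqrt(|rho|)*f, block B with -sqrt(|rho|)*f,
    # everyone adds sqrt(1-|rho|)*independent noise -> cross-corr = -|rho|.
    res_disp = np.zeros((nf, nres, 3))
    expected_disp_var = np.zeros(nres)  # per component, nm^2
    if spec.corr_blocks:
        sig = spec.corr_sigma
        in_block = np.zeros(nres, dtype=bool)
        for block_a, block_b, rho in spec.corr_blocks:
            a_loc = np.array([int(r) - spec.resid_start for r in block_a])
            b_loc = np.array([int(r) - spec.resid_start for r in block_b])
            amp = math.sqrt(abs(rho))
            f = rng.normal(0.0, 1.0, (nf, 1, 3))
            sgn = -1.0 if rho < 0 else 1.0
            res_disp[:, a_loc] += sig * amp * f
            res_disp[:, b_loc] += sgn * sig * amp * f
            in_block[a_loc] = in_block[b_loc] = True
            indep = sig * math.sqrt(1.0 - abs(rho))
            res_disp[:, a_loc] += rng.normal(0.0, indep, (nf, a_loc.size, 3))
            res_disp[:, b_loc] += rng.normal(0.0, indep, (nf, b_loc.size, 3))
            expected_disp_var[a_loc] += sig ** 2
            expected_disp_var[b_loc] += sig ** 2
        # residues outside any block: independent motion of the same scale
        out = ~in_block
        res_disp[:, out] += rng.normal(0.0, sig, (nf, int(out.sum()), 3))
        expected_disp_var[out] += sig ** 2
    coords += np.repeat(res_disp, 4, axis=1)

    # planted contacts: rigid translation of residue j toward/away from i
    realized_contacts = {}
    perturbed = set()
    atoms = _atom_table(spec, coords[0].copy())
    for res_i, res_j, prob in spec.contacts:
        ia = atoms.residue_atoms(int(res_i), heavy_only=True)
        ib = atoms.residue_atoms(int(res_j), heavy_only=True)
        jb_all = atoms.residue_atoms(int(res_j))
        in_contact = rng.random(nf) < prob
        target = np.where(in_contact, spec.contact_near, spec.contact_far) \
            * spec.contact_cutoff
        for k in range(nf):
            d = np.linalg.norm(coords[k, ia][:, None, :]
                               - coords[k, ib][None, :, :], axis=-1)
            a_loc, b_loc = np.unravel_index(int(np.argmin(d)), d.shape)
            pa, pb = coords[k, ia[a_loc]], coords[k, ib[b_loc]]
            gap = pb - pa
            dist = float(np.linalg.norm(gap))
            u = gap / dist if dist > 1e-9 else np.array([1.0, 0.0, 0.0])
            coords[k, jb_all] += (target[k] - dist) * u
        realized_contacts[(int(res_i), int(res_j))] = float(in_contact.mean())
        for r in (int(res_j) - 1, int(res_j), int(res_j) + 1,
                  int(res_i) - 1, int(res_i) + 1):
            perturbed.add(r)

    # per-atom fluctuation noise
    if np.isscalar(spec.fluct_sigma):
        sigma_atom = np.full(nres, float(spec.fluct_sigma))
    else:
        sigma_atom = np.array([float(spec.fluct_sigma.get(int(r), 0.0))
                               for r in resids])
    if np.any(sigma_atom > 0):
        coords += rng.normal(0.0, 1.0, coords.shape) \
            * np.repeat(sigma_atom, 4)[None, :, None]

    realized_helix = {int(r): float(is_helix[:, i].mean())
                      for i, r in enumerate(resids)}
    total_var = expected_disp_var + sigma_atom ** 2  # per component
    truth = {
        "helix_prob_planted": {int(r): float(p) for r, p in zip(resids, probs)},
        "helix_fraction_realized": realized_helix,
        "corr_blocks": [(tuple(int(r) for r in a), tuple(int(r) for r in b),
                         float(rho)) for a, b, rho in spec.corr_blocks],
        "contact_occupancy_realized": realized_contacts,
        "contact_perturbed_residues": sorted(perturbed),
        "rmsf_expected_nm": np.sqrt(3.0 * total_var),
        "seed": spec.seed,
    }
    atoms = _atom_table(spec, coords[0].copy())
    ens = LabeledEnsemble(atoms=atoms, coords=coords)
    return ens, truth
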