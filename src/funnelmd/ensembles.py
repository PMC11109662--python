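"""Conformational-ensemble analytics: basin assignment, DCC, contacts,
helicity, superposition/RMSD, ΔRMSF, and Cα anchor distances.

These are the observables computed on basin-assigned frame ensembles:

* **DCC** — the dynamic cross-correlation of Cα displacement vectors,
  ``DCC_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|^2><|Δr_j|^2>)`` with deviations
  taken from the ensemble mean after superposition; values in [-1, 1],
  negative for anti-correlated motion.
* **Contact occupancy** — the fraction of frames in which any heavy-atom
  pair of two residues is within a distance cutoff.
* **Helicity** — the fraction of frames whose backbone dihedrals fall in
  the α-helical window φ ∈ [-100°, -30°], ψ ∈ [-67°, -7°].  A plain
  dihedral-window criterion is used so the definition is exact and
  dependency-light.
* **ΔRMSF** — the mean per-atom difference of root-mean-square fluctuation
  between a mutant and a wild-type ensemble over a region of interest
  (``(Σ RMSF_mut - Σ RMSF_wt) / N``, Å); antisymmetric by construction.
* **Cα distance statistics** — mean ± population standard deviation of
  Cα–Cα distances for anchor-residue pairs (Å).

Internally coordinates are nm; RMSD/RMSF/distance statistics are reported
in Å, the unit these observables are conventionally quoted in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .colvars import StructureModel
from .fes import Basin
from .units import ANGSTROM_PER_NM

__all__ = [
    "LabeledEnsemble",
    "DCCMatrix",
    "assign_frames",
    "superpose",
    "superpose_ensemble_to_mean",
    "dcc_map",
    "contact_occupancy",
    "backbone_dihedrals",
    "helicity",
    "rmsf",
    "delta_rmsf",
    "ca_distance_stats",
    "HELIX_PHI_WINDOW",
    "HELIX_PSI_WINDOW",
]

HELIX_PHI_WINDOW = (-100.0, -30.0)  # degrees
HELIX_PSI_WINDOW = (-67.0, -7.0)


@dataclass
class LabeledEnsemble:
    """Frames sharing one atom table, optionally weighted and basin-labeled."""

    atoms: StructureModel
    coords: np.ndarray                    # (n_frames, n_atoms, 3), nm
    weights: Optional[np.ndarray] = None  # per-frame, sum to 1
    basin_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.atoms.n_atoms:
            raise ValueError("coords must be (n_frames, n_atoms, 3) matching "
                             "the atom table")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.n_frames,):
                raise ValueError("weights must be per-frame")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")
            total = self.weights.sum()
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise ValueError("weights must sum to 1")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.n_frames, 1.0 / self.n_frames)
        return self.weights


@dataclass
class DCCMatrix:
    """Symmetric Cα cross-correlation matrix over a residue selection."""

    values: np.ndarray
    selection: tuple[int, ...]         # residue numbers
    threshold_display: float = 0.4     # |DCC| below this is left blank in maps

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        finite = np.isfinite(v)
        if np.any(np.abs(v[finite]) > 1.0 + 1e-10):
            raise ValueError("DCC values must lie in [-1, 1]")
        if not np.allclose(v, v.T, equal_nan=True, atol=1e-10):
            raise ValueError("DCC matrix must be symmetric")
        self.values = v

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of undefined entries (zero-variance residues)."""
        return ~np.isfinite(self.values)


# --------------------------------------------------------------------------
# basin assignment
# --------------------------------------------------------------------------

def assign_frames(cv_series, basins: Sequence[Basin]) -> list[str]:
    """Label each CV-space point with the basin whose extent contains it.

    Points outside every extent get ``"unassigned"``; overlapping extents
    are resolved in favor of the deeper (lower-minimum) basin.
    Deterministic.
    """
    pts = np.atleast_2d(np.asarray(cv_series, dtype=float))
    ordered = sorted(basins, key=lambda b: b.value)
    labels = []
    for pt in pts:
        lab = "unassigned"
        for b in ordered:
            if b.contains(pt):
                lab = b.label
                break
        labels.append(lab)
    return labels


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray,
              fit_selection: Optional[np.ndarray] = None,
              report_selection: Optional[np.ndarray] = None):
    """Optimal rigid-body least-squares (Kabsch) superposition.

    Fits ``mobile`` onto ``reference`` using ``fit_selection`` (default:
    all atoms), applies the transform to the whole frame and returns
    ``(transformed, rmsd_angstrom)`` with the RMSD measured on
    ``report_selection`` (default: the fit selection).  Degenerate
    (collinear, < 2 distinct points) fit sets raise ``ValueError``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    fit = np.arange(mobile.shape[0]) if fit_selection is None \
        else np.asarray(fit_selection, dtype=int)
    rep = fit if report_selection is None else np.asarray(report_selection, int)
    if fit.size < 2:
        raise ValueError("need at least 2 fit atoms")
    mob_f = mobile[fit]
    ref_f = reference[fit]
    mob_c = mob_f.mean(axis=0)
    ref_c = ref_f.mean(axis=0)
    h = (mob_f - mob_c).T @ (ref_f - ref_c)
    u, s, vt = np.linalg.svd(h)
    # a pair of points is tolerated (1-D fit: rotation about the axis is
    # unconstrained but the RMSD is well defined); a fully degenerate set is not
    if np.count_nonzero(s > 1e-12 * max(s[0], 1e-300)) == 0:
        raise ValueError("degenerate fit selection: all fit atoms coincide")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transformed = (mobile - mob_c) @ rot.T + ref_c
    diff = transformed[rep] - reference[rep]
    rmsd_nm = math.sqrt(float(np.mean(np.sum(diff * diff, axis=1))))
    return transformed, rmsd_nm * ANGSTROM_PER_NM


def superpose_ensemble_to_mean(ens: LabeledEnsemble,
                               fit_selection: Optional[np.ndarray] = None,
                               passes: int = 2) -> LabeledEnsemble:
    """Iteratively superpose every frame onto the (weighted) ensemble mean.

    Two passes are enough in practice: fit to frame 0, recompute the mean,
    refit.  Returns a new ensemble; the input is unmodified.
    """
    coords = ens.coords.copy()
    w = ens.frame_weights()
    reference = coords[0]
    for _ in range(max(1, passes)):
        for k in range(coords.shape[0]):
            coords[k], _ = superpose(coords[k], reference, fit_selection)
        reference = np.einsum("f,fij->ij", w, coords)
    return LabeledEnsemble(atoms=ens.atoms, coords=coords,
                           weights=ens.weights, basin_label=ens.basin_label)


# --------------------------------------------------------------------------
# DCC
# --------------------------------------------------------------------------

def dcc_map(ens: LabeledEnsemble, selection: Sequence[int],
            threshold_display: float = 0.4) -> DCCMatrix:
    """Dynamic cross-correlation of Cα displacement vectors.

    Frames must already be superposed (see
    :func:`superpose_ensemble_to_mean`).  Residues with zero positional
    variance give undefined (NaN) rows/columns rather than 0.
    Requires at least 10 frames.
    """
    if ens.n_frames < 10:
        raise ValueError("DCC needs at least 10 frames")
    idx = np.array([ens.atoms.ca_index(r) for r in selection])
    w = ens.frame_weights()
    x = ens.coords[:, idx, :]                       # (F, R, 3)
    mean = np.einsum("f,frd->rd", w, x)
    dev = x - mean
    cov = np.einsum("f,frd,fsd->rs", w, dev, dev)   # <Δr_i · Δr_j>
    var = np.diag(cov).copy()
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        dcc = cov / denom
    dcc[:, var <= 0] = np.nan
    dcc[var <= 0, :] = np.nan
    np.clip(dcc, -1.0, 1.0, out=dcc)
    ok = var > 0
    dcc[np.diag_indices_from(dcc)] = np.where(ok, 1.0, np.nan)
    return DCCMatrix(values=dcc, selection=tuple(int(r) for r in selection),
                     threshold_display=threshold_display)


# --------------------------------------------------------------------------
# contacts
# --------------------------------------------------------------------------

def contact_occupancy(ens: LabeledEnsemble, residue_pair: tuple[int, int],
                      cutoff: float = 0.45) -> float:
    """Weighted fraction of frames in which the two residues touch.

    A frame counts when *any* heavy-atom pair across the residues is
    within ``cutoff`` (nm).  Monotone non-decreasing in the cutoff.
    """
    ra, rb = residue_pair
    ia = ens.atoms.residue_atoms(ra, heavy_only=True)
    ib = ens.atoms.residue_atoms(rb, heavy_only=True)
    d = np.linalg.norm(
        ens.coords[:, ia, None, :] - ens.coords[:, ib, None, :].transpose(0, 2, 1, 3),
        axis=-1)
    in_contact = np.any(d.reshape(ens.n_frames, -1) <= cutoff, axis=1)
    return float(np.dot(ens.frame_weights(), in_contact))


# --------------------------------------------------------------------------
# helicity
# --------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3):
    """Signed dihedral angle in degrees, vectorized over leading axes."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


def backbone_dihedrals(ens: LabeledEnsemble, resid: int):
    """Per-frame (φ, ψ) for one residue, degrees.

    φ needs the previous residue's C and ψ the next residue's N; a missing
    neighbor raises ``KeyError`` (chain terminus)."""
    at = ens.atoms

    def atom(r, name):
        idx = np.flatnonzero((at.resid == r) & (at.name == name))
        if idx.size == 0:
            raise KeyError(f"atom {name} of residue {r} not present")
        return int(idx[0])

    c_prev = ens.coords[:, atom(resid - 1, "C")]
    n = ens.coords[:, atom(resid, "N")]
    ca = ens.coords[:, atom(resid, "CA")]
    c = ens.coords[:, atom(resid, "C")]
    n_next = ens.coords[:, atom(resid + 1, "N")]
    phi = _dihedral(c_prev, n, ca, c)
    psi = _dihedral(n, ca, c, n_next)
    return phi, psi


def helicity(ens: LabeledEnsemble, residues: Sequence[int]) -> dict[int, float]:
    """Per-residue fraction of frames in the α-helical dihedral window.

    Residues lacking a φ or ψ (chain termini) are reported as NaN rather
    than dropped.  Weighted by frame weights; invariant under per-frame
    rigid transforms.
    """
    w = ens.frame_weights()
    out: dict[int, float] = {}
    for r in residues:
        try:
            phi, psi = backbone_dihedrals(ens, r)
        except KeyError:
            out[int(r)] = float("nan")
            continue
        helical = ((phi >= HELIX_PHI_WINDOW[0]) & (phi <= HELIX_PHI_WINDOW[1])
                   & (psi >= HELIX_PSI_WINDOW[0]) & (psi <= HELIX_PSI_WINDOW[1]))
        out[int(r)] = float(np.dot(w, helical))
    return out


# --------------------------------------------------------------------------
# RMSF
# --------------------------------------------------------------------------

def rmsf(ens: LabeledEnsemble, selection: np.ndarray) -> np.ndarray:
    """Per-atom RMSF about the weighted ensemble mean, Å.

    Superpose the ensemble on a stable core first (see
    :func:`superpose_ensemble_to_mean`); the RMSF itself uses the frames
    as given.
    """
    sel = np.asarray(selection, dtype=int)
    w = ens.frame_weights()
    x = ens.coords[:, sel, :]
    mean = np.einsum("f,fad->ad", w, x)
    msd = np.einsum("f,fad->ad", w, (x - mean) ** 2).sum(axis=1)
    return np.sqrt(msd) * ANGSTROM_PER_NM


def delta_rmsf(ens_mut: LabeledEnsemble, ens_wt: LabeledEnsemble,
               selection_mut: np.ndarray,
               selection_wt: Optional[np.ndarray] = None) -> float:
    """Mean per-atom RMSF increment of mutant over wild type, Å.

    ``(Σ RMSF_mut - Σ RMSF_wt) / N`` over the analyzed region (the AF2
    main-chain heavy atoms in the receptor application).  Sign-preserving
    and exactly antisymmetric under swapping the ensembles.  The two
    selections must contain the same number of atoms.
    """
    sel_m = np.asarray(selection_mut, dtype=int)
    sel_w = sel_m if selection_wt is None else np.asarray(selection_wt, int)
    if sel_m.size != sel_w.size:
        raise ValueError("selections must map to the same atom count "
                         f"({sel_m.size} vs {sel_w.size})")
    if sel_m.size == 0:
        raise ValueError("empty selection")
    r_mut = rmsf(ens_mut, sel_m)
    r_wt = rmsf(ens_wt, sel_w)
    return float((r_mut.sum() - r_wt.sum()) / sel_m.size)


# --------------------------------------------------------------------------
# anchor distances
# --------------------------------------------------------------------------

def ca_distance_stats(ens: LabeledEnsemble, residue_triple: Sequence[int]):
    """Mean ± population SD of Cα–Cα distances for each residue pair, Å.

    Returns ``{(ri, rj): (mean, sd)}`` for the three pairs of the triple
    (population, not sample, standard deviation).
    """
    residues = [int(r) for r in residue_triple]
    idx = {r: ens.atoms.ca_index(r) for r in residues}
    w = ens.frame_weights()
    out = {}
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            ri, rj = residues[a], residues[b]
            d = np.linalg.norm(ens.coords[:, idx[ri]] - ens.coords[:, idx[rj]],
                               axis=1) * ANGSTROM_PER_NM
            mean = float(np.dot(w, d))
            sd = float(math.sqrt(np.dot(w, (d - mean) ** 2)))
            out[(ri, rj)] = (mean, sd)
    return out
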