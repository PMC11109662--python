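"""Reaction coordinates for ligand binding: COM distance and native-contact score.

Two collective variables describe binding to the receptor pocket:

* **CV1** — the distance between the mass-weighted centers of the ligand and
  the protein (nm).
* **CV2** — a logistic native-contact score.  Given the ``m`` heavy-atom
  pairs that are in contact in the reference crystal structure, the score of
  a conformation ``X`` is

  .. math:: S(X) = \\sum_{i=1}^{m} \\frac{1}{1 + e^{\\beta (r_i - \\lambda r_0)}}

  with steepness ``beta`` (nm^-1), scale ``lambda`` (dimensionless) and
  reference distance ``r0`` (nm).  Each term is 1 for a formed contact,
  0 for a broken one, and exactly 1/2 at ``r = lambda*r0``; hence
  ``0 <= S <= m``.  Higher S means a more closed, compact channel.

The native pair list is identified once on the reference structure
(within a distance cutoff, heavy atoms only — crystal structures carry no
hydrogens) and then frozen; it is never recomputed per frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "StructureModel",
    "ContactDefinition",
    "CVRecord",
    "AR_CHANNEL_RESIDUE_PAIRS",
    "switching_value",
    "switching_derivative",
    "contact_number",
    "contact_number_gradient",
    "identify_native_pairs",
    "com_distance",
]

#: Residue-number pairs spanning the H3-H7-H11 egress channel of the androgen
#: receptor ligand-binding domain (1T5Z numbering).  Heavy-atom pairs of these
#: residues within the contact cutoff in the crystal structure define CV2.
AR_CHANNEL_RESIDUE_PAIRS: tuple[tuple[int, int], ...] = (
    (697, 700), (697, 701), (697, 777), (697, 778), (697, 779), (697, 887),
    (698, 887), (698, 889),
    (700, 703), (700, 704), (700, 778),
    (701, 778), (701, 780), (701, 876), (701, 880), (701, 889), (701, 890),
    (704, 780),
    (778, 876), (779, 876), (780, 876),
    (876, 879), (876, 880),
    (880, 883), (880, 884), (880, 887), (880, 889), (880, 891),
    (881, 891),
    (883, 886), (883, 887),
    (884, 888), (884, 889), (884, 891),
)


@dataclass
class StructureModel:
    """Flat atom table of a (reference) structure, coordinates in nm."""

    serial: np.ndarray      # int, atom serial numbers
    name: np.ndarray        # str, atom names (e.g. "CA")
    resname: np.ndarray     # str
    resid: np.ndarray       # int residue numbers
    chain: np.ndarray       # str
    element: np.ndarray     # str, upper-case element symbols ("" if unknown)
    coords: np.ndarray      # (n_atoms, 3) float, nm
    source: str = ""        # free-text provenance, e.g. a PDB id

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.serial)
        for fld in ("name", "resname", "resid", "chain", "element"):
            if len(getattr(self, fld)) != n:
                raise ValueError(f"atom table field {fld!r} has inconsistent length")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in structure")

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def residue_atoms(self, resid: int, heavy_only: bool = False) -> np.ndarray:
        """Indices of the atoms of residue ``resid`` (lookup error if absent)."""
        mask = self.resid == resid
        if heavy_only:
            mask &= self.element != "H"
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError(f"residue {resid} not present in structure "
                           f"{self.source or '<anonymous>'}")
        return idx

    def ca_index(self, resid: int) -> int:
        idx = np.flatnonzero((self.resid == resid) & (self.name == "CA"))
        if idx.size == 0:
            raise KeyError(f"no CA atom for residue {resid}")
        return int(idx[0])


@dataclass(frozen=True)
class ContactDefinition:
    """Frozen native-contact pair list plus the logistic parameters of CV2."""

    pairs: tuple[tuple[int, int], ...]  # atom-index pairs into a StructureModel
    beta: float = 50.0   # nm^-1
    lam: float = 1.8     # dimensionless
    r0: float = 0.45     # nm

    def __post_init__(self) -> None:
        if not (self.beta > 0 and self.lam > 0 and self.r0 > 0):
            raise ValueError("beta, lam and r0 must all be positive")
        seen = set()
        for i, j in self.pairs:
            if i == j:
                raise ValueError(f"degenerate pair ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate unordered pair ({i}, {j})")
            seen.add(key)

    @property
    def m(self) -> int:
        """Number of native pairs."""
        return len(self.pairs)

    @property
    def midpoint(self) -> float:
        """Distance at which a single contact term equals 1/2 (= lambda*r0, nm)."""
        return self.lam * self.r0


@dataclass(frozen=True)
class CVRecord:
    """One row of a CV time series."""

    time: float  # ps
    cv1: float   # nm, COM distance
    cv2: float   # dimensionless contact value

    def __post_init__(self) -> None:
        if self.cv1 < 0:
            raise ValueError("cv1 (a distance) cannot be negative")


def switching_value(r, beta: float, lam: float, r0: float):
    """Logistic contact term 1 / (1 + exp(beta*(r - lam*r0))).

    Strictly decreasing in r, exactly 1/2 at r = lam*r0.  Implemented with
    the numerically saturating logistic so extreme arguments return 0 or 1
    instead of overflowing.
    """
    r = np.asarray(r, dtype=float)
    out = expit(-beta * (r - lam * r0))
    return float(out) if out.ndim == 0 else out


def switching_derivative(r, beta: float, lam: float, r0: float):
    """d/dr of :func:`switching_value` (analytic: -beta * s * (1 - s))."""
    s = switching_value(r, beta, lam, r0)
    return -beta * s * (1.0 - s)


def _pair_vectors(coords: np.ndarray, cdef: ContactDefinition):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    idx = np.asarray(cdef.pairs, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        bad = [p for p in cdef.pairs if p[0] >= n or p[1] >= n or min(p) < 0]
        raise IndexError(f"contact pair(s) {bad[:3]} not resolvable in a frame "
                         f"with {n} atoms")
    return idx


def contact_number(coords, cdef: ContactDefinition) -> float:
    """Eq.-1 contact score S of a frame: sum of per-pair logistic terms."""
    idx = _pair_vectors(coords, cdef)
    if idx.size == 0:
        return 0.0
    d = np.asarray(coords)[idx[:, 0]] - np.asarray(coords)[idx[:, 1]]
    r = np.linalg.norm(d, axis=1)
    return float(np.sum(switching_value(r, cdef.beta, cdef.lam, cdef.r0)))


def contact_number_gradient(coords, cdef: ContactDefinition):
    """Contact score and its analytic Cartesian gradient.

    Returns ``(S, dS/dcoords)`` with the gradient shaped like ``coords``;
    used by the toy simulator to apply biased forces along CV2.
    """
    coords = np.asarray(coords, dtype=float)
    idx = _pair_vectors(coords, cdef)
    grad = np.zeros_like(coords)
    if idx.size == 0:
        return 0.0, grad
    d = coords[idx[:, 0]] - coords[idx[:, 1]]
    r = np.linalg.norm(d, axis=1)
    s = switching_value(r, cdef.beta, cdef.lam, cdef.r0)
    dsdr = -cdef.beta * s * (1.0 - s)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[:, None] > 0, d / np.where(r[:, None] == 0, 1.0, r[:, None]), 0.0)
    contrib = dsdr[:, None] * unit
    np.add.at(grad, idx[:, 0], contrib)
    np.add.at(grad, idx[:, 1], -contrib)
    return float(np.sum(s)), grad


def identify_native_pairs(
    ref: StructureModel,
    residue_pairs,
    cutoff: float = 0.45,
    beta: float = 50.0,
    lam: float = 1.8,
    r0: float = 0.45,
) -> ContactDefinition:
    """Freeze the native-contact atom-pair list from a reference structure.

    For every listed residue-number pair, every heavy-atom pair (one atom
    from each residue) whose reference distance is <= ``cutoff`` (nm) is
    included.  Ordering is deterministic: pairs are sorted ascending by the
    serial numbers of their atoms.  A missing residue raises ``KeyError``.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    found: list[tuple[int, int, int, int]] = []
    for ra, rb in residue_pairs:
        ia = ref.residue_atoms(ra, heavy_only=True)
        ib = ref.residue_atoms(rb, heavy_only=True)
        d = np.linalg.norm(ref.coords[ia][:, None, :] - ref.coords[ib][None, :, :],
                           axis=-1)
        for a_loc, b_loc in zip(*np.nonzero(d <= cutoff)):
            i, j = int(ia[a_loc]), int(ib[b_loc])
            found.append((int(ref.serial[i]), int(ref.serial[j]), i, j))
    found.sort()
    return ContactDefinition(pairs=tuple((i, j) for _, _, i, j in found),
                             beta=beta, lam=lam, r0=r0)


def com_distance(coords, group_a, group_b, masses) -> float:
    """Distance between mass-weighted centroids of two atom selections (nm).

    Symmetric in group order; empty selections raise ``ValueError``.
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    if ga.size == 0 or gb.size == 0:
        raise ValueError("both selections must be non-empty")
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    com_a = np.average(coords[ga], axis=0, weights=masses[ga])
    com_b = np.average(coords[gb], axis=0, weights=masses[gb])
    return float(np.linalg.norm(com_a - com_b))
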