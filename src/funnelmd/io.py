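"""Readers/writers for the external formats, run configuration, logging.

Formats supported: PDB and multi-model PDB (via biotite, altloc resolved by
highest occupancy, Å converted to nm on ingestion), XTC/DCD trajectories
(via MDAnalysis, a PDB topology supplies the atom table), the PLUMED
HILLS/COLVAR whitespace table dialect (``#! FIELDS ...`` header), a
delimited text grid for free-energy surfaces, and a YAML run configuration
validated against a strict schema whose defaults reproduce the production
funnel-metadynamics parameters exactly (β = 50 nm⁻¹, λ = 1.8, r₀ = 0.45 nm;
hill height 1.0 kJ/mol, widths 0.1 and 10, 2 ps pace, bias factor 16; RAMD
16 kcal mol⁻¹ Å⁻¹ / 100 fs / 0.025 Å).

All writers are deterministic: stable ordering and fixed ``%.6f`` float
formatting, so well-formed files round-trip byte-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .colvars import StructureModel
from .engine import Hill, HillsLog, MetaDParams, RamdState
from .ensembles import LabeledEnsemble
from .fes import FreeEnergySurface
from .funnel import FunnelGeometry

__all__ = [
    "ParseError",
    "read_hills",
    "write_hills",
    "read_colvar",
    "write_colvar",
    "read_structure",
    "read_trajectory",
    "write_ensemble_pdb",
    "read_residue_pairs",
    "read_fes",
    "write_fes",
    "RunConfig",
    "load_config",
    "dump_config",
    "config_hash",
    "get_logger",
    "PACKAGE_VERSION",
]

PACKAGE_VERSION = "0.1.0"
_FLOAT_FMT = "{:.6f}"


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


# --------------------------------------------------------------------------
# logging
# --------------------------------------------------------------------------

def get_logger(verbosity: int = 0) -> logging.Logger:
    """Structured logging to stderr; verbosity 0 = warnings, 1 = info, 2+ = debug."""
    logger = logging.getLogger("funnelmd")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.WARNING if verbosity <= 0
                    else logging.INFO if verbosity == 1 else logging.DEBUG)
    return logger


# --------------------------------------------------------------------------
# HILLS / COLVAR dialect
# --------------------------------------------------------------------------

def _parse_table(path):
    fields = None
    comments: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#! FIELDS"):
                if fields is not None:
                    raise ParseError(f"{path}:{lineno}: duplicate FIELDS header")
                fields = line.split()[2:]
            elif line.startswith("#"):
                comments.append(line)
            else:
                if fields is None:
                    raise ParseError(f"{path}:{lineno}: data before the "
                                     "'#! FIELDS' header (or header missing)")
                parts = line.split()
                if len(parts) != len(fields):
                    raise ParseError(
                        f"{path}:{lineno}: expected {len(fields)} columns, "
                        f"got {len(parts)}")
                try:
                    rows.append([float(p) for p in parts])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from None
    if fields is None:
        raise ParseError(f"{path}: missing '#! FIELDS' header")
    return fields, comments, np.array(rows, dtype=float).reshape(-1, len(fields))


def read_hills(path) -> HillsLog:
    """Parse a PLUMED-dialect HILLS file.

    Expected columns: ``time <cv...> <sigma_cv...> height biasf``.  Raises
    :class:`ParseError` (with a line number) on a missing header, wrong
    row arity, or non-monotone time.
    """
    fields, comments, data = _parse_table(path)
    if len(fields) < 5 or fields[0] != "time" or fields[-2:] != ["height", "biasf"]:
        raise ParseError(f"{path}: not a HILLS header: {' '.join(fields)}")
    n_cv = (len(fields) - 3) // 2
    cv_names = fields[1:1 + n_cv]
    sigma_names = fields[1 + n_cv:1 + 2 * n_cv]
    if sigma_names != [f"sigma_{c}" for c in cv_names]:
        raise ParseError(f"{path}: sigma columns {sigma_names} do not match "
                         f"CVs {cv_names}")
    hills = []
    prev_t = -np.inf
    for i, row in enumerate(data):
        t = row[0]
        if t <= prev_t:
            raise ParseError(f"{path}: non-monotone time at data row {i + 1}")
        prev_t = t
        hills.append(Hill(time=float(t),
                          center=tuple(row[1:1 + n_cv]),
                          sigma=tuple(row[1 + n_cv:1 + 2 * n_cv]),
                          height=float(row[-2]),
                          bias_factor=float(row[-1])))
    meta = {"comments": comments}
    if hills:
        meta["bias_factor"] = hills[0].bias_factor
    return HillsLog(hills=hills, cv_names=tuple(cv_names), metadata=meta)


def write_hills(log: HillsLog, path, provenance: Optional[dict] = None) -> None:
    """Write a HILLS file; deterministic %.6f formatting."""
    n_cv = log.n_cv
    names = list(log.cv_names)[:n_cv]
    header = ["time", *names, *[f"sigma_{c}" for c in names], "height", "biasf"]
    lines = ["#! FIELDS " + " ".join(header)]
    lines += list(log.metadata.get("comments", []))
    if provenance:
        lines += [f"# SET {k} {v}" for k, v in sorted(provenance.items())]
    for h in log.hills:
        row = [h.time, *h.center, *h.sigma, h.height, h.bias_factor]
        lines.append(" ".join(_FLOAT_FMT.format(x) for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_colvar(path) -> pd.DataFrame:
    """Parse a COLVAR-dialect table into a DataFrame (column names from
    the FIELDS header)."""
    fields, _, data = _parse_table(path)
    return pd.DataFrame(data, columns=fields)


def write_colvar(df: pd.DataFrame, path, provenance: Optional[dict] = None) -> None:
    lines = ["#! FIELDS " + " ".join(str(c) for c in df.columns)]
    if provenance:
        lines += [f"# SET {k} {v}" for k, v in sorted(provenance.items())]
    for row in df.itertuples(index=False):
        lines.append(" ".join(_FLOAT_FMT.format(x) for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# structures and trajectories
# --------------------------------------------------------------------------

def _atom_array_to_model(arr, source: str) -> StructureModel:
    serial = (arr.atom_id if "atom_id" in arr.get_annotation_categories()
              else np.arange(1, arr.array_length() + 1))
    return StructureModel(
        serial=np.asarray(serial, dtype=int),
        name=np.asarray(arr.atom_name, dtype=object),
        resname=np.asarray(arr.res_name, dtype=object),
        resid=np.asarray(arr.res_id, dtype=int),
        chain=np.asarray(arr.chain_id, dtype=object),
        element=np.char.upper(np.asarray(arr.element, dtype=str)).astype(object),
        coords=np.asarray(arr.coord, dtype=float) / 10.0,  # Å -> nm
        source=source,
    )


def read_structure(path) -> StructureModel:
    """Read a PDB file into a flat atom table (first model, nm).

    Alternate locations are resolved by highest occupancy.
    """
    from biotite.structure.io.pdb import PDBFile

    pf = PDBFile.read(str(path))
    arr = pf.get_structure(model=1, altloc="occupancy", extra_fields=["atom_id"])
    return _atom_array_to_model(arr, source=str(path))


def read_trajectory(path, topology=None) -> LabeledEnsemble:
    """Read a multi-frame trajectory into a :class:`LabeledEnsemble` (nm).

    Multi-model PDB files are self-contained; XTC/DCD need a PDB
    ``topology``.  Frame/topology atom-count mismatches raise ValueError.
    """
    path = str(path)
    suffix = Path(path).suffix.lower()
    if suffix in (".pdb", ".ent"):
        from biotite.structure.io.pdb import PDBFile

        pf = PDBFile.read(path)
        stack = pf.get_structure(altloc="occupancy", extra_fields=["atom_id"])
        atoms = _atom_array_to_model(stack[0], source=path)
        coords = np.asarray(stack.coord, dtype=float) / 10.0
        return LabeledEnsemble(atoms=atoms, coords=coords)
    if suffix in (".xtc", ".dcd"):
        if topology is None:
            raise ValueError(f"{suffix} trajectories need a PDB topology")
        import MDAnalysis as mda

        atoms = read_structure(topology)
        u = mda.Universe(str(topology), path)
        if len(u.atoms) != atoms.n_atoms:
            raise ValueError(
                f"topology has {atoms.n_atoms} atoms but trajectory frames "
                f"have {len(u.atoms)}")
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                          dtype=float) / 10.0
        return LabeledEnsemble(atoms=atoms, coords=coords)
    raise ValueError(f"unsupported trajectory format: {suffix}")


def write_ensemble_pdb(ens: LabeledEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB (coordinates nm -> Å)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = ens.atoms.n_atoms
    template = struc.AtomArray(n)
    template.atom_name = np.asarray(ens.atoms.name, dtype="U6")
    template.res_name = np.asarray(ens.atoms.resname, dtype="U5")
    template.res_id = np.asarray(ens.atoms.resid, dtype=int)
    template.chain_id = np.asarray(ens.atoms.chain, dtype="U4")
    template.element = np.asarray(ens.atoms.element, dtype="U2")
    template.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([template] * ens.n_frames)
    stack.coord = np.asarray(ens.coords, dtype=np.float32) * 10.0
    pf = PDBFile()
    pf.set_structure(stack)
    pf.write(str(path))


def read_residue_pairs(path) -> list[tuple[int, int]]:
    """Residue-pair list: two whitespace-separated residue numbers per
    line, ``#`` comments allowed."""
    pairs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two residue "
                                 f"numbers, got {len(parts)} tokens")
            try:
                pairs.append((int(parts[0]), int(parts[1])))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer residue "
                                 "number") from None
    return pairs


# --------------------------------------------------------------------------
# FES grid files
# --------------------------------------------------------------------------

def write_fes(fes: FreeEnergySurface, path, provenance: Optional[dict] = None) -> None:
    """Delimited text grid with a header recording axes, γ, T and the
    reference convention."""
    lines = [
        "#! FIELDS " + " ".join(fes.axis_names) + " free",
        f"# SET reference {fes.reference}",
        f"# SET temperature {_FLOAT_FMT.format(fes.temperature)}",
        f"# SET bias_factor {_FLOAT_FMT.format(fes.bias_factor)}",
    ]
    if provenance:
        lines += [f"# SET {k} {v}" for k, v in sorted(provenance.items())]
    if fes.ndim == 1:
        for x, f in zip(fes.axes[0], fes.values):
            lines.append(f"{_FLOAT_FMT.format(x)} {_FLOAT_FMT.format(f)}")
    else:
        for i, x in enumerate(fes.axes[0]):
            for j, y in enumerate(fes.axes[1]):
                lines.append(" ".join(_FLOAT_FMT.format(v)
                                      for v in (x, y, fes.values[i, j])))
    Path(path).write_text("\n".join(lines) + "\n")


def read_fes(path) -> FreeEnergySurface:
    fields, comments, data = _parse_table(path)
    if fields[-1] != "free":
        raise ParseError(f"{path}: last column must be 'free'")
    meta = {}
    for line in comments:
        parts = line.split()
        if len(parts) >= 4 and parts[0] == "#" and parts[1] == "SET":
            meta[parts[2]] = parts[3]
    axis_names = tuple(fields[:-1])
    kwargs = dict(reference=meta.get("reference", "minimum"),
                  temperature=float(meta.get("temperature", 300.0)),
                  bias_factor=float(meta.get("bias_factor", "nan")),
                  axis_names=axis_names)
    if len(axis_names) == 1:
        return FreeEnergySurface(axes=[data[:, 0]], values=data[:, 1], **kwargs)
    x = np.unique(data[:, 0])
    y = np.unique(data[:, 1])
    if x.size * y.size != data.shape[0]:
        raise ParseError(f"{path}: grid is not a complete cartesian product")
    values = np.full((x.size, y.size), np.nan)
    xi = np.searchsorted(x, data[:, 0])
    yi = np.searchsorted(y, data[:, 1])
    values[xi, yi] = data[:, 2]
    return FreeEnergySurface(axes=[x, y], values=values, **kwargs)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FunnelConfig(_StrictModel):
    """Funnel restraint; ``axis`` is normalized on load."""

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)   # nm
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    z_cc: float = Field(0.5, gt=0)      # nm
    r_cyl: float = Field(0.1, gt=0)     # nm
    alpha: float = Field(1.1, gt=0)     # rad
    k_wall: float = Field(10000.0, gt=0)  # kJ mol^-1 nm^-2

    def to_geometry(self) -> FunnelGeometry:
        axis = np.asarray(self.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        return FunnelGeometry(origin=np.asarray(self.origin, dtype=float),
                              axis=axis, z_cc=self.z_cc, r_cyl=self.r_cyl,
                              alpha=self.alpha, k_wall=self.k_wall)


class ContactConfig(_StrictModel):
    """Eq.-1 native-contact parameters (production defaults)."""

    beta: float = Field(50.0, gt=0)     # nm^-1
    lam: float = Field(1.8, gt=0)
    r0: float = Field(0.45, gt=0)       # nm
    cutoff: float = Field(0.45, gt=0)   # nm, pair-identification cutoff


class MetadConfig(_StrictModel):
    """Well-tempered deposition schedule (production defaults)."""

    height0: float = Field(1.0, gt=0)        # kJ/mol
    sigma_cv1: float = Field(0.1, gt=0)      # nm
    sigma_cv2: float = Field(10.0, gt=0)
    pace_ps: float = Field(2.0, gt=0)        # ps between depositions
    bias_factor: float = Field(16.0, gt=1)
    temperature: float = Field(300.0, gt=0)  # K

    def to_params(self, timestep_ps: float, n_cv: int = 2) -> MetaDParams:
        sigma = (self.sigma_cv1, self.sigma_cv2)[:n_cv]
        return MetaDParams(height0=self.height0, sigma=sigma,
                           pace=max(1, round(self.pace_ps / timestep_ps)),
                           bias_factor=self.bias_factor,
                           temperature=self.temperature)


class RamdConfig(_StrictModel):
    """RAMD parameters in their conventional units (production defaults)."""

    force_magnitude: float = Field(16.0, gt=0)       # kcal mol^-1 Å^-1
    checkpoint_fs: float = Field(100.0, gt=0)        # fs
    threshold_A: float = Field(0.025, gt=0)          # Å

    def to_state(self, direction=(0.0, 0.0, 1.0)) -> RamdState:
        d = np.asarray(direction, dtype=float)
        return RamdState(force_magnitude=self.force_magnitude,
                         direction=d / np.linalg.norm(d),
                         checkpoint_interval=self.checkpoint_fs,
                         threshold=self.threshold_A)


class RunConfig(_StrictModel):
    """Top-level run configuration; unknown keys are rejected."""

    preset: str = "double_well_1d"
    preset_params: dict = Field(default_factory=dict)
    funnel: Optional[FunnelConfig] = None
    contacts: ContactConfig = Field(default_factory=ContactConfig)
    metad: MetadConfig = Field(default_factory=MetadConfig)
    ramd: RamdConfig = Field(default_factory=RamdConfig)
    seed: int = 0
    timestep_ps: float = Field(0.004, gt=0)
    n_steps: int = Field(100000, ge=0)
    temperature: float = Field(300.0, gt=0)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration, for provenance headers."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance(cfg: Optional[RunConfig] = None, seed: Optional[int] = None) -> dict:
    out = {"version": PACKAGE_VERSION}
    if cfg is not None:
        out["config_hash"] = config_hash(cfg)
        out["seed"] = cfg.seed if seed is None else seed
    elif seed is not None:
        out["seed"] = seed
    return out
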