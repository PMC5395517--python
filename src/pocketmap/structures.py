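"""Protein structure I/O, solvent accessibility, superposition and quality filters.

Structures are held as a flat, ordered list of :class:`Atom` records classified
into protein / ligand / water / other. Parsing goes through gemmi, which
handles both fixed-column PDB and mmCIF; alternate locations are resolved to
the highest-occupancy conformer before the atom list is built.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

AtomRecord = Literal["protein", "ligand", "water", "other"]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

DEFAULT_FALLBACK_RADIUS = 1.7


class StructureError(ValueError):
    """Base class for structure-level errors."""


class StructureParseError(StructureError):
    pass


class EmptyStructureError(StructureError):
    pass


class DegeneratePairingError(StructureError):
    pass


@dataclass
class Atom:
    """A single atom with its source identity and record classification."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coords: np.ndarray
    record: AtomRecord
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.serial}: coords must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.serial}: empty element")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Structure:
    """An ordered collection of atoms from one model of one file."""

    id: str
    atoms: list[Atom]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self, indices: Optional[Iterable[int]] = None) -> np.ndarray:
        if indices is None:
            return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)
        return np.array([self.atoms[i].coords for i in indices], dtype=float).reshape(-1, 3)

    def indices(
        self,
        record: Optional[AtomRecord] = None,
        heavy_only: bool = False,
    ) -> list[int]:
        out = []
        for i, a in enumerate(self.atoms):
            if record is not None and a.record != record:
                continue
            if heavy_only and a.is_hydrogen:
                continue
            out.append(i)
        return out

    def protein_heavy_indices(self) -> list[int]:
        return self.indices(record="protein", heavy_only=True)

    def ligand_heavy_indices(self, residue_name: Optional[str] = None) -> list[int]:
        out = []
        for i in self.indices(record="ligand", heavy_only=True):
            if residue_name is None or self.atoms[i].residue_name == residue_name:
                out.append(i)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every coordinate mapped to R @ x + t."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        atoms = []
        for a in self.atoms:
            atoms.append(
                Atom(
                    serial=a.serial,
                    name=a.name,
                    element=a.element,
                    residue_name=a.residue_name,
                    residue_number=a.residue_number,
                    chain_id=a.chain_id,
                    coords=rotation @ a.coords + translation,
                    record=a.record,
                    occupancy=a.occupancy,
                    b_factor=a.b_factor,
                )
            )
        return Structure(id=self.id, atoms=atoms, provenance=dict(self.provenance))


def _classify(residue: gemmi.Residue) -> AtomRecord:
    if residue.name.strip().upper() in _WATER_NAMES:
        return "water"
    if residue.het_flag == "A":
        return "protein"
    if residue.het_flag == "H":
        return "ligand"
    return "other"


def read_structure(path: str | Path, dialect: Optional[str] = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    ATOM records are classified as protein; HETATM waters (HOH/WAT) as water;
    every other HETATM as ligand. Alternate locations are resolved to the
    highest-occupancy conformer (ties by altloc letter order). Hydrogens are
    retained but excluded by heavy-atom consumers.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = gemmi.CoorFormat.Unknown
    if dialect == "pdb":
        fmt = gemmi.CoorFormat.Pdb
    elif dialect == "mmcif":
        fmt = gemmi.CoorFormat.Mmcif
    elif dialect is not None:
        raise ValueError(f"unknown dialect: {dialect!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"failed to parse {path}: {exc}") from exc
    st.setup_entities()

    atoms: list[Atom] = []
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    for chain in model:
        for residue in chain:
            record = _classify(residue)
            # altloc resolution: highest occupancy wins, ties by letter order
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            for name in by_name:
                group = sorted(by_name[name], key=lambda a: (-a.occ, a.altloc or "~"))
                atom = group[0]
                atoms.append(
                    Atom(
                        serial=atom.serial,
                        name=name,
                        element=atom.element.name.upper() or "X",
                        residue_name=residue.name.strip(),
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        record=record,
                        occupancy=atom.occ,
                        b_factor=atom.b_iso,
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"{path}: zero atoms")
    return Structure(
        id=path.stem,
        atoms=atoms,
        provenance={"path": str(path), "dialect": dialect or "auto"},
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as fixed-column PDB (via gemmi)."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in structure.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        chain = chains[a.chain_id]
        if len(chain) == 0 or chain[-1].seqid.num != a.residue_number or chain[-1].name != a.residue_name:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "A" if a.record == "protein" else "H"
            chain.add_residue(res)
        res = chain[-1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element.capitalize())
        at.pos = gemmi.Position(*a.coords)
        at.occ = a.occupancy
        at.b_iso = a.b_factor
        at.serial = a.serial
        res.add_atom(at)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def load_vdw_radii() -> dict[str, float]:
    with resources.files("pocketmap").joinpath("data/vdw_radii.json").open() as fh:
        return {k.upper(): float(v) for k, v in json.load(fh).items()}


_VDW = None


def vdw_radius(element: str, fallback: float = DEFAULT_FALLBACK_RADIUS) -> float:
    global _VDW
    if _VDW is None:
        _VDW = load_vdw_radii()
    el = element.upper()
    if el not in _VDW:
        logger.warning("unknown element %r: falling back to radius %.2f", element, fallback)
        return fallback
    return _VDW[el]


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _local_frame(rel: np.ndarray) -> np.ndarray:
    """Orthonormal frame (rows) derived from neighbour displacement vectors.

    The frame rotates with the structure, so the discretized buried/exposed
    classification — and hence every area — is exactly invariant under global
    rigid motion rather than invariant only in the n_points limit.
    """
    norms = np.linalg.norm(rel, axis=1)
    units = rel / norms[:, None]
    z = units.sum(axis=0)
    if np.linalg.norm(z) < 1e-8:
        z = units[int(np.argmin(norms))]
    z = z / np.linalg.norm(z)
    ref = rel[int(np.argmin(norms))]
    x = ref - (ref @ z) * z
    if np.linalg.norm(x) < 1e-8:
        ref = rel[int(np.argmax(norms))]
        x = ref - (ref @ z) * z
    if np.linalg.norm(x) < 1e-8:  # all neighbours along z: any transverse axis
        x = np.array([z[1], -z[0], 0.0]) if abs(z[2]) > 0.9 else np.cross(z, [0.0, 0.0, 1.0])
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def atom_sasa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    include_ligand: bool = False,
    fallback_radius: float = DEFAULT_FALLBACK_RADIUS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley), in A^2.

    Areas are computed for protein heavy atoms (optionally also ligand heavy
    atoms as occluders and targets); hydrogens and waters always get area 0.
    The test-point sphere is a fixed golden-spiral set, so results are
    deterministic for a given ``n_points``.
    """
    records = {"protein"} | ({"ligand"} if include_ligand else set())
    idx = [i for i in structure.indices() if structure.atoms[i].record in records
           and not structure.atoms[i].is_hydrogen]
    if not any(structure.atoms[i].record == "protein" for i in idx):
        raise EmptyStructureError("no protein heavy atoms for SASA")

    coords = structure.coords(idx)
    radii = np.array([vdw_radius(structure.atoms[i].element, fallback_radius) for i in idx])
    ext = radii + probe
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    areas_sub = np.zeros(len(idx))
    for k in range(len(idx)):
        neigh = [j for j in tree.query_ball_point(coords[k], ext[k] + ext.max())
                 if j != k and np.linalg.norm(coords[j] - coords[k]) < ext[k] + ext[j]]
        if neigh:
            rel = coords[neigh] - coords[k]
            frame = _local_frame(rel)
            test = coords[k] + ext[k] * (pts @ frame)
            d = np.linalg.norm(test[:, None, :] - coords[neigh][None, :, :], axis=2)
            buried = (d < ext[neigh][None, :]).any(axis=1)
            n_free = int((~buried).sum())
        else:
            n_free = n_points
        areas_sub[k] = 4.0 * math.pi * ext[k] ** 2 * n_free / n_points
    areas = np.zeros(len(structure.atoms))
    areas[idx] = areas_sub
    return areas


def surface_atoms(
    structure: Structure,
    min_area: float = 0.5,
    sasa: Optional[np.ndarray] = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> set[int]:
    """Protein heavy atoms with solvent accessibility >= ``min_area`` A^2."""
    if sasa is None:
        sasa = atom_sasa(structure, probe=probe, n_points=n_points)
    return {
        i
        for i in structure.protein_heavy_indices()
        if sasa[i] >= min_area
    }


def superpose(
    mobile_coords: np.ndarray,
    reference_coords: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch least-squares rigid superposition of paired coordinates.

    Returns ``(rotation, translation, rmsd)`` with the proper rotation
    (det = +1) and translation mapping mobile onto reference:
    ``x -> R @ x + t``. RMSD is evaluated over the pairing after transform.
    """
    mob = np.asarray(mobile_coords, float)
    ref = np.asarray(reference_coords, float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise DegeneratePairingError("pairing must give two equal (n, 3) arrays")
    n = mob.shape[0]
    if n < 3:
        raise DegeneratePairingError("need at least 3 atom pairs")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # collinear pairings leave a free rotation about the common axis
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise DegeneratePairingError("pairing is collinear or degenerate")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return R, t, rmsd


def superpose_structures(
    mobile: Structure,
    reference: Structure,
    pairing: Sequence[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray, float]:
    mob = mobile.coords([i for i, _ in pairing])
    ref = reference.coords([j for _, j in pairing])
    return superpose(mob, ref)


# --- crystallographic quality -------------------------------------------------

@dataclass
class QualityRecord:
    """Per-structure crystallographic quality metrics; missing values are None."""

    structure_id: str
    resolution: Optional[float] = None
    rscc: Optional[float] = None
    rsr: Optional[float] = None
    owab: Optional[float] = None
    rfree: Optional[float] = None
    dpi: Optional[float] = None


_QUALITY_FIELDS = ("resolution", "rscc", "rsr", "owab", "rfree", "dpi")

#: protein-centric bounds used to curate structure sets:
#: resolution 2.5 A or better, Rfree <= 0.3, DPI <= 0.5 A
PROTEIN_QUALITY_BOUNDS: dict[str, tuple] = {
    "resolution": ("le", 2.5),
    "rfree": ("le", 0.3),
    "dpi": ("le", 0.5),
}

#: ligand-centric bounds: resolution 2.7 A or better, ligand RSCC >= 0.9,
#: ligand RSR <= 0.15, ligand OWAB within [5, 50] A^2
LIGAND_QUALITY_BOUNDS: dict[str, tuple] = {
    "resolution": ("le", 2.7),
    "rscc": ("ge", 0.9),
    "rsr": ("le", 0.15),
    "owab": ("range", (5.0, 50.0)),
}


def quality_filter(
    records: Iterable[QualityRecord],
    thresholds: Mapping[str, tuple],
) -> list[str]:
    """Structure ids whose records satisfy every named bound.

    ``thresholds`` maps a QualityRecord field to ``("le", x)``, ``("ge", x)``
    or ``("range", (lo, hi))``. A record with a missing thresholded field
    fails (and is logged); empty thresholds pass everything.
    """
    for name in thresholds:
        if name not in _QUALITY_FIELDS:
            raise ValueError(f"unknown quality field: {name!r}")
    passing = []
    for rec in records:
        ok = True
        for name, bound in thresholds.items():
            value = getattr(rec, name)
            if value is None:
                logger.info("quality_filter: %s missing %s -> fail", rec.structure_id, name)
                ok = False
                break
            kind = bound[0]
            if kind == "le":
                ok = value <= bound[1]
            elif kind == "ge":
                ok = value >= bound[1]
            elif kind == "range":
                lo, hi = bound[1]
                ok = lo <= value <= hi
            else:
                raise ValueError(f"unknown bound kind: {kind!r}")
            if not ok:
                break
        if ok:
            passing.append(rec.structure_id)
    return passing


def read_quality_table(path: str | Path) -> list[QualityRecord]:
    """Read a delimited (TSV/CSV) table with a header naming quality fields."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if "structure_id" not in df.columns:
        raise ValueError(f"{path}: quality table needs a structure_id column")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for name in _QUALITY_FIELDS:
            if name in df.columns and pd.notna(row[name]):
                kwargs[name] = float(row[name])
        records.append(QualityRecord(structure_id=str(row["structure_id"]), **kwargs))
    return records
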