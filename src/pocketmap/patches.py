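"""Binding-site patches: surface shape points plus typed pharmacophore centres.

A patch is the unit of comparison. Its shape is the set of surface protein
atom centres around a (pseudo-)ligand; its chemistry ("color") is a set of
pseudocenters of five interaction types — hydrogen-bond donor, hydrogen-bond
acceptor, anion, cation and hydrophobe — placed by a residue/atom-name rule
table (rings and charged groups collapse to centroids). Patches come either
from a bound ligand (surface atoms within a distance cutoff, default 4 A) or
from a detected cavity via the pseudo-ligand rule: the cavity's tangent
surface atoms, dilated by a small ``site_size`` (default 0.3 A).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .cavities import Cavity
from .structures import Structure, surface_atoms

logger = logging.getLogger(__name__)

PharmacophoreType = Literal["donor", "acceptor", "anion", "cation", "hydrophobe"]
PHARMACOPHORE_TYPES: tuple[str, ...] = ("donor", "acceptor", "anion", "cation", "hydrophobe")


class PatchError(ValueError):
    pass


class EmptyPatchError(PatchError):
    pass


@dataclass
class Pseudocenter:
    position: np.ndarray
    ptype: PharmacophoreType
    source_atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        if self.ptype not in PHARMACOPHORE_TYPES:
            raise PatchError(f"unknown pharmacophore type: {self.ptype!r}")


@dataclass
class Patch:
    """Shape points + pharmacophore pseudocenters for one binding site."""

    id: str
    structure_id: str
    origin: tuple[str, str]  # ("ligand" | "cavity", source id)
    atom_indices: tuple[int, ...]
    shape_points: np.ndarray
    pseudocenters: list[Pseudocenter]

    def __post_init__(self) -> None:
        self.shape_points = np.asarray(self.shape_points, float).reshape(-1, 3)
        if len(self.shape_points) == 0:
            raise EmptyPatchError(f"patch {self.id}: no shape points")
        atom_set = set(self.atom_indices)
        for pc in self.pseudocenters:
            if not set(pc.source_atoms) <= atom_set:
                raise PatchError(
                    f"patch {self.id}: pseudocenter sources outside the patch atom set"
                )

    def color_points(self) -> tuple[np.ndarray, list[str]]:
        if not self.pseudocenters:
            return np.zeros((0, 3)), []
        return (
            np.array([pc.position for pc in self.pseudocenters]),
            [pc.ptype for pc in self.pseudocenters],
        )

    def type_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in PHARMACOPHORE_TYPES}
        for pc in self.pseudocenters:
            counts[pc.ptype] += 1
        return counts

    def to_json(self) -> str:
        return json.dumps(
            {
                "id": self.id,
                "structure_id": self.structure_id,
                "origin": list(self.origin),
                "atom_indices": list(self.atom_indices),
                "shape_points": self.shape_points.tolist(),
                "pseudocenters": [
                    {
                        "position": pc.position.tolist(),
                        "ptype": pc.ptype,
                        "source_atoms": list(pc.source_atoms),
                    }
                    for pc in self.pseudocenters
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "Patch":
        doc = json.loads(text)
        return cls(
            id=doc["id"],
            structure_id=doc["structure_id"],
            origin=tuple(doc["origin"]),
            atom_indices=tuple(doc["atom_indices"]),
            shape_points=np.array(doc["shape_points"], float),
            pseudocenters=[
                Pseudocenter(
                    position=np.array(pc["position"], float),
                    ptype=pc["ptype"],
                    source_atoms=tuple(pc["source_atoms"]),
                )
                for pc in doc["pseudocenters"]
            ],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Patch":
        return cls.from_json(Path(path).read_text())


_TABLE = None


def load_pharmacophore_table() -> dict:
    global _TABLE
    if _TABLE is None:
        with resources.files("pocketmap").joinpath("data/pharmacophores.json").open() as fh:
            _TABLE = json.load(fh)
    return _TABLE


def type_pharmacophores(
    structure: Structure,
    atom_subset: Iterable[int],
    his_mode: str = "acceptor",
    ring_mode: str = "centroid",
) -> list[Pseudocenter]:
    """Place typed pseudocenters on a subset of protein atoms.

    Typing is by residue and atom name from the bundled rule table: charged
    groups (Asp/Glu carboxylates, Arg guanidinium) and aromatic rings collapse
    to centroid pseudocenters (``ring_mode="atoms"`` keeps ring carbons as
    individual hydrophobes); Ser/Thr/Tyr hydroxyls emit both a donor and an
    acceptor. Histidine is neutral (ring-nitrogen acceptors) unless
    ``his_mode="cation"``. A group pseudocenter is emitted only when every
    group atom is inside the subset. Unknown atoms of standard residues are
    skipped; atoms of non-standard residues fall back to element typing.
    """
    table = load_pharmacophore_table()
    backbone = table["backbone"]
    residues = table["residues"]
    fallback = table["element_fallback"]

    subset = sorted(set(atom_subset))
    by_residue: dict[tuple[str, int, str], list[int]] = {}
    for i in subset:
        a = structure.atoms[i]
        by_residue.setdefault((a.chain_id, a.residue_number, a.residue_name), []).append(i)

    out: list[Pseudocenter] = []
    for (_, _, res_name), members in sorted(by_residue.items(), key=lambda kv: kv[1][0]):
        res_name = res_name.upper()
        rules = residues.get(res_name)
        name_to_idx = {structure.atoms[i].name.upper(): i for i in members}
        consumed: set[str] = set()

        if rules is not None:
            groups = list(rules.get("groups", []))
            if res_name == "HIS" and his_mode == "cation":
                groups = [table["his_cation_group"]]
            for group in groups:
                wanted = [n.upper() for n in group["atoms"]]
                if not all(n in name_to_idx for n in wanted):
                    continue
                if group["type"] == "hydrophobe" and ring_mode == "atoms":
                    for n in wanted:
                        out.append(
                            Pseudocenter(
                                position=structure.atoms[name_to_idx[n]].coords,
                                ptype="hydrophobe",
                                source_atoms=(name_to_idx[n],),
                            )
                        )
                else:
                    idxs = tuple(name_to_idx[n] for n in wanted)
                    centroid = structure.coords(idxs).mean(axis=0)
                    out.append(
                        Pseudocenter(position=centroid, ptype=group["type"], source_atoms=idxs)
                    )
                consumed.update(wanted)
            singles = rules.get("singles", {})
            if res_name == "HIS" and his_mode == "cation":
                singles = {}
            for n, types in singles.items():
                n = n.upper()
                if n in name_to_idx and n not in consumed:
                    for t in types:
                        out.append(
                            Pseudocenter(
                                position=structure.atoms[name_to_idx[n]].coords,
                                ptype=t,
                                source_atoms=(name_to_idx[n],),
                            )
                        )
                    consumed.add(n)

        for n, i in name_to_idx.items():
            if n in consumed:
                continue
            if n in backbone:
                out.append(
                    Pseudocenter(
                        position=structure.atoms[i].coords,
                        ptype=backbone[n],
                        source_atoms=(i,),
                    )
                )
            elif rules is None:
                el = structure.atoms[i].element.upper()
                if el in fallback:
                    out.append(
                        Pseudocenter(
                            position=structure.atoms[i].coords,
                            ptype=fallback[el],
                            source_atoms=(i,),
                        )
                    )
                else:
                    logger.debug("untyped atom %s/%s (element %s)", res_name, n, el)
    return out


def _build_patch(
    structure: Structure,
    atom_indices: Sequence[int],
    origin: tuple[str, str],
    patch_id: Optional[str] = None,
    his_mode: str = "acceptor",
    ring_mode: str = "centroid",
) -> Patch:
    atom_indices = tuple(sorted(atom_indices))
    if not atom_indices:
        raise EmptyPatchError(f"{origin}: no atoms in range")
    return Patch(
        id=patch_id or f"{structure.id}:{origin[0]}:{origin[1]}",
        structure_id=structure.id,
        origin=origin,
        atom_indices=atom_indices,
        shape_points=structure.coords(atom_indices),
        pseudocenters=type_pharmacophores(
            structure, atom_indices, his_mode=his_mode, ring_mode=ring_mode
        ),
    )


def patch_from_ligand(
    structure: Structure,
    ligand_atoms: Iterable[int],
    cutoff: float = 4.0,
    surface: Optional[set[int]] = None,
    patch_id: Optional[str] = None,
    **typing_kwargs,
) -> Patch:
    """Patch of surface protein atoms within ``cutoff`` of ligand heavy atoms."""
    ligand_atoms = [i for i in ligand_atoms if not structure.atoms[i].is_hydrogen]
    if not ligand_atoms:
        raise PatchError("empty ligand")
    if surface is None:
        surface = surface_atoms(structure)
    surf = sorted(surface)
    if not surf:
        raise EmptyPatchError("structure has no surface atoms")
    tree = cKDTree(structure.coords(ligand_atoms))
    d, _ = tree.query(structure.coords(surf))
    chosen = [surf[k] for k in np.nonzero(d <= cutoff)[0]]
    if not chosen:
        raise EmptyPatchError(f"no surface atoms within {cutoff} A of the ligand")
    lig_res = structure.atoms[ligand_atoms[0]].residue_name
    return _build_patch(
        structure, chosen, ("ligand", lig_res), patch_id=patch_id, **typing_kwargs
    )


def pseudo_ligand_atoms(
    structure: Structure,
    cavity: Cavity,
    surface: Optional[set[int]] = None,
) -> list[int]:
    """Surface protein atoms tangent to the cavity's alpha spheres.

    These stand in for a bound ligand when building ligand-independent
    patches; a cavity with no surface-exposed tangent atoms is an error.
    """
    if len(cavity) == 0:
        raise PatchError("empty cavity")
    if surface is None:
        surface = surface_atoms(structure)
    out = sorted(cavity.tangent_atom_indices() & surface)
    if not out:
        raise EmptyPatchError(f"cavity {cavity.id} is not surface-exposed")
    return out


def patch_from_cavity(
    structure: Structure,
    cavity: Cavity,
    site_size: float = 0.3,
    surface: Optional[set[int]] = None,
    patch_id: Optional[str] = None,
    **typing_kwargs,
) -> Patch:
    """Ligand-independent patch from a detected cavity.

    Patch atoms are the surface protein atoms whose centre lies within
    ``site_size`` of any pseudo-ligand atom centre; at the 0.3 A default this
    is essentially the pseudo-ligand set itself plus exact-overlap neighbours.
    """
    if surface is None:
        surface = surface_atoms(structure)
    pseudo = pseudo_ligand_atoms(structure, cavity, surface=surface)
    surf = sorted(surface)
    tree = cKDTree(structure.coords(pseudo))
    d, _ = tree.query(structure.coords(surf))
    chosen = [surf[k] for k in np.nonzero(d <= site_size)[0]]
    chosen = sorted(set(chosen) | set(pseudo))
    return _build_patch(
        structure, chosen, ("cavity", cavity.id), patch_id=patch_id, **typing_kwargs
    )


def write_patch_pdb(patch: Patch, path: str | Path) -> None:
    """Pseudo-atom PDB for visual inspection (shape as C, centres by type)."""
    element_for = {"donor": "N", "acceptor": "O", "anion": "O", "cation": "N", "hydrophobe": "C"}
    lines = []
    serial = 1
    for p in patch.shape_points:
        lines.append(
            f"HETATM{serial:5d}  C   SHP A{1:4d}    "
            f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00           C"
        )
        serial += 1
    for pc in patch.pseudocenters:
        el = element_for[pc.ptype]
        res = pc.ptype[:3].upper()
        p = pc.position
        lines.append(
            f"HETATM{serial:5d}  {el:<3s}{res} B{2:4d}    "
            f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00           {el}"
        )
        serial += 1
    Path(path).write_text("\n".join(lines) + "\nEND\n")
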