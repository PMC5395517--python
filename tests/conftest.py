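"""Shared fixtures: toy structures and a detected-pocket test protein."""

from __future__ import annotations

import numpy as np
import pytest

from pocketmap import (
    PocketSpec,
    Structure,
    detect_cavities,
    make_pocket_protein,
    match_cavity_to_ligand,
    surface_atoms,
)
from pocketmap.structures import Atom

MIXED_LINING = ("donor", "acceptor", "anion", "cation", "hydrophobe")


def protein_from_coords(coords, element="C", name="CA", residue_name="GLY") -> Structure:
    atoms = [
        Atom(
            serial=i + 1,
            name=name,
            element=element,
            residue_name=residue_name,
            residue_number=i + 1,
            chain_id="A",
            coords=np.asarray(c, float),
            record="protein",
        )
        for i, c in enumerate(coords)
    ]
    return Structure(id="toy", atoms=atoms)


def default_pocket_spec(**overrides) -> PocketSpec:
    kwargs = dict(
        center=np.array([6.0, 0.0, 0.0]),
        mouth_direction=np.array([1.0, 0.0, 0.0]),
        depth=9.0,
        width=7.0,
        lining_types=MIXED_LINING,
    )
    kwargs.update(overrides)
    return PocketSpec(**kwargs)


TOY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
HETATM    3  O   HOH A 101       5.000   5.000   5.000  1.00 20.00           O
HETATM    4  PA  ATP A 201       1.000   2.000   3.000  1.00 15.00           P
END
"""


@pytest.fixture()
def toy_pdb_path(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture(scope="session")
def pocket_protein():
    """One 420-atom toy protein with a mixed-lining pocket, plus ground truth."""
    structure, truths = make_pocket_protein(
        n_atoms=420, shell_radius=14.0, pockets=[default_pocket_spec()], seed=7
    )
    return structure, truths


@pytest.fixture(scope="session")
def pocket_surface(pocket_protein):
    structure, _ = pocket_protein
    return surface_atoms(structure)


@pytest.fixture(scope="session")
def matched_cavity(pocket_protein):
    structure, truths = pocket_protein
    cavities = detect_cavities(structure)
    ligand = structure.coords(
        [i for i, a in enumerate(structure.atoms) if a.record == "ligand"]
    )
    cavity = match_cavity_to_ligand(cavities, ligand)
    assert cavity is not None
    return cavity
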