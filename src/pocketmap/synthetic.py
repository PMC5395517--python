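"""Deterministic toy protein structures with known pockets, plus labeled rankings.

The generator packs carbon pseudo-atoms on a jittered cubic lattice filling a
ball ("the protein"), carves each requested pocket as a capsule-shaped
invagination reaching the surface, renames the atoms lining the carved region
so that pharmacophore typing realizes the requested interaction types, and
drops a small rigid pseudo-ligand at the pocket centre. Ground truth (lining
atom serials, pocket centres, ligand serials) travels with the structure so
every downstream stage can be checked without real data.

None of this is physically realistic geometry; it exists to give the cavity
detector, patch builder and comparison engine inputs with a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .structures import Atom, Structure, surface_atoms, write_structure

PharmacophoreType = Literal["donor", "acceptor", "anion", "cation", "hydrophobe"]

#: single-atom residues whose (residue, atom) names type as each interaction
#: type under the bundled pharmacophore table
_TYPE_ATOMS: dict[str, tuple[str, str, str]] = {
    "donor": ("GLY", "N", "N"),
    "acceptor": ("GLY", "O", "O"),
    "anion": ("GLY", "OXT", "O"),
    "cation": ("LYS", "NZ", "N"),
    "hydrophobe": ("ALA", "CB", "C"),
}

_FILLER = ("GLY", "CA", "C")


class SyntheticError(ValueError):
    pass


@dataclass
class PocketSpec:
    """Geometry and chemistry of one carved pocket.

    The pocket occupies a capsule of radius ``width / 2`` around the segment
    from ``center`` (the buried end) towards ``center + depth * mouth_direction``
    (the mouth, which should reach the surface). ``lining_types`` is
    distributed over the atoms lining the carved region, keyed to each atom's
    lattice position so identical specs present identical chemistry.
    """

    center: np.ndarray
    mouth_direction: np.ndarray
    depth: float
    width: float
    lining_types: tuple[PharmacophoreType, ...]

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        d = np.asarray(self.mouth_direction, float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise SyntheticError("mouth_direction must be non-zero")
        self.mouth_direction = d / norm
        if self.depth <= 0 or self.width <= 0:
            raise SyntheticError("depth and width must be positive")
        if not self.lining_types:
            raise SyntheticError("lining_types must be non-empty")

    @property
    def axis_end(self) -> np.ndarray:
        return self.center + self.depth * self.mouth_direction

    @property
    def midpoint(self) -> np.ndarray:
        return self.center + 0.5 * self.depth * self.mouth_direction


@dataclass
class PocketTruth:
    """Ground truth for one generated pocket.

    ``lining_serials`` is the pocket atom set proper: renamed lining atoms
    that are solvent-accessible (on the surface); ``relined_serials`` is the
    full set of atoms renamed to lining residues, including any that ended up
    buried in the wall.
    """

    spec: PocketSpec
    lining_serials: list[int]
    relined_serials: list[int]
    ligand_serials: list[int]
    center: np.ndarray  # capsule midpoint, the nominal pocket centre


@dataclass
class RankingFixture:
    """Scores plus positive/negative labels for retrieval-metric tests."""

    scores: np.ndarray
    labels: np.ndarray  # boolean, True = positive
    seed: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        self.labels = np.asarray(self.labels, bool)
        if self.scores.shape != self.labels.shape:
            raise SyntheticError("scores and labels must have equal length")
        if not (self.labels.any() and (~self.labels).any()):
            raise SyntheticError("need at least one positive and one negative")


def _segment_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0) if denom > 0 else np.zeros(len(points))
    closest = a + t[:, None] * ab
    return np.linalg.norm(points - closest, axis=1)


def _capsule_gap(p1: PocketSpec, p2: PocketSpec, samples: int = 32) -> float:
    t = np.linspace(0, 1, samples)
    pts1 = p1.center + t[:, None] * (p1.axis_end - p1.center)
    d = _segment_distances(pts1, p2.center, p2.axis_end)
    return float(d.min()) - (p1.width + p2.width) / 2.0


def _ligand_offsets(spec: PocketSpec) -> np.ndarray:
    """Rigid 16-atom pseudo-ligand filling the pocket: four 4-atom rosettes
    along the capsule axis, symmetric about the midpoint. Offsets are built
    in a frame derived from the mouth direction, so the ligand is a pure
    function of the pocket spec."""
    u = spec.mouth_direction
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    offsets = []
    for frac in (-0.4, -0.15, 0.15, 0.4):
        axial = frac * spec.depth * u
        for k in range(4):
            angle = np.pi / 2 * k + (0.3 * frac)
            offsets.append(axial + 1.5 * (np.cos(angle) * v + np.sin(angle) * w))
    return np.array(offsets)


def make_pocket_protein(
    n_atoms: int,
    shell_radius: float,
    pockets: Sequence[PocketSpec],
    seed: int,
    jitter: float = 0.25,
    lining_shell: float = 2.2,
    structure_id: str | None = None,
) -> tuple[Structure, list[PocketTruth]]:
    """Build a toy pocket protein; deterministic for identical arguments.

    ``n_atoms`` sets the target atom count, which fixes the lattice spacing
    for a ball of radius ``shell_radius``. Pockets must not overlap.
    """
    pockets = list(pockets)
    for i in range(len(pockets)):
        for j in range(i + 1, len(pockets)):
            if _capsule_gap(pockets[i], pockets[j]) < 0:
                raise SyntheticError(f"pockets {i} and {j} overlap")

    volume = 4.0 / 3.0 * np.pi * shell_radius**3
    spacing = (volume / max(n_atoms, 8)) ** (1.0 / 3.0)
    k = int(np.ceil(shell_radius / spacing))
    ints = np.arange(-k, k + 1)
    gx, gy, gz = np.meshgrid(ints, ints, ints, indexing="ij")
    grid_idx = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    grid = grid_idx * spacing
    inside = np.linalg.norm(grid, axis=1) <= shell_radius
    grid, grid_idx = grid[inside], grid_idx[inside]

    rng = np.random.default_rng(seed)
    coords = grid + rng.normal(0.0, jitter, grid.shape)

    lining_idx: list[set[int]] = []
    keep = np.ones(len(coords), dtype=bool)
    for spec in pockets:
        d = _segment_distances(coords, spec.center, spec.axis_end)
        keep &= d >= spec.width / 2.0
        lining_idx.append(set(np.nonzero(d < spec.width / 2.0 + lining_shell)[0]))

    atoms: list[Atom] = []
    serial = 1
    index_to_serial: dict[int, int] = {}
    lining_assignment: dict[int, PharmacophoreType] = {}
    for p, spec in enumerate(pockets):
        members = sorted(i for i in lining_idx[p] if keep[i])
        for i in members:
            # type keyed to the underlying lattice point (not the member rank)
            # so the lining chemistry of identical pocket specs matches across
            # independently jittered structures
            ix, iy, iz = (int(v) for v in grid_idx[i])
            h = (ix * 73856093) ^ (iy * 19349663) ^ (iz * 83492791)
            lining_assignment[i] = spec.lining_types[h % len(spec.lining_types)]

    for i in np.nonzero(keep)[0]:
        if i in lining_assignment:
            res_name, atom_name, element = _TYPE_ATOMS[lining_assignment[i]]
        else:
            res_name, atom_name, element = _FILLER
        atoms.append(
            Atom(
                serial=serial,
                name=atom_name,
                element=element,
                residue_name=res_name,
                residue_number=serial,
                chain_id="A",
                coords=coords[i],
                record="protein",
            )
        )
        index_to_serial[int(i)] = serial
        serial += 1

    # ground-truth pocket atoms must be solvent accessible: intersect the
    # renamed lining with the surface-atom set of the protein-only structure
    surface_serials: set[int] = set()
    if pockets:
        protein_only = Structure(id="tmp", atoms=list(atoms))
        surf = surface_atoms(protein_only)
        surface_serials = {atoms[i].serial for i in surf}

    truths: list[PocketTruth] = []
    for p, spec in enumerate(pockets):
        lig_serials = []
        for ci, offset in enumerate(_ligand_offsets(spec)):
            atoms.append(
                Atom(
                    serial=serial,
                    name=f"C{ci + 1}",
                    element="C",
                    residue_name="LIG",
                    residue_number=9000 + p,
                    chain_id="L",
                    coords=spec.midpoint + offset,
                    record="ligand",
                )
            )
            lig_serials.append(serial)
            serial += 1
        relined = sorted(index_to_serial[i] for i in lining_idx[p] if keep[i])
        truths.append(
            PocketTruth(
                spec=spec,
                lining_serials=[s for s in relined if s in surface_serials],
                relined_serials=relined,
                ligand_serials=lig_serials,
                center=spec.midpoint,
            )
        )

    sid = structure_id or f"synth_{seed}"
    structure = Structure(
        id=sid,
        atoms=atoms,
        provenance={"generator": "make_pocket_protein", "seed": seed, "n_pockets": len(pockets)},
    )
    return structure, truths


def write_fixture(
    structure: Structure, truths: Sequence[PocketTruth], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the fixture as a PDB file plus a JSON ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_path = out_dir / f"{structure.id}.pdb"
    write_structure(structure, pdb_path)
    sidecar = {
        "structure_id": structure.id,
        "seed": structure.provenance.get("seed"),
        "pockets": [
            {
                "center": list(map(float, t.center)),
                "width": t.spec.width,
                "depth": t.spec.depth,
                "lining_types": list(t.spec.lining_types),
                "lining_serials": t.lining_serials,
                "relined_serials": t.relined_serials,
                "ligand_serials": t.ligand_serials,
            }
            for t in truths
        ],
    }
    json_path = out_dir / f"{structure.id}.truth.json"
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return pdb_path, json_path


def make_structure_family(
    base: Structure, n_members: int, jitter_sd: float, seed: int
) -> list[Structure]:
    """Jittered copies of ``base``; member 0 is the unperturbed base."""
    if jitter_sd < 0:
        raise SyntheticError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    members = []
    for m in range(n_members):
        noise = rng.normal(0.0, jitter_sd, (len(base.atoms), 3)) if m > 0 else None
        atoms = []
        for i, a in enumerate(base.atoms):
            coords = a.coords if noise is None else a.coords + noise[i]
            atoms.append(
                Atom(
                    serial=a.serial,
                    name=a.name,
                    element=a.element,
                    residue_name=a.residue_name,
                    residue_number=a.residue_number,
                    chain_id=a.chain_id,
                    coords=coords,
                    record=a.record,
                    occupancy=a.occupancy,
                    b_factor=a.b_factor,
                )
            )
        members.append(
            Structure(
                id=f"{base.id}_m{m}",
                atoms=atoms,
                provenance=dict(base.provenance, family_member=m, family_seed=seed),
            )
        )
    return members


def make_labeled_ranking(
    n: int,
    n_pos: int,
    enrichment: str = "random",
    seed: int = 0,
    mu_shift: float = 1.0,
) -> RankingFixture:
    """Labeled score list with controlled enrichment.

    ``perfect``: every positive outranks every negative. ``random``: scores
    i.i.d. uniform, independent of labels. ``graded``: standard-normal scores
    with the positives' mean shifted by ``mu_shift``.
    """
    if not 0 < n_pos < n:
        raise SyntheticError("need 0 < n_pos < n")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, bool)
    pos_idx = rng.choice(n, size=n_pos, replace=False)
    labels[pos_idx] = True
    if enrichment == "perfect":
        scores = np.where(labels, 1.0 + rng.random(n), rng.random(n))
    elif enrichment == "random":
        scores = rng.random(n)
    elif enrichment == "graded":
        scores = rng.normal(0.0, 1.0, n) + np.where(labels, mu_shift, 0.0)
    else:
        raise SyntheticError(f"unknown enrichment: {enrichment!r}")
    return RankingFixture(scores=scores, labels=labels, seed=seed)
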