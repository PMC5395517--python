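"""Alpha-sphere cavity detection, clustering, descriptors, scoring and interop.

An alpha sphere is the circumsphere of a Delaunay tetrahedron of protein
heavy-atom centres: an empty sphere tangent to four atoms. Spheres with radius
in a window (default 3.0-6.0 A) mark pocket-sized voids; single-linkage
clustering of their centres (default linkage distance 3.0 A, minimum component
size 3) yields candidate cavities. Cavities are summarised by descriptors
(size, sphere radius, hydrophobic/polar tangent character, Monte-Carlo union
volume) feeding a transparent linear Score used to rank them; a recall-based
calibration picks the Score threshold above which a requested fraction of
known ligand-bound sites is retained.

fpocket output directories can also be parsed so that externally detected
pockets (and their printed Score / Druggability Score / Volume) flow into the
same patch-building machinery.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError, cKDTree

from .structures import Structure

logger = logging.getLogger(__name__)

APOLAR_ELEMENTS = {"C", "S"}

#: fpocket interop: printed Score above which a parsed cavity is considered a
#: potential ligand-binding site (95%-recall calibration on known sites)
FPOCKET_SCORE_MIN = 16.8


class CavityError(ValueError):
    pass


class GeometryError(CavityError):
    pass


@dataclass
class AlphaSphere:
    """An empty sphere tangent to four protein heavy atoms."""

    center: np.ndarray
    radius: float
    tangent_atoms: tuple[int, ...]
    apolar_contact_count: int

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)


@dataclass
class Cavity:
    """A connected cluster of alpha spheres on one structure."""

    id: str
    spheres: list[AlphaSphere]
    structure_id: str

    def __len__(self) -> int:
        return len(self.spheres)

    def sphere_centers(self) -> np.ndarray:
        return np.array([s.center for s in self.spheres], float).reshape(-1, 3)

    def tangent_atom_indices(self) -> set[int]:
        out: set[int] = set()
        for s in self.spheres:
            out.update(s.tangent_atoms)
        return out


@dataclass
class CavityDescriptors:
    n_spheres: int
    mean_radius: float
    hydrophobic_fraction: float
    polarity_fraction: float
    mc_volume: float
    mc_seed: int


@dataclass
class ScoreWeights:
    """Linear cavity-scoring model: dot(weights, (x - mean)/scale) + intercept."""

    weights: dict[str, float]
    intercept: float = 0.0
    means: dict[str, float] = field(default_factory=dict)
    scales: dict[str, float] = field(default_factory=dict)
    weights_id: str = "custom"


#: bundled transparent default: score grows with cavity size, volume and
#: hydrophobic character (directions documented; magnitudes are package
#: choices, not a retrained model)
DEFAULT_SCORE_WEIGHTS = ScoreWeights(
    weights={
        "n_spheres": 0.25,
        "mean_radius": 1.0,
        "hydrophobic_fraction": 5.0,
        "polarity_fraction": 0.0,
        "mc_volume": 0.01,
    },
    intercept=0.0,
    weights_id="pocketmap-linear-v1",
)


@dataclass
class CavityScore:
    value: float
    weights_id: str


def _circumspheres(points: np.ndarray, simplices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Circumcenters and radii of tetrahedra; degenerate (near-flat) simplices
    get infinite radius so the radius window removes them."""
    p0 = points[simplices[:, 0]]
    rel = points[simplices[:, 1:]] - p0[:, None, :]  # (m, 3, 3)
    rhs = 0.5 * np.einsum("mij,mij->mi", rel, rel)
    det = np.linalg.det(rel)
    ok = np.abs(det) > 1e-10
    centers = np.full((len(simplices), 3), np.nan)
    if ok.any():
        centers[ok] = np.linalg.solve(rel[ok], rhs[ok][..., None])[..., 0] + p0[ok]
    radii = np.where(ok, np.linalg.norm(centers - p0, axis=1), np.inf)
    return centers, radii


def compute_alpha_spheres(
    structure: Structure,
    r_min: float = 3.0,
    r_max: float = 6.0,
) -> list[AlphaSphere]:
    """Alpha spheres of the protein heavy-atom Delaunay complex.

    One candidate per tetrahedron (its circumsphere), kept when the radius is
    within ``[r_min, r_max]`` and no protein heavy atom lies strictly inside.
    """
    idx = structure.protein_heavy_indices()
    if len(idx) < 4:
        raise GeometryError("need at least 4 protein heavy atoms")
    points = structure.coords(idx)
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise GeometryError(f"degenerate geometry: {exc}") from exc

    centers, radii = _circumspheres(points, tri.simplices)
    window = (radii >= r_min) & (radii <= r_max)
    tree = cKDTree(points)
    spheres: list[AlphaSphere] = []
    for m in np.nonzero(window)[0]:
        simplex = tri.simplices[m]
        inside = tree.query_ball_point(centers[m], radii[m] - 1e-6)
        if any(j not in simplex for j in inside):
            continue  # numeric near-degeneracy: not actually empty
        tangent = tuple(int(idx[j]) for j in simplex)
        apolar = sum(
            1 for j in tangent if structure.atoms[j].element.upper() in APOLAR_ELEMENTS
        )
        spheres.append(
            AlphaSphere(
                center=centers[m],
                radius=float(radii[m]),
                tangent_atoms=tangent,
                apolar_contact_count=apolar,
            )
        )
    return spheres


def cluster_alpha_spheres(
    spheres: Sequence[AlphaSphere],
    r: float = 3.0,
    n_min: int = 3,
    structure_id: str = "",
) -> list[Cavity]:
    """Single-linkage clusters of sphere centres at linkage distance ``r``.

    Components with fewer than ``n_min`` spheres are discarded; cavities are
    ordered by descending sphere count, ties by lowest member index.
    """
    if not spheres:
        return []
    centers = np.array([s.center for s in spheres])
    tree = cKDTree(centers)
    pairs = tree.query_pairs(r, output_type="ndarray")
    n = len(spheres)
    if len(pairs):
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        graph = coo_matrix((n, n))
    n_comp, labels = connected_components(graph, directed=False)
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    members = [sorted(g) for g in groups.values() if len(g) >= n_min]
    members.sort(key=lambda g: (-len(g), g[0]))
    return [
        Cavity(
            id=f"{structure_id or 'structure'}:cav{k:03d}",
            spheres=[spheres[i] for i in g],
            structure_id=structure_id,
        )
        for k, g in enumerate(members)
    ]


def detect_cavities(
    structure: Structure,
    r_min: float = 3.0,
    r_max: float = 6.0,
    r: float = 3.0,
    n_min: int = 3,
) -> list[Cavity]:
    """Convenience: alpha spheres -> clustered cavities for one structure."""
    spheres = compute_alpha_spheres(structure, r_min=r_min, r_max=r_max)
    return cluster_alpha_spheres(spheres, r=r, n_min=n_min, structure_id=structure.id)


def cavity_descriptors(
    cavity: Cavity,
    structure: Structure,
    mc_points: int = 100_000,
    seed: int = 0,
) -> CavityDescriptors:
    """Descriptors of a cavity; the union volume is Monte-Carlo, seeded."""
    if len(cavity) == 0:
        raise CavityError("empty cavity")
    centers = cavity.sphere_centers()
    radii = np.array([s.radius for s in cavity.spheres])
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(mc_points, 3))
    inside = np.zeros(mc_points, bool)
    for c, r in zip(centers, radii):
        inside |= np.einsum("ij,ij->i", samples - c, samples - c) <= r * r
    box = float(np.prod(hi - lo))
    mc_volume = box * inside.mean()
    hydro = float(np.mean([s.apolar_contact_count >= 3 for s in cavity.spheres]))
    return CavityDescriptors(
        n_spheres=len(cavity),
        mean_radius=float(radii.mean()),
        hydrophobic_fraction=hydro,
        polarity_fraction=1.0 - hydro,
        mc_volume=mc_volume,
        mc_seed=seed,
    )


def cavity_score(
    descriptors: CavityDescriptors,
    weights: ScoreWeights = DEFAULT_SCORE_WEIGHTS,
) -> CavityScore:
    """Linear score over (standardized) descriptors."""
    value = weights.intercept
    for name, w in weights.weights.items():
        if not hasattr(descriptors, name):
            raise CavityError(f"weight for unknown descriptor: {name!r}")
        x = float(getattr(descriptors, name))
        mu = weights.means.get(name, 0.0)
        sd = weights.scales.get(name, 1.0)
        value += w * (x - mu) / sd
    for name in ("n_spheres", "mean_radius", "hydrophobic_fraction", "polarity_fraction", "mc_volume"):
        if name not in weights.weights:
            raise CavityError(f"missing weight for descriptor: {name!r}")
    return CavityScore(value=float(value), weights_id=weights.weights_id)


def match_cavity_to_ligand(
    cavities: Sequence[Cavity],
    ligand_coords: np.ndarray,
    contact: float = 4.0,
) -> Optional[Cavity]:
    """The cavity with the most sphere centres within ``contact`` of the ligand.

    Returns None when no sphere touches the ligand. Ties go to the larger
    cavity, then the lexicographically lower id.
    """
    ligand_coords = np.asarray(ligand_coords, float).reshape(-1, 3)
    if len(ligand_coords) == 0:
        raise CavityError("empty ligand")
    tree = cKDTree(ligand_coords)
    best: tuple[int, int, str] | None = None
    best_cavity = None
    for cav in cavities:
        d, _ = tree.query(cav.sphere_centers())
        count = int((d <= contact).sum())
        if count == 0:
            continue
        key = (-count, -len(cav), cav.id)
        if best is None or key < best:
            best = key
            best_cavity = cav
    return best_cavity


def calibrate_score_threshold(
    true_site_scores: Sequence[float], recall: float = 0.95
) -> float:
    """Largest threshold t with at least ``recall`` of the scores >= t.

    This is the ceil(n * recall)-th largest score, so recall at the returned
    threshold is >= the request by construction.
    """
    scores = np.asarray(true_site_scores, float)
    if scores.size == 0:
        raise CavityError("empty score list")
    if not 0 < recall <= 1:
        raise CavityError("recall must be in (0, 1]")
    k = math.ceil(scores.size * recall)
    return float(np.sort(scores)[::-1][k - 1])


# --- fpocket interoperability -------------------------------------------------

@dataclass
class FpocketPocket:
    """One pocket parsed from an fpocket output directory, values verbatim."""

    id: str
    cavity: Cavity
    score: Optional[float]
    druggability_score: Optional[float]
    volume: Optional[float]


_INFO_KEYS = {
    "Score": "score",
    "Druggability Score": "druggability_score",
    "Volume": "volume",
    "Real volume (approximation)": "volume",
}


def _parse_info_file(path: Path) -> dict[int, dict[str, float]]:
    pockets: dict[int, dict[str, float]] = {}
    current: Optional[int] = None
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        header = re.match(r"\s*Pocket\s+(\d+)\s*:?", line)
        if header and ":" in line and "Score" not in line:
            current = int(header.group(1))
            pockets[current] = {}
            continue
        kv = re.match(r"\s*([A-Za-z][A-Za-z ()\-.]*?)\s*:\s*(-?[\d.]+)\s*$", line)
        if kv and current is not None:
            key = kv.group(1).strip()
            if key in _INFO_KEYS:
                try:
                    pockets[current][_INFO_KEYS[key]] = float(kv.group(2))
                except ValueError as exc:
                    raise CavityError(f"{path}:{lineno}: bad value for {key}") from exc
    if not pockets:
        raise CavityError(f"{path}: no pocket blocks found")
    return pockets


def _parse_vert_pqr(path: Path) -> list[AlphaSphere]:
    spheres = []
    for line in path.read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        fields = line.split()
        try:
            x, y, z = map(float, fields[-5:-2])
            radius = float(fields[-1])
        except (ValueError, IndexError) as exc:
            raise CavityError(f"{path}: malformed PQR line: {line!r}") from exc
        name = fields[2].upper()
        apolar = 4 if name.startswith(("C", "APOL")) else 0
        spheres.append(
            AlphaSphere(
                center=np.array([x, y, z]),
                radius=radius,
                tangent_atoms=(),
                apolar_contact_count=apolar,
            )
        )
    return spheres


def parse_fpocket_results(
    directory: str | Path,
    score_min: Optional[float] = None,
) -> list[FpocketPocket]:
    """Parse an fpocket output directory into pocket records.

    Reported Score / Druggability Score / Volume are carried verbatim; sphere
    centres come from the per-pocket ``pocket<N>_vert.pqr`` files. When
    ``score_min`` is given (e.g. the 16.8 interop default), pockets whose
    printed Score falls below it are dropped.
    """
    directory = Path(directory)
    info_files = sorted(directory.glob("*_info.txt"))
    if not info_files:
        logger.warning("parse_fpocket_results: no *_info.txt under %s", directory)
        return []
    info = _parse_info_file(info_files[0])
    structure_id = info_files[0].name.replace("_info.txt", "")
    pockets_dir = directory / "pockets"
    out: list[FpocketPocket] = []
    for num in sorted(info):
        spheres: list[AlphaSphere] = []
        for pattern in (f"pocket{num}_vert.pqr", f"pocket{num}_vert.pdb"):
            candidate = pockets_dir / pattern
            if candidate.exists():
                spheres = _parse_vert_pqr(candidate)
                break
        rec = FpocketPocket(
            id=f"{structure_id}:fpocket{num}",
            cavity=Cavity(
                id=f"{structure_id}:fpocket{num}",
                spheres=spheres,
                structure_id=structure_id,
            ),
            score=info[num].get("score"),
            druggability_score=info[num].get("druggability_score"),
            volume=info[num].get("volume"),
        )
        if score_min is not None and (rec.score is None or rec.score < score_min):
            continue
        out.append(rec)
    return out
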