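"""End-to-end orchestration helpers.

These functions wire the stages together for the common experiment shape:
a set of protein "targets", each an ensemble of structures, whose detected
cavities are patched, compared all-vs-all and clustered into a map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cavities import detect_cavities, match_cavity_to_ligand
from .compare import SimilarityMatrix, all_vs_all
from .mapping import ClusterMap, LinkRow, build_cluster_map, cluster_link_table
from .patches import Patch, patch_from_cavity
from .structures import Structure, surface_atoms
from .synthetic import PocketSpec, make_pocket_protein, make_structure_family

logger = logging.getLogger(__name__)


def structure_cavity_patch(
    structure: Structure,
    ligand_coords: Optional[np.ndarray] = None,
    site_size: float = 0.3,
    **detect_kwargs,
) -> Optional[Patch]:
    """Detect cavities on one structure and patch the best one.

    With ``ligand_coords`` the ligand-matched cavity is patched (the rule used
    to validate detection against known sites); otherwise the largest cavity.
    Returns None when nothing is detected or the cavity is buried.
    """
    cavities = detect_cavities(structure, **detect_kwargs)
    if not cavities:
        return None
    if ligand_coords is not None:
        cavity = match_cavity_to_ligand(cavities, ligand_coords)
    else:
        cavity = cavities[0]
    if cavity is None:
        return None
    surface = surface_atoms(structure)
    try:
        return patch_from_cavity(structure, cavity, site_size=site_size, surface=surface)
    except ValueError:
        logger.info("cavity %s not patchable", cavity.id)
        return None


@dataclass
class SyntheticTarget:
    """A named family of structures generated around shared pocket specs."""

    name: str
    structures: list[Structure]
    pockets: list[PocketSpec]


def synthetic_target_patches(
    targets: Sequence[tuple[str, Sequence[PocketSpec]]],
    n_structures: int = 15,
    n_atoms: int = 420,
    shell_radius: float = 14.0,
    jitter_sd: float = 0.25,
    seed: int = 0,
) -> tuple[list[Patch], list[str]]:
    """Detected-cavity patches for families of synthetic targets.

    Each target is an ensemble of ``n_structures`` jittered copies of a base
    pocket protein built from its pocket specs; every member structure
    contributes one patch per pocket (the cavity matched to the planted
    pseudo-ligand). Returns the patches and their target labels.
    """
    patches: list[Patch] = []
    labels: list[str] = []
    for t_index, (name, specs) in enumerate(targets):
        base, truths = make_pocket_protein(
            n_atoms=n_atoms,
            shell_radius=shell_radius,
            pockets=list(specs),
            seed=seed + 101 * t_index,  # independent base lattice per target
            structure_id=f"{name}_base",
        )
        family = make_structure_family(
            base, n_members=n_structures, jitter_sd=jitter_sd,
            seed=seed * 1000 + 17 * t_index + 1,
        )
        for member in family:
            for p_index, truth in enumerate(truths):
                lig = member.coords(
                    [i for i, a in enumerate(member.atoms)
                     if a.serial in set(truth.ligand_serials)]
                )
                patch = structure_cavity_patch(member, ligand_coords=lig)
                if patch is None:
                    logger.warning("no cavity patch for %s pocket %d", member.id, p_index)
                    continue
                patch.id = f"{member.id}:p{p_index}"
                patches.append(patch)
                labels.append(name)
    return patches, labels


def run_site_map(
    patches: Sequence[Patch],
    target_labels: Sequence[str],
    min_links: int = 5,
    link_threshold: float = 2.0,
    eps: float = 7.0,
    min_samples: int = 10,
    **align_kwargs,
) -> tuple[SimilarityMatrix, ClusterMap, list[LinkRow]]:
    """All-vs-all comparison -> conservation filter -> clustering -> links."""
    matrix = all_vs_all(patches, target_labels=target_labels, **align_kwargs)
    cmap = build_cluster_map(
        matrix,
        min_links=min_links,
        link_threshold=link_threshold,
        eps=eps,
        min_samples=min_samples,
    )
    sub = matrix.submatrix(cmap.retained_ids)
    links = cluster_link_table(
        cmap.per_target_labels, cmap.target_of, sub, highlight_threshold=link_threshold
    )
    return matrix, cmap, links
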