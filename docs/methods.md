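# Methods

This note records the models, defaults and numerical choices behind
pocketmap, and what the synthetic test bed does and does not establish.

## Structures and solvent accessibility

Structures are parsed with gemmi (PDB or mmCIF). ATOM records are protein;
HETATM waters (HOH/WAT/DOD) are water; all other HETATM records are ligand.
Ions and cofactors that are not the ligand of interest therefore count as
ligand-record atoms and are excluded from the protein surface; callers that
want them treated otherwise can reclassify before downstream calls. Alternate
locations are resolved to the highest-occupancy conformer, ties broken by
altloc letter. Hydrogens are kept in the atom list but ignored by SASA,
cavity detection and patch typing, which are residue/atom-name based.

Per-atom solvent-accessible surface area is Shrake–Rupley with a probe of
1.4 Å, a golden-spiral test sphere of 960 points, and a bundled Bondi-style
van der Waals radius table (unknown elements fall back to 1.7 Å with a logged
warning). The test sphere is oriented per atom by a frame derived from the
atom's neighbour displacement vectors, so the discretized areas are exactly
invariant under global rigid motion instead of only in the many-points limit.
Surface atoms are protein heavy atoms with area ≥ 0.5 Å² (configurable).
Superposition is closed-form Kabsch (SVD, proper rotation enforced);
pairings with fewer than three pairs, or collinear ones, are rejected.

Crystallographic quality filtering is pure thresholding of supplied values.
The bundled bound sets read "resolution 2.5 Å (protein-centric) / 2.7 Å
(ligand-centric) or better" as numeric upper bounds, with Rfree ≤ 0.3,
DPI ≤ 0.5 Å, ligand RSCC ≥ 0.9, ligand RSR ≤ 0.15 and ligand OWAB within
5–50 Å². A record missing a thresholded field fails and is logged; the DPI
itself is consumed as a provided number, never computed.

## Cavity detection

Alpha spheres are circumspheres of the Delaunay tetrahedra of protein
heavy-atom centres, kept when the radius lies in [3.0, 6.0] Å and no heavy
atom is strictly inside (tolerance 1e-6 Å). Near-degenerate (flat) tetrahedra
are given infinite radius and removed by the window rather than raising.
Clustering is one single-linkage pass over sphere centres at distance
r = 3.0 Å with components of fewer than n = 3 spheres discarded; this is a
deliberately deterministic simplification of fpocket's multi-step clustering,
tuned to the same modified parameters, and fpocket's own output can be parsed
for bit-faithful interop instead. Apolar tangency means element C or S.

Descriptors per cavity: sphere count, mean radius, hydrophobic fraction
(spheres with ≥ 3 apolar tangent atoms), polarity fraction (its complement)
and a seeded Monte-Carlo union volume (default 100,000 samples of the
bounding box; relative error well under 1% at that size for single spheres).
The ranking Score is an explicitly linear model over these descriptors with
bundled, documented default weights (positive on size, volume and
hydrophobicity). It is *not* a retrained druggability model: the external
tool's trained weights are unpublished, so its printed scores are only ever
consumed via the interop parser, where the 16.8 threshold applies. Scores
carry a `weights_id` so thresholds are never mixed across scoring models.

Threshold calibration returns the ⌈n·recall⌉-th largest of the supplied
true-site scores — the largest threshold at which the requested recall
(default 95%) is met; recall at the returned threshold is therefore
guaranteed by construction.

The ligand↔cavity correspondence rule (used to validate detection) picks the
cavity with the most sphere centres within 4 Å of any ligand heavy atom, ties
to the larger cavity then the lower id, and counts one site per complex.

## Patches and pharmacophore typing

A patch is shape points (coordinates of its surface atoms) plus typed
pseudocenters. The rule table: Asp/Glu carboxylates and the C-terminal OXT
are anions (carboxylates as group centroids); Lys NZ and the Arg guanidinium
centroid are cations; backbone N and side-chain N–H (Asn ND2, Gln NE2,
Trp NE1) are donors; backbone O, Asn OD1, Gln OE1 and the His ring nitrogens
are acceptors; Ser/Thr/Tyr hydroxyls emit both donor and acceptor; side-chain
carbons of Ala/Val/Leu/Ile/Met/Pro plus the Phe/Trp ring centroids are
hydrophobes. Histidine is neutral by default with a `his_mode="cation"`
switch, since protonation states are not assigned here. Ring centroids (and
a per-atom mode) keep atom-rich rings from dominating the color overlap. A
group pseudocenter is emitted only when every group atom is in the patch, so
pseudocenter sources always lie inside the patch atom set. Non-standard
residues fall back to element typing (N donor, O acceptor, C/S hydrophobe);
anything else is skipped with a debug log.

Ligand patches are surface atoms within 4.0 Å of any ligand heavy atom
(hydrogens excluded from the distance test). Cavity patches use the
pseudo-ligand rule: "cavity surface atoms" are interpreted as the alpha
spheres' tangent atoms intersected with the surface set — a definition the
method leaves open, and one that shapes every ligand-independent patch —
then dilated by site_size = 0.3 Å. At that default
the patch is essentially the pseudo-ligand set plus exact-overlap neighbours,
and the patch atom set is non-decreasing in site_size.

## Alignment and PatchScore

Gaussian overlap between point sets is the exact double sum
O = Σᵢⱼ δ(typeᵢ,typeⱼ)·(π/2γ)^{3/2}·exp(−(γ/2)d²ᵢⱼ), with the type filter
applied only to the color term. Defaults γ_shape = 0.3 Å⁻²,
γ_color = 0.5 Å⁻² (color more localized); both are package choices, exposed
as parameters. Component similarities are Tanimoto coefficients
T = O_ab / (O_aa + O_bb − O_ab), clipped to [0, 1]; a patch with no
pseudocenters contributes color 0 rather than an error. The score and the
alignment objective are the same 3·T_color + T_shape combination, chosen for
self-consistency since nothing separates them at the definition level.

Optimization over the six rigid degrees of freedom is deterministic: four
starts (principal-axes superposition of the shape clouds and its three 180°
flips, with eigenvector signs fixed by a largest-component convention),
each refined by L-BFGS-B on a coarse-to-fine schedule of Gaussian widths
(0.15× then 1× the target γ). The smoothed first stage exists because the
full-width objective is rugged; without it the optimizer measurably
undershoots the identity-transform score on near-identical patch pairs.
Tolerance 1e-6, maxiter 120 per stage. All-vs-all matrices compute each
unordered pair once in a canonical orientation (sorted by patch id), so
results are independent of input order; failures become explicit NaNs, and a
per-pair append-only log allows resuming long runs.

## Retrieval metrics

AUROC is computed by scikit-learn (ties counted half; equals the
Mann–Whitney probability, which the tests verify exactly). ROC points come
from the grouped-ties threshold sweep, (0,0) to (1,1). The enrichment factor
uses a ceiling cutoff m = ⌈fraction·n⌉ with ties at the boundary broken by
stable input order, making EF defined for small n. BEDROC sums
exp(−α·rank/N) over positive ranks and normalizes by the exact geometric-sum
extremes (all positives first/last), so a perfect ranking scores exactly 1
and an inverted one exactly 0; this agrees with the published
Boltzmann-weighted formulation as implemented in RDKit to 1e-9 on shared
inputs. Default α = 20, EF fraction 0.05.

The retrieval protocol labels, for each database structure sharing the
query's protein identity, only its best-scoring patch as the true positive;
sibling patches are *ignored* — removed from numerator and denominator —
because treating them as negatives would penalize correct retrieval.
Aggregated reports state mean ± standard error over queries.

## Mapping

Patch feature vectors are their PatchScore rows — restricted to same-target
columns for the local step, all retained columns for the global step —
compared with Euclidean distance. This makes the DBSCAN radius ε = 7
dimensionally consistent with the score-matrix usage; it is the most
consequential open choice in the mapping stage and a (4 − score)
dissimilarity alternative is available via the same row-vector machinery.
The conservation filter keeps patches with at least 5 off-diagonal scores
≥ 2.0, counted in a single pass on the original matrix (not iterated), and
is monotone in both parameters. Hierarchical clustering is scipy
average-linkage with leaves in scipy's standard order; flat labels require a
cut the method itself does not define, so a `cut_n_clusters` parameter is
provided and the dendrogram is always exported. DBSCAN (scikit-learn) uses
min_samples = 10 with the point itself included, noise label −1; targets
with fewer patches than min_samples are all noise by definition. Link tables
report, for every unordered cluster pair, the maximum member-pair PatchScore,
with a highlight flag at ≥ 2.0 and a within-target marker (the circular map
shows cross-target ribbons; both kinds are emitted and flagged). Exports are
byte-stable for identical inputs: ordered matrix TSV, PNG heat map and chord
render (fixed metadata), Circos karyotype/link text files, JSON summary.

## The synthetic test bed

`make_pocket_protein` packs carbon pseudo-atoms on a cubic lattice (spacing
set by the requested atom count) filling a ball, adds seeded Gaussian jitter
of 0.25 Å to break lattice degeneracy, carves each pocket as a capsule of
radius width/2 reaching the surface, renames the atoms lining the carved
region to single-atom residues whose names type to the requested
pharmacophores (e.g. Lys NZ for a cation), and places a rigid 16-atom
pseudo-ligand along the pocket axis. Lining chemistry is keyed to the
underlying lattice point, not to the member index, so identical pocket specs
carved into independently jittered lattices present matching chemistry.
Ground-truth pocket atoms are the solvent-accessible lining atoms, which
makes them a subset of the surface set by construction. Defaults used
throughout the tests: 420 atoms, shell radius 14 Å, pocket depth 9 Å, width
7 Å, family jitter 0.25 Å — one realistic-scale pocket on a small,
fast-to-triangulate body.

Structure families add i.i.d. Gaussian coordinate noise (member 0
unperturbed), giving a mean pairwise all-atom RMSD of √(6)·σ between
perturbed members, in the spirit of a crystal-structure ensemble of one
protein. Ranking fixtures provide perfect, random and graded (Gaussian
mean-shift) enrichment regimes.

What this establishes — and what it does not: the fixtures have no covalent
geometry, no rotamers, no conformational change beyond isotropic jitter, and
chemistry placed exactly where the detector should find it. Passing tests
demonstrate that every stage implements its stated contract and that the
pipeline recovers planted cross-target similarity against unrelated-pocket
background; they do not demonstrate retrieval performance on real crystal
structures, which depends on conformational variability the generator does
not emulate. The end-to-end experiment (three targets of 15 structures, two
sharing a pocket archetype) was sized to exercise every stage, including the
min_samples = 10 clustering floor, at desk scale.

## Known limitations

- The internal cavity Score is a documented linear stand-in for ranking;
  absolute values are not comparable to fpocket's printed scores (use the
  interop parser and its 16.8 threshold for those).
- Single-pass single-linkage clustering can chain pocket spheres to shallow
  surface spheres through a pocket mouth; the ligand-match rule and the
  conservation filter absorb this downstream, as noise of the same kind is
  absorbed in real detector output.
- Gaussian widths per pseudocenter type are global, not type-specific.
- The alignment optimum is a local-search result; the deterministic
  multi-start plus annealing recovers the global basin on all tested
  constructions, but adversarial geometries can in principle defeat four
  starts.
- Protonation/tautomer assignment, symmetry mates and metal-coordination
  pharmacophores are out of scope.
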