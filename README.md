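# pocketmap

Ligand-independent mapping of small-molecule binding sites on protein
structures: geometric cavity detection, pharmacophore-typed binding-site
patches, pairwise Gaussian-overlap similarity scoring, retrieval evaluation
and clustering of binding-site space.

## Who this is for

Structural bioinformaticians and computational chemists who want to compare
binding sites *without* requiring a bound ligand — for example to find
conserved pockets across an ensemble of structures, to flag cross-target
similarities that suggest polypharmacology, or to benchmark binding-site
comparison on controlled synthetic data.

## The method

**Cavity detection.** An *alpha sphere* is the circumsphere of a Delaunay
tetrahedron of protein heavy-atom centres — an empty sphere tangent to four
atoms. Spheres with radius in a window (default 3.0–6.0 Å) mark pocket-sized
voids; single-linkage clustering of sphere centres (linkage distance r = 3.0 Å,
minimum component size n = 3) yields candidate cavities. Cavities are ranked
by a transparent linear *Score* over descriptors (sphere count, mean radius,
hydrophobic/polar tangent character, Monte-Carlo union volume), and a
sensitivity threshold can be calibrated as the Score above which a requested
fraction (default 95%) of known ligand-bound sites is retained. Output from
the external tool fpocket can be parsed directly, including its printed
Score ≥ 16.8 filter.

**Binding-site patches.** A patch is the comparison unit: *shape points* (the
solvent-accessible protein atoms around a site, Shrake–Rupley SASA ≥ 0.5 Å²)
plus *pharmacophore pseudocenters* of five types — H-bond donor, H-bond
acceptor, anion, cation, hydrophobe — assigned from a residue/atom-name rule
table (carboxylates, guanidinium and aromatic rings collapse to centroids).
Patches come either from a bound ligand (surface atoms within 4 Å) or, with
no ligand, from a detected cavity via the *pseudo-ligand* rule: the cavity's
tangent surface atoms dilated by a small site size (0.3 Å).

**PatchScore.** A patch pair is rigidly aligned by maximizing atom-centred
Gaussian overlap, and scored

```
PatchScore = 3·T_color + 1·T_shape   ∈ [0, 4]
```

where `T_shape` and `T_color` are Tanimoto coefficients of Gaussian overlap
volumes — over all shape points, and over type-matched pseudocenters,
respectively. 0 conveys complete dissimilarity, 4 perfect similarity, and the
symmetric Tanimoto builds in size matching. Alignment is deterministic:
principal-axes starts plus the three 180° flips, each refined coarse-to-fine.

**Retrieval evaluation.** Rankings of database patches against a query are
scored with AUROC, enrichment factor in the top fraction (EF@5%) and BEDROC
(α = 20). When a structure contributes several patches, only its best-scoring
one counts as the true positive; siblings are ignored rather than punished.

**Mapping.** The all-vs-all PatchScore matrix is filtered (a patch needs ≥ 5
pairwise scores ≥ 2.0 to be conserved enough to keep), clustered within each
target and globally (average-linkage hierarchical clustering, Euclidean
distance on PatchScore row vectors) and per-target with DBSCAN (ε = 7,
min_samples = 10, noise explicit). Cluster pairs are summarised by their
maximum member-pair PatchScore; pairs ≥ 2.0 are highlighted — the candidate
cross-target similarities. Exports include reordered matrices, heat maps,
Circos-compatible karyotype/link files and a built-in chord render.

A bundled synthetic generator builds deterministic "pocket proteins" (atom
lattices with carved, chemically typed pockets and placed pseudo-ligands), so
the entire pipeline is testable without downloading structures.

## Worked example

`examples/02_compare_patches.py` builds two independent realizations of the
same pocket archetype (A, B) and one unrelated pocket (C), detects each
cavity and compares the patches:

```
A vs A (self)                PatchScore 4.00 (color 1.00, shape 1.00)
A vs B (same archetype)      PatchScore 3.05 (color 0.74, shape 0.83)
A vs C (unrelated pocket)    PatchScore 0.72 (color 0.11, shape 0.39)
```

Self-comparison is exact (4.0). The two realizations of the same site score
3.05 — well above the 2.0 similarity threshold — because both their geometry
(shape 0.83) and their planted chemistry (color 0.74) match. The unrelated
pocket scores 0.72: some residual shape overlap, almost no matched chemistry.
`examples/04_site_map.py` runs the full three-target map and highlights
exactly the planted A–B link; `examples/01_detect_and_patch.py` and
`examples/03_retrieval_metrics.py` demonstrate detection and the metrics.

A thin CLI mirrors the stages (`pocketmap synth | detect | patch | compare |
matrix | filter | cluster | map | eval`); run `pocketmap --help`.

## Layout

- `src/pocketmap/structures.py` — PDB/mmCIF I/O, SASA, Kabsch superposition, quality filters
- `src/pocketmap/synthetic.py` — pocket-protein generator, structure families, labeled rankings
- `src/pocketmap/cavities.py` — alpha spheres, cavity clustering, descriptors/Score, fpocket interop
- `src/pocketmap/patches.py` — pharmacophore typing and patch construction
- `src/pocketmap/compare.py` — Gaussian-overlap alignment, PatchScore, similarity matrices
- `src/pocketmap/retrieval.py` — ROC/AUROC, EF, BEDROC, deduplicated retrieval runs
- `src/pocketmap/mapping.py` — conservation filter, clustering, link tables, map exports
- `src/pocketmap/pipeline.py` — end-to-end orchestration helpers
- `docs/methods.md` — modelling choices, defaults and limitations
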