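# Methods

This note documents the models and procedures implemented in `vscreen`,
the parameters that matter, and the design choices made where conventions
genuinely diverge.

## Standardization

`dbprep.standardize` keeps the *largest organic fragment*: among the
fragments containing at least one carbon, the one with the most heavy
atoms wins, ties broken by molecular weight and then by canonical-SMILES
order (ascending). If no fragment contains carbon, all fragments compete.
Charges are then neutralized with the toolkit's uncharger, which protonates
anions and deprotonates cations where a neutral form exists and leaves
permanent charges (quaternary nitrogen, N-oxides) alone. A structure that
fails sanitization after these transforms is returned unchanged with a
`standardization_warning` property rather than aborting the run — a single
pathological entry must not kill a library preparation.

Tautomer canonicalization (`dbprep.canonical_tautomer`) replaces the
working structure with the canonical tautomer under the toolkit's standard
scoring rules; the pre-canonicalization SMILES is retained in
`properties["pre_tautomer_smiles"]` when it differs. We chose replacement
over side-by-side storage because every downstream consumer (fingerprints,
conformers, matching) should see one consistent structure; the property
preserves the input form for auditing. The `tautomer_canonicalized` flag
guards the operation, making it strictly idempotent.

## Fingerprints

Supported families: Morgan (ECFP-like connectivity invariants or FCFP-like
feature invariants), RDKit path, topological torsion, atom pair and MACCS
keys (fixed 167 bits). Each fingerprint is stored under a key that encodes
every generation parameter (e.g. `morgan-r2-2048-fcfp`), so a search can
detect a preparation/query mismatch instead of silently comparing
incompatible bit vectors. The default is Morgan, radius 2, 2048 bits, with
feature invariants — i.e. an FCFP4-like fingerprint (the "4" names the
environment *diameter*; the generation parameter is the radius, 2).

Similarity coefficients are evaluated from the set statistics
(a, b, c, n); any zero denominator yields 0, so two empty fingerprints are
"dissimilar". This matches common toolkit behavior and keeps every
coefficient total. Tversky weights default to α = β = 0.5 (the Dice-like
symmetric point); both are exposed.

Similarity maps use the bit-removal scheme: the weight of atom *i* in the
hit molecule is the similarity drop when all bits whose circular
environments contain atom *i* are removed from the hit fingerprint.
Weights are only defined for atom-attributable (Morgan) fingerprints.

## Conformers

Conformers are embedded with ETKDGv3 (fixed seed, single-threaded for
bit-reproducibility) after adding hydrogens, pruned during embedding at a
heavy-atom RMSD threshold of 0.5 Å (a common default; duplicates of a rigid
ring collapse to one conformer), then relaxed with MMFF94 — or UFF when
MMFF94 parameters are missing for the molecule, recorded as a warning —
and stored as heavy-atom geometries sorted by ascending force-field energy.
Records for which embedding fails entirely keep zero conformers and a
warning; 3D screening skips them. Embedding failure for a *query* is fatal
instead, because a shape search without a query makes no sense.

## The screening database container

The `.vsdb` container is gzip-compressed JSON with an explicit magic string
and `format_version` header. Structures are stored in the toolkit's native
binary form (base64), so loading deserializes rather than re-perceives
chemistry — the container's reason to exist is that loading it is faster
than re-parsing the equivalent SDF. The gzip filename field is blanked and
its mtime zeroed so identical databases are byte-identical on disk. A
version mismatch or truncated file is a clean, named error.

## Substructure search

Matching delegates to the toolkit's subgraph matcher. Matches are
deduplicated by *atom set*: the twelve automorphic mappings of benzene onto
itself count as one occurrence, and a molecule with two separate thiazole
rings counts two. This is the semantics a chemist means by "the molecule
contains two thiazole groups". Chirality is ignored by default (flag to
enable). Hits are ordered by source index; atom indices are 0-based in
input-file order everywhere (highlighting, coordinates).

## Volumetric shape similarity

Atoms are hard spheres with Bondi van der Waals radii (1.70 Å fallback)
sampled on a regular boolean grid, default spacing 0.4 Å; volumes are voxel
counts. Metrics: Tanimoto V(A∩B)/V(A∪B); a Tversky analogue with weights on
the two difference volumes; and "protrude" similarity 1 − V(A∖B)/V(A),
which is deliberately asymmetric (how little of A sticks out of B).
Distance-like outputs are uniformly converted so that every reported score
is "higher is better", which a coherent combo score requires. The grid
implementation was validated against the closed-form lens volume of two
intersecting unit spheres: at 0.2 Å spacing the grid Tanimoto is within
0.007 of the analytic value (tolerance 0.02).

## 3D pharmacophore fingerprint

Two-point pharmacophores over six feature families (donor, acceptor,
aromatic, hydrophobe, positive, negative ionizable; perceived with the
toolkit's standard feature definitions, lumped-hydrophobe and zinc-binder
families excluded) with inter-feature distances binned into
0–2, 2–4, 4–6, 6–8, 8–100 Å — 105 bits total. Similarity is the Tanimoto
of the two bit sets; a molecule with no feature *pair* scores 0 with a
warning. Note the corollary: a molecule with exactly one perceived feature
(benzene — one aromatic ring) has an empty 2-point fingerprint. The
pharmacophore fingerprint is computed on the best-aligned conformer pair,
consistent with the pipeline ordering (2-point distance sets are rotation
invariant, so this choice only matters if the schema is extended to
alignment-dependent features).

## Shape search

For each database record, all query-conformer × database-conformer pairs
are aligned (Open3DAlign; MMFF94 or Crippen atom weights) and the pair
maximizing shape similarity is selected; the pharmacophore similarity is
computed on that pair and combo = (shape + pharm)/2. Pairs the aligner
cannot handle are skipped with score 0. Hits are ranked by combo (or
either component), ties broken by record id, top 10 returned by default —
the same ten that the session export aligns for visual inspection.

## Validation harness

Leave-one-active-out: each active is the query once; the remaining actives
plus all decoys form the validation set. The AUC is computed in tie-aware
Mann–Whitney form (ties credited ½), which is exactly the trapezoidal
integral of the tie-aware ROC curve; both the curve construction and the
midrank form are implemented and agree to 1e-12, and both are checked in
the tests against O(n²) pair counting and an independent library
implementation. Random ranking has expectation 0.5.

## Synthetic benchmark

The generator emulates the *structure* of a MUV subset — one small actives
class sharing chemotype signal against a large unrelated decoy background —
not its chemistry or its difficulty. Actives are one scaffold core (drawn
per-seed from four drug-like cores) decorated with 1–3 substituents from a
17-fragment menu at random attachable positions; decoys are chains of 2–4
aliphatic/ether/amine fragments, filtered to exclude the scaffold. Defaults
are 30 actives and 1,500 decoys (a 10× decoy reduction of MUV scale) so the
full harness runs in well under a minute. Because the actives share a large
common substructure, fingerprint screening separates them almost perfectly
(mean AUC ≈ 1.0); MUV is deliberately constructed to defeat exactly this
kind of analog signal, so **passing the synthetic benchmark certifies the
harness and the pipeline plumbing, not screening power on hard real-world
data**. Label-shuffled versions of the same library score ≈ 0.5, which is
the matching negative control.

## Parallelism and reproducibility

All per-record work goes through an order-preserving chunked process-pool
map whose contract is worker-count invariance: outputs are identical for
any `-np`. Ties in every ranking are broken by record id, all stochastic
stages (embedding, benchmark generation, random baseline) take explicit
seeds (default 42), and the container writer is byte-deterministic, so
screening outputs are byte-identical across reruns and worker counts.

## Problem sizes used in the checks

The automated checks run on programmatically generated inputs: a
20-molecule library for round-trip and ranking contracts, a 300-record
library for the load-speed comparison, a 3-record × ≤4-conformer database
for the exhaustive shape oracle, 1,000 random fingerprint pairs and 200
random score/label sets for the coefficient and AUC oracles, and the
30/1,500 synthetic benchmark (100 repetitions for the random baseline).

## Known limitations

- Screening quality on real targets is bounded by 2D fingerprints and
  hard-sphere shape overlap; no electrostatics, no Gaussian volumes, no
  protein context.
- The hard-sphere grid is O(volume/spacing³) per pair; the 0.4 Å default
  trades ~2% metric error for speed.
- Tautomer canonicalization follows one rule set; "canonical" is a
  convention, not a physical claim.
- The MUV loader expects the published tab-separated `.dat` layout from a
  local directory; no downloader is included (a pre-downloaded file is the
  supported path).
- Exact-match mode compares atom sets after substructure matching; it does
  not enforce stereochemistry unless chirality matching is enabled.
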