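# vscreen

Ligand-based virtual screening for medicinal and computational chemists:
given one or more query molecules, find the most similar compounds in a
library by **substructure**, **2D fingerprint similarity**, or **3D shape +
pharmacophore** matching — and validate any of these screening modes with a
leave-one-active-out ROC/AUC harness.

## What it computes

**Database preparation.** Libraries (SDF, SMILES, CSV) are standardized
(largest organic fragment kept, charges neutralized where a neutral form
exists, optional tautomer canonicalization), fingerprinted, optionally
embedded in 3D (ETKDGv3 conformers relaxed with MMFF94, UFF fallback), and
serialized into a versioned fast-loading container (`.vsdb`) so that a
screening run never re-perceives chemistry.

**2D similarity.** For binary fingerprints A and B with a = |A|, b = |B|,
c = |A∩B| and length n, eight coefficients are available:

| coefficient | formula | range |
|---|---|---|
| Tanimoto | c/(a+b−c) | [0,1] |
| Dice | 2c/(a+b) | [0,1] |
| Cosine | c/√(ab) | [0,1] |
| Sokal | c/(2a+2b−3c) | [0,1] |
| Russel | c/n | [0,1] |
| Kulczynski | c(a+b)/(2ab) | [0,1] |
| McConnaughey | (c(a+b)−ab)/(ab) | [−1,1] |
| Tversky | c/(α(a−c)+β(b−c)+c) | [0,1] |

Tversky(1,1) = Tanimoto and Tversky(½,½) = Dice. The default fingerprint is
an FCFP4-like Morgan fingerprint (radius 2, 2048 bits, pharmacophoric
feature invariants). Morgan/RDKit-path/topological-torsion/atom-pair/MACCS
families are supported.

**3D screening.** Every query conformer is aligned to every database
conformer (Open3DAlign, MMFF94 or Crippen-logP atom weights); shape
similarity is a volumetric Tanimoto V(A∩B)/V(A∪B) (Tversky and protrude
variants available) on a hard-sphere occupancy grid; the best-shape pair is
then scored with a binned 2-point 3D pharmacophore fingerprint, and the
**combo score** is the arithmetic mean of shape and pharmacophore
similarity.

**Validation.** The benchmark module implements the MUV-style protocol:
each active in turn becomes the query, the remaining actives are pooled
with all decoys, and performance is the tie-aware ROC AUC (Mann–Whitney
form, probability that a random active outranks a random decoy) averaged
over all splits. A synthetic actives/decoys generator (one decorated
scaffold class vs. an unrelated fragment background, 30 actives / 1,500
decoys by default) lets the whole harness run without downloading anything;
real MUV `.dat` files can be loaded from a local directory.

## Worked example

```bash
cat > demo.smi <<'EOF'
CCO ethanol
Cc1ccccc1 toluene
c1ccccc1 benzene
c1scnc1 thiazole
Cc1ccc(N)cc1 toluidine
CC(=O)Nc1ccc(O)cc1 paracetamol
CC(C)Cc1ccc(C(C)C(=O)O)cc1 ibuprofen
OC(=O)c1ccccc1OC(C)=O aspirin
EOF

vscreen preparedb -i demo.smi -o demo.vsdb -s
# wrote 8 records to demo.vsdb (0 skipped)

vscreen fpsim -i "Cc1ccc(O)cc1" -d demo.vsdb -o demo_hits.csv --top 4
# 4 hits -> demo_hits.csv
```

`demo_hits.csv` (query: p-cresol):

```
record_id,smiles,query,coefficient,score,rank
toluene,Cc1ccccc1,Cc1ccc(O)cc1,tanimoto,0.5384615384615384,1
toluidine,Cc1ccc(N)cc1,Cc1ccc(O)cc1,tanimoto,0.4117647058823529,2
paracetamol,CC(=O)Nc1ccc(O)cc1,Cc1ccc(O)cc1,tanimoto,0.34782608695652173,3
ibuprofen,CC(C)Cc1ccc(C(C)C(=O)O)cc1,Cc1ccc(O)cc1,tanimoto,0.2222222222222222,4
```

The hits are ranked by Tanimoto similarity of the default FCFP4-like
fingerprints: toluene and p-toluidine share the methyl-substituted ring
with the query, paracetamol shares the phenol, ibuprofen only the
para-substituted aromatic pattern. A substructure query works the same way:

```bash
vscreen substructure -i "c1scnc1" -d demo.vsdb -o demo_sub.csv
# 1 hits -> demo_sub.csv
#   record_id,smiles,query,n_matches,matched_atoms
#   thiazole,c1cscn1,c1scnc1,1,"0,1,2,3,4"
```

3D screening needs a conformer database (`vscreen preparedb -c`) and is run
with `vscreen shape`; `vscreen bench` runs the leave-one-active-out
validation (`--library synthetic` needs no input files and prints the mean
AUC with the random-ranking reference of 0.5).

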