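"""Virtual-screening validation harness (MUV-style leave-one-active-out).

The protocol: a labelled library of actives and decoys is split once per
active — that active becomes the query, the remaining actives are pooled
with all decoys as the validation set.  The screening method ranks the
validation set against the query and performance is summarized as the area
under the ROC curve (AUC), averaged over all splits (mean AUC).  Random
ranking has expected AUC 0.5.

The AUC is computed in tie-aware Mann-Whitney form — the probability that a
randomly chosen active outscores a randomly chosen decoy, with ties credited
1/2 — which equals exactly the trapezoidal integral of the tie-aware ROC
curve.

A synthetic actives/decoys generator emulates the structure of the MUV sets
(one small actives class sharing a chemotype, a large unrelated decoy
background) so the harness runs with no external download; real MUV ``.dat``
files can be loaded from a local directory instead.
"""

from __future__ import annotations

import os
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem

from . import dbprep, fpsim, shape as shape_mod
from .models import (
    ACTIVE,
    DECOY,
    EvalSplit,
    FingerprintSpec,
    LabeledLibrary,
    MoleculeRecord,
    ROCResult,
    VScreenError,
)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def make_splits(library: LabeledLibrary) -> list[EvalSplit]:
    """One leave-one-active-out split per active, in record order."""
    actives = [r.record_id for r in library.actives]
    if len(actives) < 2:
        raise VScreenError("leave-one-active-out validation needs >= 2 actives")
    if len(library.decoys) < 2:
        raise VScreenError("validation needs >= 2 decoys")
    splits = []
    for query_id in actives:
        val = [(r.record_id, library.labels[r.record_id])
               for r in library.records if r.record_id != query_id]
        splits.append(
            EvalSplit(
                query_id=query_id,
                validation_ids=tuple(v[0] for v in val),
                validation_labels=tuple(v[1] for v in val),
            )
        )
    return splits


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> ROCResult:
    """Tie-aware ROC curve and area for active-vs-decoy scores.

    The curve sweeps a threshold over the distinct score values from high
    to low; tied scores enter together, which draws a diagonal segment whose
    trapezoidal area contributes exactly the 1/2-credit of the rank form.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise VScreenError("scores and labels must have equal length")
    if not np.all(np.isfinite(scores)):
        raise VScreenError("scores must be finite")
    is_active = labels == ACTIVE
    n_pos = int(is_active.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise VScreenError("ROC needs at least one active and one decoy")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    a_sorted = is_active[order]
    # collapse ties: cumulative counts at each distinct threshold
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tp = np.cumsum(a_sorted)[distinct]
    fp = (distinct + 1) - tp
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc)


def rank_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Mann-Whitney AUC via midranks (identical to the ROC trapezoid)."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_active = labels == ACTIVE
    n_pos = int(is_active.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise VScreenError("AUC needs at least one active and one decoy")
    ranks = rankdata(scores)
    u = ranks[is_active].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# screening-method adapters
# ---------------------------------------------------------------------------


@dataclass
class FingerprintMethod:
    """2D fingerprint similarity as the ranking method."""

    spec: FingerprintSpec = None
    coefficient: str = "tanimoto"
    alpha: float = fpsim.DEFAULT_TVERSKY_ALPHA
    beta: float = fpsim.DEFAULT_TVERSKY_BETA

    def __post_init__(self):
        if self.spec is None:
            self.spec = FingerprintSpec()

    def prepare(self, records: Sequence[MoleculeRecord]) -> None:
        for r in records:
            if self.spec.key not in r.fingerprints:
                dbprep.compute_fingerprint(r, self.spec)

    def score(self, query: MoleculeRecord, records: Sequence[MoleculeRecord]) -> np.ndarray:
        qfp = query.fingerprints.get(self.spec.key)
        if qfp is None:
            qfp = dbprep.compute_fingerprint(query, self.spec)
        return np.array(
            [
                fpsim.similarity(
                    self.coefficient, *fpsim.bit_counts(qfp, r.fingerprints[self.spec.key]),
                    self.alpha, self.beta,
                )
                for r in records
            ]
        )


@dataclass
class ShapeMethod:
    """3D shape + pharmacophore combo score as the ranking method."""

    metric: str = "tanimoto"
    weighting: str = "mmff"
    rank_by: str = "combo"
    n_confs: int = 5
    seed: int = dbprep.DEFAULT_SEED
    spacing: float = shape_mod.DEFAULT_GRID_SPACING

    def prepare(self, records: Sequence[MoleculeRecord]) -> None:
        for i, r in enumerate(records):
            if not r.conformers:
                records[i].conformers = dbprep.generate_conformers(
                    r, max_confs=self.n_confs, seed=self.seed
                ).conformers

    def score(self, query: MoleculeRecord, records: Sequence[MoleculeRecord]) -> np.ndarray:
        query = shape_mod.embed_query(query, n_confs=self.n_confs, seed=self.seed)
        out = np.zeros(len(records))
        pick = {"combo": "combo", "shape": "shape_sim", "pharm": "pharm_sim"}[self.rank_by]
        for i, r in enumerate(records):
            hit = shape_mod.score_record(
                query, r, metric=self.metric, weighting=self.weighting, spacing=self.spacing
            )
            out[i] = getattr(hit, pick) if hit is not None else 0.0
        return out


@dataclass
class RandomMethod:
    """Uniform random scores — the null baseline (expected AUC 0.5)."""

    seed: int = 0

    def prepare(self, records: Sequence[MoleculeRecord]) -> None:
        pass

    def score(self, query: MoleculeRecord, records: Sequence[MoleculeRecord]) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        self.seed = int(rng.integers(0, 2**31 - 1))
        return rng.random(len(records))


@dataclass
class EvalResult:
    subset_name: str
    split_aucs: dict[str, float]  # query_id -> AUC

    @property
    def mean_auc(self) -> float:
        return float(statistics.fmean(self.split_aucs.values()))

    @property
    def std_auc(self) -> float:
        vals = list(self.split_aucs.values())
        return float(statistics.stdev(vals)) if len(vals) > 1 else 0.0


def run_eval(library: LabeledLibrary, method) -> EvalResult:
    """Run the full leave-one-active-out evaluation with any screening
    method exposing ``prepare(records)`` and ``score(query, records)``."""
    method.prepare(library.records)
    by_id = {r.record_id: r for r in library.records}
    split_aucs: dict[str, float] = {}
    for split in make_splits(library):
        query = by_id[split.query_id]
        records = [by_id[i] for i in split.validation_ids]
        scores = method.score(query, records)
        split_aucs[split.query_id] = roc_auc(scores, split.validation_labels).auc
    return EvalResult(subset_name=library.subset_name, split_aucs=split_aucs)


# ---------------------------------------------------------------------------
# synthetic benchmark generator
# ---------------------------------------------------------------------------

# scaffold cores for the actives class (one is picked per library)
_SCAFFOLDS = (
    "c1ccc(-c2nccs2)cc1",        # 2-phenylthiazole
    "c1ccc(-c2ncco2)cc1",        # 2-phenyloxazole
    "c1ccc(-c2nc3ccccc3s2)cc1",  # 2-phenylbenzothiazole
    "O=C(Nc1ccccc1)c1ccncc1",    # isonicotinanilide
)

# substituents appended to the scaffold to make decorated actives
_SUBSTITUENTS = (
    "C", "CC", "C(C)C", "O", "OC", "N", "NC", "F", "Cl", "Br",
    "C(F)(F)F", "C#N", "C(=O)N", "C(=O)OC", "S(C)(=O)=O", "CCO", "CN(C)C",
)

# unrelated fragment pool for the decoy background
_DECOY_FRAGMENTS = (
    "C1CCNCC1", "C1CCOC1", "C1CCCCC1", "C1CCNC1", "C1CCOCC1",
    "CCOCC", "CCNCC", "OCCO", "CC(C)CC", "CCCCC", "NCCCN",
    "CC(=O)CC", "COCCOC", "CC(O)CC", "CCSCC", "C1CC1", "C1CCC1",
)


def _attachment_points(mol: Chem.Mol) -> list[int]:
    pts = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() in (6, 7) and atom.GetTotalNumHs() > 0:
            pts.append(atom.GetIdx())
    return pts


def _attach(core: Chem.Mol, frag_smiles: str, core_atom: int) -> Chem.Mol | None:
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None:
        return None
    combo = Chem.RWMol(Chem.CombineMols(core, frag))
    frag_first = core.GetNumAtoms()
    try:
        combo.AddBond(core_atom, frag_first, Chem.BondType.SINGLE)
        mol = combo.GetMol()
        Chem.SanitizeMol(mol)
        return mol
    except Exception:
        return None


def generate_synthetic_benchmark(
    n_actives: int = 30,
    n_decoys: int = 1500,
    seed: int = 7,
    subset_name: str = "synthetic",
) -> LabeledLibrary:
    """Build a labelled actives/decoys library with MUV-like structure.

    Actives are decorated variants of one scaffold core (substituent types
    and positions varied, so every active contains the scaffold as a
    substructure and the class shares fingerprint bits); decoys are random
    combinations of unrelated aliphatic/ether/amine fragments, filtered to
    exclude the scaffold.  Deterministic per seed.
    """
    if n_actives < 2:
        raise VScreenError("need at least 2 actives")
    if n_decoys < n_actives:
        raise VScreenError("need at least as many decoys as actives")
    rng = np.random.default_rng(seed)
    scaffold_smiles = _SCAFFOLDS[int(rng.integers(len(_SCAFFOLDS)))]
    scaffold = Chem.MolFromSmiles(scaffold_smiles)
    scaffold_query = Chem.MolFromSmiles(scaffold_smiles)

    records: list[MoleculeRecord] = []
    labels: dict[str, str] = {}
    seen: set[str] = set()

    # actives: scaffold + 1-3 substituents at random positions
    idx = 0
    guard = 0
    while len(records) < n_actives and guard < 10000:
        guard += 1
        mol = Chem.Mol(scaffold)
        for _ in range(int(rng.integers(1, 4))):
            pts = _attachment_points(mol)
            if not pts:
                break
            sub = _SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]
            new = _attach(mol, sub, int(pts[int(rng.integers(len(pts)))]))
            if new is not None:
                mol = new
        smi = Chem.MolToSmiles(mol)
        if smi in seen or not mol.HasSubstructMatch(scaffold_query):
            continue
        seen.add(smi)
        rid = f"{subset_name}_A_{idx}"
        records.append(MoleculeRecord(record_id=rid, source_index=idx, mol=mol))
        labels[rid] = ACTIVE
        idx += 1
    if len(records) < n_actives:
        raise VScreenError("could not generate enough unique actives")

    # decoys: 2-4 unrelated fragments joined by single bonds
    guard = 0
    n_found = 0
    while n_found < n_decoys and guard < 100 * n_decoys:
        guard += 1
        mol = Chem.MolFromSmiles(_DECOY_FRAGMENTS[int(rng.integers(len(_DECOY_FRAGMENTS)))])
        for _ in range(int(rng.integers(1, 4))):
            pts = _attachment_points(mol)
            if not pts:
                break
            frag = _DECOY_FRAGMENTS[int(rng.integers(len(_DECOY_FRAGMENTS)))]
            new = _attach(mol, frag, int(pts[int(rng.integers(len(pts)))]))
            if new is not None:
                mol = new
        smi = Chem.MolToSmiles(mol)
        if smi in seen or mol.HasSubstructMatch(scaffold_query):
            continue
        seen.add(smi)
        rid = f"{subset_name}_D_{n_found}"
        records.append(
            MoleculeRecord(record_id=rid, source_index=n_actives + n_found, mol=mol)
        )
        labels[rid] = DECOY
        n_found += 1
    if n_found < n_decoys:
        raise VScreenError("could not generate enough unique decoys")

    return LabeledLibrary(
        records=records,
        labels=labels,
        subset_name=subset_name,
        scaffold_smiles=scaffold_smiles,
    )


# ---------------------------------------------------------------------------
# MUV .dat loader (user-supplied local files; no network access)
# ---------------------------------------------------------------------------


def load_muv_subset(directory: str | os.PathLike, subset: str) -> LabeledLibrary:
    """Load one MUV subset from the published tab-separated ``.dat`` layout
    (``cmp_list_MUV_<id>_actives.dat`` / ``..._decoys.dat`` with columns
    including a compound id and a SMILES) from a local directory."""
    directory = Path(directory)
    records: list[MoleculeRecord] = []
    labels: dict[str, str] = {}
    idx = 0
    for kind, label in (("actives", ACTIVE), ("decoys", DECOY)):
        path = directory / f"cmp_list_MUV_{subset}_{kind}.dat"
        if not path.is_file():
            raise VScreenError(f"MUV file not found: {path}")
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            cols = {c.strip().lower(): i for i, c in enumerate(header)}
            smi_col = next((i for c, i in cols.items() if "smile" in c), None)
            id_col = next((i for c, i in cols.items() if c in ("id", "cmp id", "pubchem cid")), 0)
            if smi_col is None:
                raise VScreenError(f"no SMILES column in {path}")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) <= smi_col:
                    continue
                mol = Chem.MolFromSmiles(parts[smi_col])
                if mol is None:
                    continue
                rid = f"MUV_{subset}_{'A' if label == ACTIVE else 'D'}_{parts[id_col]}"
                records.append(MoleculeRecord(record_id=rid, source_index=idx, mol=mol))
                labels[rid] = label
                idx += 1
    return LabeledLibrary(records=records, labels=labels, subset_name=f"MUV_{subset}")
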