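"""3D shape + pharmacophore screening.

The screening cascade for one query / database-molecule pair:

1.  every query conformer is aligned to every database conformer with
    Open3DAlign (atom weights from MMFF94 parameters or Crippen logP
    contributions);
2.  for each aligned pair a volumetric shape similarity is computed on a
    boolean occupancy grid (atoms as hard spheres of van der Waals radius);
3.  the conformer pair with the highest shape similarity is kept;
4.  on that pair a 3D pharmacophore fingerprint (2-point pharmacophores,
    six feature families, binned inter-feature distances) is generated for
    both molecules and compared by Tanimoto;
5.  the combo score is the arithmetic mean of shape and pharmacophore
    similarity, and the database is ranked by it (or by either component).

Shape metrics: ``tanimoto`` = V(A∩B)/V(A∪B) (symmetric), ``tversky`` with
weights alpha/beta on the two difference volumes, and ``protrude`` =
1 - V(A∖B)/V(A), which is deliberately asymmetric (it measures how little
of A sticks out of B).
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import ChemicalFeatures, rdMolAlign
from rdkit.Chem.Pharm2D import Generate as Pharm2DGenerate
from rdkit.Chem.Pharm2D.SigFactory import SigFactory
from rdkit import RDConfig

from . import dbprep
from .models import (
    AlignmentResult,
    Conformer,
    MoleculeRecord,
    ScreenDB,
    ShapeHit,
    VScreenError,
)

SHAPE_METRICS = ("tanimoto", "tversky", "protrude")
WEIGHTINGS = ("mmff", "crippen")
RANK_BY = ("combo", "shape", "pharm")

DEFAULT_GRID_SPACING = 0.4  # Å

# Bondi van der Waals radii (Å) for common organic elements
VDW_RADII = {
    1: 1.20, 5: 1.92, 6: 1.70, 7: 1.55, 8: 1.52, 9: 1.47,
    14: 2.10, 15: 1.80, 16: 1.80, 17: 1.75, 35: 1.85, 53: 1.98,
}
DEFAULT_VDW = 1.70

# 2-point pharmacophore schema: six feature families, five distance bins
PHARM_FEATURE_FAMILIES = (
    "Donor", "Acceptor", "Aromatic", "Hydrophobe", "PosIonizable", "NegIonizable",
)
PHARM_DISTANCE_BINS = [(0.0, 2.0), (2.0, 4.0), (4.0, 6.0), (6.0, 8.0), (8.0, 100.0)]

_SIG_FACTORY: SigFactory | None = None


def _sig_factory() -> SigFactory:
    global _SIG_FACTORY
    if _SIG_FACTORY is None:
        feat_factory = ChemicalFeatures.BuildFeatureFactory(
            os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
        )
        skip = [
            f for f in feat_factory.GetFeatureFamilies()
            if f not in PHARM_FEATURE_FAMILIES
        ]
        sig = SigFactory(feat_factory, minPointCount=2, maxPointCount=2, skipFeats=skip)
        sig.SetBins(PHARM_DISTANCE_BINS)
        sig.Init()
        _SIG_FACTORY = sig
    return _SIG_FACTORY


def pharm_fp_size() -> int:
    """Length of the 3D pharmacophore bit vector under the configured schema."""
    return _sig_factory().GetSigSize()


def vdw_radii(mol: Chem.Mol) -> np.ndarray:
    """Van der Waals radius per atom (Bondi table, 1.7 Å fallback)."""
    return np.array(
        [VDW_RADII.get(a.GetAtomicNum(), DEFAULT_VDW) for a in mol.GetAtoms()],
        dtype=float,
    )


# ---------------------------------------------------------------------------
# query embedding
# ---------------------------------------------------------------------------


def embed_query(
    query: MoleculeRecord, n_confs: int = 10, seed: int = dbprep.DEFAULT_SEED
) -> MoleculeRecord:
    """Ensure the query carries 3D conformers.

    A query that already has 3D coordinates (e.g. a bioactive pose read from
    an SDF) keeps exactly that single conformer; a 2D query is embedded with
    the same ETKDGv3 + force-field pipeline used for database preparation.
    Embedding failure is fatal for a query (unlike for database records).
    """
    if query.conformers:
        return query
    if query.mol.GetNumConformers() > 0 and query.mol.GetConformer().Is3D():
        out = query.copy()
        coords = np.array(query.mol.GetConformer().GetPositions(), dtype=float)
        out.conformers = [Conformer(conf_id=0, coordinates=coords, energy=0.0)]
        return out
    out = dbprep.generate_conformers(query, max_confs=n_confs, seed=seed)
    if not out.conformers:
        raise VScreenError(
            f"3D embedding failed for query {query.record_id!r} "
            f"({query.canonical_smiles})"
        )
    return out


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def align_pair(
    query_mol: Chem.Mol,
    query_conf_id: int,
    db_mol: Chem.Mol,
    db_conf_id: int,
    weighting: str = "mmff",
) -> AlignmentResult | None:
    """Rigidly align one database conformer onto one query conformer with
    Open3DAlign.  Returns None when the aligner cannot find a common feature
    support (the caller scores the pair 0)."""
    if weighting not in WEIGHTINGS:
        raise VScreenError(f"unknown alignment weighting {weighting!r}")
    if query_mol.GetNumAtoms() < 3 or db_mol.GetNumAtoms() < 3:
        raise VScreenError("alignment needs at least 3 atoms on both sides")
    try:
        if weighting == "mmff":
            o3a = rdMolAlign.GetO3A(
                db_mol, query_mol, prbCid=db_conf_id, refCid=query_conf_id
            )
        else:
            o3a = rdMolAlign.GetCrippenO3A(
                db_mol, query_mol, prbCid=db_conf_id, refCid=query_conf_id
            )
        _, mat = o3a.Trans()
        score = float(o3a.Score())
    except Exception:
        return None
    mat = np.asarray(mat, dtype=float)
    rotation = mat[:3, :3]
    translation = mat[:3, 3]
    coords = np.array(db_mol.GetConformer(db_conf_id).GetPositions(), dtype=float)
    aligned = coords @ rotation.T + translation
    return AlignmentResult(
        query_conf_id=query_conf_id,
        db_conf_id=db_conf_id,
        rotation=rotation,
        translation=translation,
        aligned_coords=aligned,
        align_score=score,
    )


# ---------------------------------------------------------------------------
# volumetric shape similarity
# ---------------------------------------------------------------------------


def _occupancy_grids(
    coords_a: np.ndarray,
    radii_a: np.ndarray,
    coords_b: np.ndarray,
    radii_b: np.ndarray,
    spacing: float,
) -> tuple[np.ndarray, np.ndarray]:
    all_coords = np.vstack([coords_a, coords_b])
    all_radii = np.concatenate([radii_a, radii_b])
    lo = (all_coords - all_radii[:, None]).min(axis=0) - spacing
    hi = (all_coords + all_radii[:, None]).max(axis=0) + spacing
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    axes = [lo[i] + spacing * np.arange(shape[i]) for i in range(3)]

    def fill(coords: np.ndarray, radii: np.ndarray) -> np.ndarray:
        occ = np.zeros(shape, dtype=bool)
        for center, r in zip(coords, radii):
            i0 = [max(0, int(np.floor((center[i] - r - lo[i]) / spacing))) for i in range(3)]
            i1 = [min(shape[i], int(np.ceil((center[i] + r - lo[i]) / spacing)) + 1) for i in range(3)]
            if any(i0[i] >= i1[i] for i in range(3)):
                continue
            dx = axes[0][i0[0]:i1[0]] - center[0]
            dy = axes[1][i0[1]:i1[1]] - center[1]
            dz = axes[2][i0[2]:i1[2]] - center[2]
            d2 = (
                dx[:, None, None] ** 2
                + dy[None, :, None] ** 2
                + dz[None, None, :] ** 2
            )
            occ[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= d2 <= r * r
        return occ

    return fill(coords_a, radii_a), fill(coords_b, radii_b)


def shape_similarity(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    metric: str = "tanimoto",
    radii_a: np.ndarray | float | None = None,
    radii_b: np.ndarray | float | None = None,
    spacing: float = DEFAULT_GRID_SPACING,
    alpha: float = 0.5,
    beta: float = 0.5,
) -> float:
    """Volumetric overlap similarity of two superposed coordinate sets.

    Atoms are hard spheres of van der Waals radius sampled on a regular
    grid of the given spacing; volumes are voxel counts.  Radii default to
    the generic carbon radius when not supplied (pass per-atom arrays from
    :func:`vdw_radii` for real molecules, or scalars for test spheres).
    """
    if metric not in SHAPE_METRICS:
        raise VScreenError(f"unknown shape metric {metric!r}; choose one of {SHAPE_METRICS}")
    coords_a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    coords_b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if coords_a.size == 0 or coords_b.size == 0:
        raise VScreenError("shape similarity needs non-empty coordinates")

    def as_radii(r, n):
        if r is None:
            return np.full(n, DEFAULT_VDW)
        r = np.asarray(r, dtype=float)
        return np.full(n, float(r)) if r.ndim == 0 else r

    ra = as_radii(radii_a, len(coords_a))
    rb = as_radii(radii_b, len(coords_b))
    occ_a, occ_b = _occupancy_grids(coords_a, ra, coords_b, rb, spacing)
    va = int(occ_a.sum())
    vb = int(occ_b.sum())
    inter = int((occ_a & occ_b).sum())
    if metric == "tanimoto":
        union = va + vb - inter
        return inter / union if union else 0.0
    if metric == "tversky":
        denom = alpha * (va - inter) + beta * (vb - inter) + inter
        return inter / denom if denom else 0.0
    # protrude: how little of A sticks out of B
    return 1.0 - (va - inter) / va if va else 0.0


# ---------------------------------------------------------------------------
# 3D pharmacophore fingerprint similarity
# ---------------------------------------------------------------------------


def pharm3d_fingerprint(mol: Chem.Mol, coords: np.ndarray) -> frozenset[int]:
    """On-bit set of the binned 2-point 3D pharmacophore fingerprint for one
    molecule at the given geometry."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    dmat = np.sqrt((diff ** 2).sum(axis=-1))
    fp = Pharm2DGenerate.Gen2DFingerprint(mol, _sig_factory(), dMat=dmat)
    return frozenset(fp.GetOnBits())


def pharm3d_similarity(
    mol_a: Chem.Mol,
    coords_a: np.ndarray,
    mol_b: Chem.Mol,
    coords_b: np.ndarray,
) -> float:
    """Tanimoto similarity of the two 3D pharmacophore fingerprints.

    A molecule in which no pharmacophore feature pair is perceived yields 0.
    """
    bits_a = pharm3d_fingerprint(mol_a, coords_a)
    bits_b = pharm3d_fingerprint(mol_b, coords_b)
    union = len(bits_a | bits_b)
    if union == 0 or not bits_a or not bits_b:
        return 0.0
    return len(bits_a & bits_b) / union


# ---------------------------------------------------------------------------
# the full shape search
# ---------------------------------------------------------------------------


def score_record(
    query: MoleculeRecord,
    record: MoleculeRecord,
    metric: str = "tanimoto",
    weighting: str = "mmff",
    spacing: float = DEFAULT_GRID_SPACING,
    alpha: float = 0.5,
    beta: float = 0.5,
) -> ShapeHit | None:
    """Evaluate all query-conformer x database-conformer pairs for one
    record; keep the pair maximizing shape similarity and score it with the
    3D pharmacophore fingerprint.  Returns None for records without
    conformers (skipped upstream)."""
    if not record.conformers:
        return None
    qmol = query.to_mol(with_conformers=True)
    dmol = record.to_mol(with_conformers=True)
    q_radii = vdw_radii(qmol)
    d_radii = vdw_radii(dmol)
    best: tuple[float, int, int, np.ndarray] | None = None
    for qc in query.conformers:
        q_coords = qc.coordinates
        for dc in record.conformers:
            aln = align_pair(qmol, qc.conf_id, dmol, dc.conf_id, weighting)
            if aln is None:
                continue
            s = shape_similarity(
                q_coords, aln.aligned_coords, metric,
                radii_a=q_radii, radii_b=d_radii,
                spacing=spacing, alpha=alpha, beta=beta,
            )
            if best is None or s > best[0]:
                best = (s, qc.conf_id, dc.conf_id, aln.aligned_coords)
    if best is None:
        return None
    shape_sim, q_id, d_id, aligned = best
    q_coords = next(c.coordinates for c in query.conformers if c.conf_id == q_id)
    pharm = pharm3d_similarity(qmol, q_coords, dmol, aligned)
    return ShapeHit(
        record_id=record.record_id,
        best_query_conf=q_id,
        best_db_conf=d_id,
        shape_sim=float(shape_sim),
        pharm_sim=float(pharm),
        combo=0.5 * (float(shape_sim) + float(pharm)),
        aligned_coords=aligned,
    )


class _ShapeTask:
    def __init__(self, query, metric, weighting, spacing, alpha, beta):
        self.query = query
        self.metric = metric
        self.weighting = weighting
        self.spacing = spacing
        self.alpha = alpha
        self.beta = beta

    def __call__(self, record: MoleculeRecord):
        return score_record(
            self.query, record, self.metric, self.weighting,
            self.spacing, self.alpha, self.beta,
        )


def shape_search(
    query: MoleculeRecord,
    db: ScreenDB | Sequence[MoleculeRecord],
    metric: str = "tanimoto",
    weighting: str = "mmff",
    rank_by: str = "combo",
    top_k: int = 10,
    n_query_confs: int = 10,
    seed: int = dbprep.DEFAULT_SEED,
    spacing: float = DEFAULT_GRID_SPACING,
    alpha: float = 0.5,
    beta: float = 0.5,
    n_workers: int = 1,
) -> list[ShapeHit]:
    """Shape + pharmacophore screening of a conformer database.

    Hits are sorted descending by the chosen score (``combo`` by default)
    with ties broken by record_id ascending; the top ``top_k`` are returned.
    """
    from .parallel import parallel_map

    if rank_by not in RANK_BY:
        raise VScreenError(f"unknown ranking {rank_by!r}; choose one of {RANK_BY}")
    records = list(db.records if isinstance(db, ScreenDB) else db)
    if not any(r.conformers for r in records):
        raise VScreenError(
            "database carries no conformers; prepare it with conformer "
            "generation enabled (preparedb -c)"
        )
    query = embed_query(query, n_confs=n_query_confs, seed=seed)
    task = _ShapeTask(query, metric, weighting, spacing, alpha, beta)
    hits = [h for h in parallel_map(task, records, n_workers) if h is not None]
    key = {"combo": lambda h: h.combo, "shape": lambda h: h.shape_sim, "pharm": lambda h: h.pharm_sim}[rank_by]
    hits.sort(key=lambda h: (-key(h), h.record_id))
    return hits[:top_k]
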