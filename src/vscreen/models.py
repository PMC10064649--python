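"""Core data containers shared by all screening modes.

The central object is the :class:`MoleculeRecord` — one library compound
carrying its structure, precomputed fingerprints and (optionally) a set of
3D conformers — and the :class:`ScreenDB`, an ordered collection of records
together with the preparation parameters that produced them.  Screening
results are small frozen hit objects (:class:`SubstructureHit`,
:class:`SimilarityHit`, :class:`ShapeHit`) that carry everything the
reporting layer needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem


class VScreenError(RuntimeError):
    """Base class for fatal errors raised by the screening pipeline."""


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BitFingerprint:
    """A fixed-length binary fingerprint stored as (length, on-bit set)."""

    n_bits: int
    on_bits: frozenset[int]

    def __post_init__(self) -> None:
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")
        if not isinstance(self.on_bits, frozenset):
            object.__setattr__(self, "on_bits", frozenset(self.on_bits))
        if self.on_bits and (min(self.on_bits) < 0 or max(self.on_bits) >= self.n_bits):
            raise ValueError("on-bit index out of range")

    @property
    def count(self) -> int:
        return len(self.on_bits)


FP_FAMILIES = ("morgan", "rdkit-path", "torsion", "atompair", "maccs")
MACCS_N_BITS = 167


@dataclass(frozen=True)
class FingerprintSpec:
    """Parameters that fully determine a fingerprint.

    ``radius`` is meaningful only for the Morgan family; ``use_features``
    switches the Morgan atom invariants from ECFP-like (connectivity) to
    FCFP-like (pharmacophoric features).  MACCS keys have a fixed length of
    167 bits and ignore ``n_bits``.
    """

    family: str = "morgan"
    radius: int = 2
    n_bits: int = 2048
    use_features: bool = True

    def __post_init__(self) -> None:
        if self.family not in FP_FAMILIES:
            raise VScreenError(
                f"unsupported fingerprint family {self.family!r}; "
                f"choose one of {FP_FAMILIES}"
            )
        if self.family == "maccs":
            object.__setattr__(self, "n_bits", MACCS_N_BITS)
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")

    @property
    def key(self) -> str:
        """Stable string key encoding every generation parameter."""
        if self.family == "maccs":
            return "maccs"
        if self.family == "morgan":
            feat = "fcfp" if self.use_features else "ecfp"
            return f"morgan-r{self.radius}-{self.n_bits}-{feat}"
        return f"{self.family}-{self.n_bits}"

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "radius": self.radius,
            "n_bits": self.n_bits,
            "use_features": self.use_features,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FingerprintSpec":
        return cls(**d)


# ---------------------------------------------------------------------------
# conformers and molecule records
# ---------------------------------------------------------------------------


@dataclass
class Conformer:
    """One 3D geometry: coordinates in Å (one triple per heavy atom) and the
    force-field energy after optimization (arbitrary units)."""

    conf_id: int
    coordinates: np.ndarray  # shape (n_atoms, 3), float64
    energy: float

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Conformer):
            return NotImplemented
        return (
            self.conf_id == other.conf_id
            and math.isclose(self.energy, other.energy, rel_tol=0, abs_tol=1e-9)
            and self.coordinates.shape == other.coordinates.shape
            and np.allclose(self.coordinates, other.coordinates, atol=1e-9)
        )


@dataclass
class MoleculeRecord:
    """One library compound with everything screening needs precomputed."""

    record_id: str
    source_index: int
    mol: Chem.Mol
    canonical_smiles: str = ""
    properties: dict[str, str] = field(default_factory=dict)
    fingerprints: dict[str, BitFingerprint] = field(default_factory=dict)
    conformers: list[Conformer] = field(default_factory=list)
    standardized: bool = False
    tautomer_canonicalized: bool = False

    def __post_init__(self) -> None:
        if self.mol is not None and not self.canonical_smiles:
            self.canonical_smiles = Chem.MolToSmiles(self.mol)

    @property
    def num_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    def copy(self) -> "MoleculeRecord":
        return MoleculeRecord(
            record_id=self.record_id,
            source_index=self.source_index,
            mol=Chem.Mol(self.mol),
            canonical_smiles=self.canonical_smiles,
            properties=dict(self.properties),
            fingerprints=dict(self.fingerprints),
            conformers=[
                Conformer(c.conf_id, c.coordinates.copy(), c.energy)
                for c in self.conformers
            ],
            standardized=self.standardized,
            tautomer_canonicalized=self.tautomer_canonicalized,
        )

    def to_mol(self, with_conformers: bool = False) -> Chem.Mol:
        """Return a copy of the structure, optionally with the stored 3D
        conformers attached as RDKit conformers (ids = ``conf_id``)."""
        mol = Chem.Mol(self.mol)
        if with_conformers:
            mol.RemoveAllConformers()
            for conf in self.conformers:
                if conf.coordinates.shape[0] != mol.GetNumAtoms():
                    raise VScreenError(
                        f"record {self.record_id}: conformer atom count "
                        f"{conf.coordinates.shape[0]} != structure atom count "
                        f"{mol.GetNumAtoms()}"
                    )
                c = Chem.Conformer(mol.GetNumAtoms())
                for i, (x, y, z) in enumerate(conf.coordinates):
                    c.SetAtomPosition(i, (float(x), float(y), float(z)))
                c.SetId(conf.conf_id)
                mol.AddConformer(c, assignId=False)
        return mol

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MoleculeRecord):
            return NotImplemented
        return (
            self.record_id == other.record_id
            and self.source_index == other.source_index
            and self.canonical_smiles == other.canonical_smiles
            and self.properties == other.properties
            and self.fingerprints == other.fingerprints
            and self.conformers == other.conformers
            and self.standardized == other.standardized
            and self.tautomer_canonicalized == other.tautomer_canonicalized
            and Chem.MolToSmiles(self.mol) == Chem.MolToSmiles(other.mol)
        )


SCREENDB_FORMAT_VERSION = 1


@dataclass
class ScreenDB:
    """A prepared screening database: records plus preparation parameters.

    Written to disk as a versioned container (see :mod:`vscreen.dbprep`);
    loading never re-perceives chemistry.
    """

    records: list[MoleculeRecord]
    prep_params: dict = field(default_factory=dict)
    format_version: int = SCREENDB_FORMAT_VERSION

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise VScreenError(f"duplicate record_id(s) in ScreenDB: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, record_id: str) -> MoleculeRecord:
        for r in self.records:
            if r.record_id == record_id:
                return r
        raise KeyError(record_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScreenDB):
            return NotImplemented
        return (
            self.format_version == other.format_version
            and self.prep_params == other.prep_params
            and self.records == other.records
        )


# ---------------------------------------------------------------------------
# hits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstructureHit:
    """All matches of one query pattern in one database record.

    ``matches`` are tuples of 0-based atom indices (input-file atom order),
    deduplicated by atom set so that symmetry-equivalent mappings of the
    same group count once.
    """

    record_id: str
    matches: tuple[tuple[int, ...], ...]

    @property
    def n_matches(self) -> int:
        return len(self.matches)


@dataclass(frozen=True)
class SimilarityHit:
    record_id: str
    coefficient: str
    score: float
    rank: int


@dataclass
class AlignmentResult:
    """A rigid motion aligning a database conformer into the query frame."""

    query_conf_id: int
    db_conf_id: int
    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    aligned_coords: np.ndarray  # (n_atoms, 3)
    align_score: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ShapeHit:
    record_id: str
    best_query_conf: int
    best_db_conf: int
    shape_sim: float
    pharm_sim: float
    combo: float
    aligned_coords: np.ndarray

    def __post_init__(self) -> None:
        expected = 0.5 * (self.shape_sim + self.pharm_sim)
        if abs(self.combo - expected) > 1e-12:
            raise ValueError("combo must be the mean of shape_sim and pharm_sim")


# ---------------------------------------------------------------------------
# benchmark containers
# ---------------------------------------------------------------------------

ACTIVE = "active"
DECOY = "decoy"


@dataclass
class LabeledLibrary:
    """A screening library with active/decoy labels (MUV-style)."""

    records: list[MoleculeRecord]
    labels: dict[str, str]
    subset_name: str = ""
    scaffold_smiles: str | None = None

    def __post_init__(self) -> None:
        for r in self.records:
            if r.record_id not in self.labels:
                raise VScreenError(f"record {r.record_id} has no label")
            if self.labels[r.record_id] not in (ACTIVE, DECOY):
                raise VScreenError(
                    f"label for {r.record_id} must be {ACTIVE!r} or {DECOY!r}"
                )

    @property
    def actives(self) -> list[MoleculeRecord]:
        return [r for r in self.records if self.labels[r.record_id] == ACTIVE]

    @property
    def decoys(self) -> list[MoleculeRecord]:
        return [r for r in self.records if self.labels[r.record_id] == DECOY]


@dataclass(frozen=True)
class EvalSplit:
    """One leave-one-active-out split: a single active as query, everything
    else (remaining actives pooled with all decoys) as validation set."""

    query_id: str
    validation_ids: tuple[str, ...]
    validation_labels: tuple[str, ...]


@dataclass
class ROCResult:
    """A tie-aware ROC curve and its area.

    The curve starts at (0, 0) and ends at (1, 1); ``auc`` equals the
    trapezoidal integral of the stored curve, which for the tie-aware
    construction coincides exactly with the Mann-Whitney rank statistic
    (ties credited 1/2).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if self.fpr[0] != 0.0 or self.tpr[0] != 0.0:
            raise ValueError("ROC curve must start at (0, 0)")
        if self.fpr[-1] != 1.0 or self.tpr[-1] != 1.0:
            raise ValueError("ROC curve must end at (1, 1)")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC curve must be non-decreasing")
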