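"""2D fingerprint similarity search.

Similarity between two binary fingerprints A and B is expressed through the
classic set statistics a = |A|, b = |B|, c = |A ∩ B| and the bit-vector
length n.  Eight coefficients are supported:

========== ==========================================
tanimoto        c / (a + b - c)
dice            2c / (a + b)
cosine          c / sqrt(a b)
sokal           c / (2a + 2b - 3c)
russel          c / n
kulczynski      c (a + b) / (2 a b)
mcconnaughey    (c (a + b) - a b) / (a b)      in [-1, 1]
tversky         c / (alpha (a-c) + beta (b-c) + c)
========== ==========================================

Any zero denominator yields 0 (two empty fingerprints are "dissimilar").
Tversky with alpha = beta = 1 reduces to Tanimoto and with
alpha = beta = 0.5 to Dice.
"""

from __future__ import annotations

import math
from typing import Sequence

from .dbprep import compute_fingerprint
from .models import (
    BitFingerprint,
    FingerprintSpec,
    MoleculeRecord,
    ScreenDB,
    SimilarityHit,
    VScreenError,
)

COEFFICIENTS = (
    "tanimoto",
    "tversky",
    "cosine",
    "dice",
    "sokal",
    "russel",
    "kulczynski",
    "mcconnaughey",
)

DEFAULT_TVERSKY_ALPHA = 0.5
DEFAULT_TVERSKY_BETA = 0.5


def bit_counts(fpA: BitFingerprint, fpB: BitFingerprint) -> tuple[int, int, int, int]:
    """Return (a, b, c, n) = (|A|, |B|, |A ∩ B|, n_bits)."""
    if fpA.n_bits != fpB.n_bits:
        raise VScreenError(
            f"fingerprint length mismatch: {fpA.n_bits} vs {fpB.n_bits}"
        )
    c = len(fpA.on_bits & fpB.on_bits)
    return len(fpA.on_bits), len(fpB.on_bits), c, fpA.n_bits


def similarity(
    coefficient: str,
    a: int,
    b: int,
    c: int,
    n: int,
    alpha: float = DEFAULT_TVERSKY_ALPHA,
    beta: float = DEFAULT_TVERSKY_BETA,
) -> float:
    """Evaluate one similarity coefficient from the bit-set statistics."""
    if coefficient == "tanimoto":
        denom = a + b - c
        return c / denom if denom else 0.0
    if coefficient == "dice":
        denom = a + b
        return 2.0 * c / denom if denom else 0.0
    if coefficient == "cosine":
        denom = math.sqrt(a * b)
        return c / denom if denom else 0.0
    if coefficient == "sokal":
        denom = 2 * a + 2 * b - 3 * c
        return c / denom if denom else 0.0
    if coefficient == "russel":
        return c / n if n else 0.0
    if coefficient == "kulczynski":
        denom = 2.0 * a * b
        return c * (a + b) / denom if denom else 0.0
    if coefficient == "mcconnaughey":
        denom = a * b
        return (c * (a + b) - a * b) / denom if denom else 0.0
    if coefficient == "tversky":
        denom = alpha * (a - c) + beta * (b - c) + c
        return c / denom if denom else 0.0
    raise VScreenError(
        f"unknown similarity coefficient {coefficient!r}; choose one of {COEFFICIENTS}"
    )


def fingerprint_similarity(
    fpA: BitFingerprint,
    fpB: BitFingerprint,
    coefficient: str = "tanimoto",
    alpha: float = DEFAULT_TVERSKY_ALPHA,
    beta: float = DEFAULT_TVERSKY_BETA,
) -> float:
    a, b, c, n = bit_counts(fpA, fpB)
    return similarity(coefficient, a, b, c, n, alpha, beta)


def _query_fp(query: MoleculeRecord, spec: FingerprintSpec) -> BitFingerprint:
    fp = query.fingerprints.get(spec.key)
    if fp is None:
        fp = compute_fingerprint(query, spec)
    return fp


def _record_fp(record: MoleculeRecord, spec: FingerprintSpec) -> BitFingerprint:
    fp = record.fingerprints.get(spec.key)
    if fp is None:
        if record.fingerprints:
            raise VScreenError(
                f"record {record.record_id} carries fingerprints "
                f"{sorted(record.fingerprints)} but the search needs {spec.key!r}; "
                "re-run preparedb with the matching fingerprint options"
            )
        fp = compute_fingerprint(record, spec)
    return fp


def fp_search(
    queries: MoleculeRecord | Sequence[MoleculeRecord],
    db: ScreenDB | Sequence[MoleculeRecord],
    spec: FingerprintSpec | None = None,
    coefficient: str = "tanimoto",
    top_k: int | None = 10,
    threshold: float | None = None,
    alpha: float = DEFAULT_TVERSKY_ALPHA,
    beta: float = DEFAULT_TVERSKY_BETA,
    n_workers: int = 1,
) -> list[list[SimilarityHit]]:
    """Rank the database against each query by fingerprint similarity.

    Database fingerprints stored under ``spec.key`` are used when present
    and computed on the fly otherwise.  Hits are sorted by descending score
    with ties broken by record_id ascending (so the ranking is deterministic
    and identical for any worker count); either the top ``top_k`` hits or
    all hits scoring at least ``threshold`` are returned per query.
    """
    from .parallel import parallel_map

    if isinstance(queries, MoleculeRecord):
        queries = [queries]
    spec = spec or FingerprintSpec()
    if coefficient not in COEFFICIENTS:
        raise VScreenError(f"unknown similarity coefficient {coefficient!r}")
    records = list(db.records if isinstance(db, ScreenDB) else db)
    db_fps = parallel_map(_FpTask(spec), records, n_workers)

    results: list[list[SimilarityHit]] = []
    for query in queries:
        qfp = _query_fp(query.copy(), spec)
        scored = [
            (similarity(coefficient, *bit_counts(qfp, fp), alpha, beta), r.record_id)
            for fp, r in zip(db_fps, records)
        ]
        scored.sort(key=lambda t: (-t[0], t[1]))
        if threshold is not None:
            scored = [t for t in scored if t[0] >= threshold]
        elif top_k is not None:
            scored = scored[: top_k]
        results.append(
            [
                SimilarityHit(record_id=rid, coefficient=coefficient, score=s, rank=i + 1)
                for i, (s, rid) in enumerate(scored)
            ]
        )
    return results


class _FpTask:
    def __init__(self, spec: FingerprintSpec):
        self.spec = spec

    def __call__(self, record: MoleculeRecord) -> BitFingerprint:
        return _record_fp(record, self.spec)


# ---------------------------------------------------------------------------
# atomic similarity maps
# ---------------------------------------------------------------------------


def similarity_map_weights(
    query: MoleculeRecord,
    hit: MoleculeRecord,
    spec: FingerprintSpec | None = None,
    coefficient: str = "tanimoto",
) -> list[float]:
    """Per-atom contributions of the hit molecule to its similarity with the
    query, via the bit-removal scheme: the weight of atom i is the drop in
    similarity when all fingerprint bits whose circular environments contain
    atom i are removed from the hit fingerprint.

    Only atom-attributable (Morgan-family) fingerprints are supported.
    """
    from rdkit.Chem import rdFingerprintGenerator

    spec = spec or FingerprintSpec()
    if spec.family != "morgan":
        raise VScreenError(
            "similarity maps need an atom-attributable fingerprint; "
            "use the morgan family"
        )
    inv = (
        rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
        if spec.use_features
        else None
    )
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=spec.radius, fpSize=spec.n_bits, atomInvariantsGenerator=inv
    )
    qfp = _query_fp(query.copy(), spec)

    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    bv = gen.GetFingerprint(hit.mol, additionalOutput=ao)
    bit_info = ao.GetBitInfoMap()
    hfp = BitFingerprint(spec.n_bits, frozenset(bv.GetOnBits()))
    base = fingerprint_similarity(qfp, hfp, coefficient)

    # atom -> bits whose environment (center, radius) touches the atom
    from rdkit import Chem

    mol = hit.mol
    atom_bits: list[set[int]] = [set() for _ in range(mol.GetNumAtoms())]
    for bit, envs in bit_info.items():
        for center, radius in envs:
            if radius == 0:
                atom_bits[center].add(bit)
                continue
            env = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
            atoms = {center}
            for bidx in env:
                bond = mol.GetBondWithIdx(bidx)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            for a in atoms:
                atom_bits[a].add(bit)

    weights = []
    for a in range(mol.GetNumAtoms()):
        reduced = BitFingerprint(spec.n_bits, hfp.on_bits - frozenset(atom_bits[a]))
        weights.append(base - fingerprint_similarity(qfp, reduced, coefficient))
    return weights
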