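"""Compound-library preparation: parsing, standardization, tautomer
canonicalization, fingerprints, conformers and the serialized screening
database.

The preparation pipeline mirrors common virtual-screening practice:

1.  parse an SDF / SMILES / CSV library into :class:`MoleculeRecord` objects;
2.  standardize each structure (keep the largest organic fragment, neutralize
    charges where a neutral form exists);
3.  optionally replace the structure by its canonical tautomer;
4.  precompute binary fingerprints and/or 3D conformers
    (ETKDGv3 embedding + MMFF94 optimization, UFF fallback);
5.  serialize everything into a versioned, fast-loading container so that a
    screening run never has to re-perceive chemistry.
"""

from __future__ import annotations

import base64
import gzip
import json
import os
from pathlib import Path
from typing import Iterable

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import (
    Descriptors,
    MACCSkeys,
    rdDistGeom,
    rdFingerprintGenerator,
    rdForceFieldHelpers,
)
from rdkit.Chem.MolStandardize import rdMolStandardize

from .models import (
    MACCS_N_BITS,
    SCREENDB_FORMAT_VERSION,
    BitFingerprint,
    Conformer,
    FingerprintSpec,
    MoleculeRecord,
    ScreenDB,
    VScreenError,
)

RDLogger.DisableLog("rdApp.*")

# heavy-atom RMSD below which a freshly embedded conformer is considered a
# duplicate of an already kept one and discarded before optimization
CONFORMER_PRUNE_RMSD = 0.5

DEFAULT_SEED = 42


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _records_from_mols(mols: Iterable[tuple[Chem.Mol | None, str | None]]):
    records: list[MoleculeRecord] = []
    skipped = 0
    for idx, (mol, name) in enumerate(mols):
        if mol is None:
            skipped += 1
            continue
        props = {k: str(v) for k, v in mol.GetPropsAsDict().items()}
        props.pop("_Name", None)
        rid = name
        if not rid and mol.HasProp("_Name"):
            rid = mol.GetProp("_Name").strip()
        if not rid:
            rid = f"mol_{idx}"
        records.append(
            MoleculeRecord(
                record_id=str(rid),
                source_index=idx,
                mol=mol,
                properties=props,
            )
        )
    return records, skipped


def parse_library(
    path: str | os.PathLike,
    format_hint: str | None = None,
    smiles_column: str = "smiles",
    id_column: str | None = None,
) -> tuple[list[MoleculeRecord], int]:
    """Parse a compound library file into molecule records.

    Supported formats: SDF (``.sdf``), SMILES (``.smi``/``.smiles``, one
    molecule per line with an optional whitespace-separated title), and CSV
    with a structure column (``smiles_column``).  Unparseable entries are
    skipped and counted, never fatal; an input from which *nothing* parses is.

    Returns ``(records, n_skipped)`` with ``source_index`` preserving the
    input order, so ``len(records) + n_skipped`` equals the number of entries
    in the file.
    """
    path = Path(path)
    if not path.is_file():
        raise VScreenError(f"library file not found: {path}")
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt in ("sdf", "sd"):
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        records, skipped = _records_from_mols((m, None) for m in supplier)
    elif fmt in ("smi", "smiles", "txt", "ism"):
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                parts = line.split(None, 1)
                mol = Chem.MolFromSmiles(parts[0])
                entries.append((mol, parts[1].strip() if len(parts) > 1 else None))
        records, skipped = _records_from_mols(entries)
    elif fmt == "csv":
        import pandas as pd

        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if smiles_column.lower() not in cols:
            raise VScreenError(
                f"CSV {path} has no structure column {smiles_column!r} "
                f"(columns: {list(df.columns)})"
            )
        scol = cols[smiles_column.lower()]
        icol = cols.get((id_column or "id").lower())
        entries = []
        for _, row in df.iterrows():
            mol = Chem.MolFromSmiles(str(row[scol]))
            if mol is not None:
                for c in df.columns:
                    if c not in (scol, icol):
                        mol.SetProp(c, str(row[c]))
            entries.append((mol, str(row[icol]) if icol else None))
        records, skipped = _records_from_mols(entries)
    else:
        raise VScreenError(f"unsupported library format {fmt!r} for {path}")
    if not records:
        raise VScreenError(f"no parseable records in {path}")
    # ensure unique ids; disambiguate collisions by source position
    seen: dict[str, int] = {}
    for r in records:
        if r.record_id in seen:
            r.record_id = f"{r.record_id}_{r.source_index}"
        seen[r.record_id] = r.source_index
    return records, skipped


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMER_ENUMERATOR: rdMolStandardize.TautomerEnumerator | None = None


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Fragment with the most heavy atoms among those containing carbon;
    ties broken by molecular weight, then by canonical SMILES."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]
    organic = [
        f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
    ] or list(frags)

    def sort_key(f: Chem.Mol):
        return (
            f.GetNumHeavyAtoms(),
            Descriptors.MolWt(f),
            # descending sort overall; invert SMILES comparison so that the
            # lexicographically smallest SMILES wins among exact ties
            tuple(-ord(c) for c in Chem.MolToSmiles(f)),
        )

    return max(organic, key=sort_key)


def standardize(record: MoleculeRecord) -> MoleculeRecord:
    """Reduce to the largest organic fragment and neutralize charges.

    Anions are protonated and cations deprotonated where a neutral form
    exists; permanent charges (e.g. quaternary nitrogen) are retained.  A
    structure that cannot be sanitized after the transformation is returned
    unchanged with ``properties["standardization_warning"]`` set.
    """
    out = record.copy()
    try:
        mol = _largest_organic_fragment(out.mol)
        Chem.SanitizeMol(mol)
        mol = _UNCHARGER.uncharge(mol)
        Chem.SanitizeMol(mol)
    except Exception as exc:  # unchanged record + warning per contract
        out.properties["standardization_warning"] = str(exc)
        return out
    out.mol = mol
    out.canonical_smiles = Chem.MolToSmiles(mol)
    out.standardized = True
    return out


def canonical_tautomer(record: MoleculeRecord, max_tautomers: int = 1000) -> MoleculeRecord:
    """Replace the structure by its canonical tautomer.

    Uses the standard tautomer scoring rules of the chemistry toolkit.  The
    pre-canonicalization SMILES is kept in ``properties["pre_tautomer_smiles"]``
    when it differs.  Idempotent: a record whose flag is already set is
    returned unchanged.  If enumeration fails the input tautomer is kept and
    a warning recorded.
    """
    if record.tautomer_canonicalized:
        return record
    global _TAUTOMER_ENUMERATOR
    if _TAUTOMER_ENUMERATOR is None:
        params = rdMolStandardize.CleanupParameters()
        params.maxTautomers = max_tautomers
        _TAUTOMER_ENUMERATOR = rdMolStandardize.TautomerEnumerator(params)
    out = record.copy()
    try:
        canon = _TAUTOMER_ENUMERATOR.Canonicalize(out.mol)
        if canon is None:
            raise ValueError("tautomer canonicalization returned nothing")
    except Exception as exc:
        out.properties["tautomer_warning"] = str(exc)
        return out
    new_smiles = Chem.MolToSmiles(canon)
    if new_smiles != out.canonical_smiles:
        out.properties["pre_tautomer_smiles"] = out.canonical_smiles
    out.mol = canon
    out.canonical_smiles = new_smiles
    out.tautomer_canonicalized = True
    return out


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------


def _fp_generator(spec: FingerprintSpec):
    if spec.family == "morgan":
        inv = (
            rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
            if spec.use_features
            else None
        )
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=spec.radius, fpSize=spec.n_bits, atomInvariantsGenerator=inv
        )
    if spec.family == "rdkit-path":
        return rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=spec.n_bits)
    if spec.family == "torsion":
        return rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=spec.n_bits)
    if spec.family == "atompair":
        return rdFingerprintGenerator.GetAtomPairGenerator(fpSize=spec.n_bits)
    raise VScreenError(f"unsupported fingerprint family {spec.family!r}")


def compute_fingerprint(record: MoleculeRecord, spec: FingerprintSpec) -> BitFingerprint:
    """Compute the fingerprint for one record and store it under ``spec.key``.

    Deterministic for a given structure and spec; the record is modified in
    place (the fingerprint is also returned).
    """
    if spec.family == "maccs":
        bv = MACCSkeys.GenMACCSKeys(record.mol)
        fp = BitFingerprint(MACCS_N_BITS, frozenset(bv.GetOnBits()))
    else:
        bv = _fp_generator(spec).GetFingerprint(record.mol)
        fp = BitFingerprint(spec.n_bits, frozenset(bv.GetOnBits()))
    record.fingerprints[spec.key] = fp
    return fp


# ---------------------------------------------------------------------------
# conformers
# ---------------------------------------------------------------------------


def generate_conformers(
    record: MoleculeRecord,
    max_confs: int = 20,
    seed: int = DEFAULT_SEED,
    forcefield: str = "mmff94",
) -> MoleculeRecord:
    """Attach up to ``max_confs`` optimized 3D conformers to a record.

    Hydrogens are added internally for ETKDGv3 embedding; near-duplicate
    geometries (heavy-atom RMSD < 0.5 Å) are pruned during embedding.  Each
    kept conformer is relaxed with MMFF94 (UFF if MMFF parameters are
    missing, recorded as a warning) and the final heavy-atom geometries are
    stored sorted by ascending energy.  Deterministic for a fixed seed.

    A record for which embedding fails entirely is returned with zero
    conformers and a warning property; shape screening skips it later.
    """
    out = record.copy()
    molH = Chem.AddHs(out.mol)
    params = rdDistGeom.ETKDGv3()
    params.randomSeed = int(seed)
    params.pruneRmsThresh = CONFORMER_PRUNE_RMSD
    params.onlyHeavyAtomsForRMS = True
    params.numThreads = 1
    conf_ids = rdDistGeom.EmbedMultipleConfs(molH, numConfs=int(max_confs), params=params)
    if len(conf_ids) == 0:
        params.useRandomCoords = True
        conf_ids = rdDistGeom.EmbedMultipleConfs(molH, numConfs=int(max_confs), params=params)
    if len(conf_ids) == 0:
        out.properties["conformer_warning"] = "3D embedding failed"
        out.conformers = []
        return out

    use_mmff = forcefield == "mmff94" and rdForceFieldHelpers.MMFFHasAllMoleculeParams(molH)
    if forcefield == "mmff94" and not use_mmff:
        out.properties["forcefield_warning"] = "MMFF94 parameters missing; used UFF"
    if use_mmff:
        results = rdForceFieldHelpers.MMFFOptimizeMoleculeConfs(molH, maxIters=500)
    else:
        results = rdForceFieldHelpers.UFFOptimizeMoleculeConfs(molH, maxIters=500)

    mol_noH = Chem.RemoveHs(molH)
    heavy = [
        (float(results[i][1]), cid) for i, cid in enumerate(conf_ids)
    ]
    heavy.sort(key=lambda t: (t[0], t[1]))
    confs: list[Conformer] = []
    for new_id, (energy, cid) in enumerate(heavy):
        coords = np.array(mol_noH.GetConformer(cid).GetPositions(), dtype=float)
        confs.append(Conformer(conf_id=new_id, coordinates=coords, energy=energy))
    out.conformers = confs
    return out


# ---------------------------------------------------------------------------
# serialization (.vsdb container)
# ---------------------------------------------------------------------------

_MAGIC = "vscreen-db"


def _record_to_payload(r: MoleculeRecord) -> dict:
    return {
        "record_id": r.record_id,
        "source_index": r.source_index,
        "mol": base64.b64encode(r.mol.ToBinary()).decode("ascii"),
        "canonical_smiles": r.canonical_smiles,
        "properties": r.properties,
        "fingerprints": {
            k: {"n_bits": fp.n_bits, "on_bits": sorted(fp.on_bits)}
            for k, fp in sorted(r.fingerprints.items())
        },
        "conformers": [
            {
                "conf_id": c.conf_id,
                "energy": c.energy,
                "coords": [round(float(v), 12) for v in c.coordinates.ravel()],
            }
            for c in r.conformers
        ],
        "standardized": r.standardized,
        "tautomer_canonicalized": r.tautomer_canonicalized,
    }


def _record_from_payload(d: dict) -> MoleculeRecord:
    mol = Chem.Mol(base64.b64decode(d["mol"]))
    confs = [
        Conformer(
            conf_id=c["conf_id"],
            coordinates=np.asarray(c["coords"], dtype=float).reshape(-1, 3),
            energy=float(c["energy"]),
        )
        for c in d["conformers"]
    ]
    return MoleculeRecord(
        record_id=d["record_id"],
        source_index=d["source_index"],
        mol=mol,
        canonical_smiles=d["canonical_smiles"],
        properties=dict(d["properties"]),
        fingerprints={
            k: BitFingerprint(v["n_bits"], frozenset(v["on_bits"]))
            for k, v in d["fingerprints"].items()
        },
        conformers=confs,
        standardized=d["standardized"],
        tautomer_canonicalized=d["tautomer_canonicalized"],
    )


def write_db(db: ScreenDB, path: str | os.PathLike) -> None:
    """Serialize a screening database to a versioned gzip-JSON container.

    Structures are stored in the toolkit's native binary form (base64) so
    that loading requires no chemistry re-perception; the gzip mtime is
    zeroed so identical databases produce byte-identical files.
    """
    payload = {
        "magic": _MAGIC,
        "format_version": db.format_version,
        "prep_params": db.prep_params,
        "records": [_record_to_payload(r) for r in db.records],
    }
    path = Path(path)
    with open(path, "wb") as raw:
        # empty filename + zero mtime keep the container byte-reproducible
        with gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0) as gz:
            gz.write(json.dumps(payload, separators=(",", ":")).encode())


def read_db(path: str | os.PathLike) -> ScreenDB:
    """Load a database written by :func:`write_db`.

    Raises a fatal error on a version mismatch (naming the found and
    expected versions) or on a truncated/corrupted file.
    """
    path = Path(path)
    if not path.is_file():
        raise VScreenError(f"database file not found: {path}")
    try:
        with gzip.open(path, "rb") as gz:
            payload = json.loads(gz.read().decode())
    except (OSError, EOFError, ValueError, UnicodeDecodeError) as exc:
        raise VScreenError(f"cannot read screening database {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("magic") != _MAGIC:
        raise VScreenError(f"{path} is not a vscreen screening database")
    version = payload.get("format_version")
    if version != SCREENDB_FORMAT_VERSION:
        raise VScreenError(
            f"unsupported database format_version {version} in {path} "
            f"(expected {SCREENDB_FORMAT_VERSION})"
        )
    return ScreenDB(
        records=[_record_from_payload(d) for d in payload["records"]],
        prep_params=payload["prep_params"],
        format_version=version,
    )


# ---------------------------------------------------------------------------
# high-level preparation pipeline
# ---------------------------------------------------------------------------


def prepare_db(
    path: str | os.PathLike,
    do_standardize: bool = True,
    do_tautomer: bool = False,
    fp_specs: list[FingerprintSpec] | None = None,
    max_confs: int = 0,
    seed: int = DEFAULT_SEED,
    format_hint: str | None = None,
    n_workers: int = 1,
) -> ScreenDB:
    """Full preparation pipeline: parse -> standardize -> (tautomer) ->
    fingerprints -> (conformers) -> ScreenDB."""
    from .parallel import parallel_map

    records, skipped = parse_library(path, format_hint=format_hint)
    if do_standardize:
        records = [standardize(r) for r in records]
    if do_tautomer:
        records = [canonical_tautomer(r) for r in records]
    specs = fp_specs or []
    for spec in specs:
        for r in records:
            compute_fingerprint(r, spec)
    if max_confs > 0:
        records = parallel_map(
            _ConformerTask(max_confs=max_confs, seed=seed), records, n_workers
        )
    prep_params = {
        "source": str(path),
        "skipped": skipped,
        "standardize": do_standardize,
        "tautomer_canonicalize": do_tautomer,
        "fingerprints": [s.to_dict() for s in specs],
        "max_confs": max_confs,
        "seed": seed,
        "forcefield": "mmff94",
    }
    return ScreenDB(records=records, prep_params=prep_params)


class _ConformerTask:
    """Picklable per-record conformer generation task for worker pools."""

    def __init__(self, max_confs: int, seed: int):
        self.max_confs = max_confs
        self.seed = seed

    def __call__(self, record: MoleculeRecord) -> MoleculeRecord:
        return generate_conformers(record, max_confs=self.max_confs, seed=self.seed)


def export_sdf(db: ScreenDB, path: str | os.PathLike) -> None:
    """Write every record (first conformer if present, else 2D) to an SDF."""
    writer = Chem.SDWriter(str(path))
    try:
        for r in db.records:
            mol = r.to_mol(with_conformers=bool(r.conformers))
            if not r.conformers:
                from rdkit.Chem import rdDepictor

                rdDepictor.Compute2DCoords(mol)
            mol.SetProp("_Name", r.record_id)
            for k, v in r.properties.items():
                mol.SetProp(k, v)
            writer.write(mol)
    finally:
        writer.close()
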