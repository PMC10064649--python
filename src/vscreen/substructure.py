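"""SMARTS / SMILES substructure search over a screening database.

Matches are reported as tuples of 0-based atom indices for depiction
highlighting.  Symmetry-equivalent mappings of the same group (e.g. the two
automorphic mappings of an unsubstituted ring) are deduplicated by atom set,
so ``n_matches`` counts distinct occurrences of the group, not mappings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem

from .models import MoleculeRecord, ScreenDB, SubstructureHit, VScreenError

QUERY_MODES = ("smarts", "smiles", "exact")


@dataclass
class SubstructureQuery:
    raw: str
    mode: str
    pattern: Chem.Mol = field(repr=False, default=None)
    use_chirality: bool = False


def compile_query(raw: str, mode: str = "smarts", use_chirality: bool = False) -> SubstructureQuery:
    """Compile a SMARTS or SMILES string into a substructure query.

    In ``smiles`` (smiles-as-substructure) mode the molecule is parsed as
    SMILES with aromaticity perceived and used as a pattern; hydrogen counts
    are not constrained.  ``exact`` mode additionally requires the match to
    cover the whole database molecule.
    """
    if not raw or not raw.strip():
        raise VScreenError("empty query string")
    if mode not in QUERY_MODES:
        raise VScreenError(f"unknown query mode {mode!r}; choose one of {QUERY_MODES}")
    raw = raw.strip()
    if mode == "smarts":
        pattern = Chem.MolFromSmarts(raw)
    else:
        pattern = Chem.MolFromSmiles(raw)
    if pattern is None or pattern.GetNumAtoms() == 0:
        raise VScreenError(f"cannot parse query {raw!r} as {mode}")
    return SubstructureQuery(raw=raw, mode=mode, pattern=pattern, use_chirality=use_chirality)


def match_record(query: SubstructureQuery, record: MoleculeRecord) -> SubstructureHit | None:
    """All unique matches of the query in one record, or None if it does not
    match.  Exact mode requires the match to span every atom of the record."""
    mol = record.mol
    matches = mol.GetSubstructMatches(
        query.pattern, uniquify=True, useChirality=query.use_chirality, maxMatches=10000
    )
    # deduplicate by atom set: automorphic mappings of one group count once
    seen: set[frozenset[int]] = set()
    unique: list[tuple[int, ...]] = []
    for m in matches:
        key = frozenset(m)
        if key not in seen:
            seen.add(key)
            unique.append(tuple(m))
    if query.mode == "exact":
        unique = [m for m in unique if len(set(m)) == mol.GetNumAtoms()]
    if not unique:
        return None
    return SubstructureHit(record_id=record.record_id, matches=tuple(unique))


def find_matches(
    query: SubstructureQuery,
    db: ScreenDB | Sequence[MoleculeRecord],
    n_workers: int = 1,
) -> list[SubstructureHit]:
    """Search the whole database; one hit per record with >= 1 match, ordered
    by source_index ascending.  Records with no match are omitted."""
    from .parallel import parallel_map

    records = list(db.records if isinstance(db, ScreenDB) else db)
    records = sorted(records, key=lambda r: r.source_index)
    results = parallel_map(_MatchTask(query), records, n_workers)
    return [h for h in results if h is not None]


class _MatchTask:
    def __init__(self, query: SubstructureQuery):
        self.query = query

    def __call__(self, record: MoleculeRecord):
        return match_record(self.query, record)
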