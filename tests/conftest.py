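"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import pytest
from rdkit import Chem
from rdkit.Chem import rdDepictor

from vscreen import dbprep
from vscreen.models import MoleculeRecord, ScreenDB

# a small, diverse drug-like library (SMILES, id)
LIBRARY_SMILES = [
    ("CCO", "ethanol"),
    ("CCN", "ethylamine"),
    ("c1ccccc1", "benzene"),
    ("Cc1ccccc1", "toluene"),
    ("CCOC", "methoxyethane"),
    ("c1scnc1", "thiazole"),
    ("CC(=O)O", "acetic_acid"),
    ("CCCCC", "pentane"),
    ("c1ccncc1", "pyridine"),
    ("OCCO", "glycol"),
    ("CC(C)O", "isopropanol"),
    ("CCS", "ethanethiol"),
    ("NCCN", "ethylenediamine"),
    ("c1ccc2ccccc2c1", "naphthalene"),
    ("CC(N)C(=O)O", "alanine"),
    ("CCCN", "propylamine"),
    ("COC(C)=O", "methyl_acetate"),
    ("CC#N", "acetonitrile"),
    ("c1ccoc1", "furan"),
    ("C1CCNCC1", "piperidine"),
]


def record_from_smiles(smiles: str, record_id: str = "mol", source_index: int = 0) -> MoleculeRecord:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    return MoleculeRecord(record_id=record_id, source_index=source_index, mol=mol)


@pytest.fixture(scope="session")
def library_records() -> list[MoleculeRecord]:
    return [
        record_from_smiles(smi, rid, i) for i, (smi, rid) in enumerate(LIBRARY_SMILES)
    ]


@pytest.fixture()
def library_db(library_records) -> ScreenDB:
    return ScreenDB(records=[r.copy() for r in library_records])


@pytest.fixture(scope="session")
def smiles_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("data") / "library.smi"
    path.write_text("".join(f"{smi} {rid}\n" for smi, rid in LIBRARY_SMILES))
    return path


@pytest.fixture(scope="session")
def sdf_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("data") / "library.sdf"
    writer = Chem.SDWriter(str(path))
    for i, (smi, rid) in enumerate(LIBRARY_SMILES):
        mol = Chem.MolFromSmiles(smi)
        rdDepictor.Compute2DCoords(mol)
        mol.SetProp("_Name", rid)
        mol.SetProp("source_smiles", smi)
        writer.write(mol)
    writer.close()
    return path


# feature-rich molecules for the 3D fixture database (donors, acceptors,
# aromatics, so pharmacophore fingerprints are non-empty)
SHAPE_FIXTURE_SMILES = [
    ("Nc1ccc(O)cc1", "aminophenol"),
    ("O=C(O)c1ccccc1", "benzoic_acid"),
    ("CCN(CC)CCO", "aminoalcohol"),
]


@pytest.fixture(scope="session")
def conformer_db() -> ScreenDB:
    """3-record database with <=4 optimized conformers per record."""
    records = []
    for i, (smi, rid) in enumerate(SHAPE_FIXTURE_SMILES):
        rec = record_from_smiles(smi, rid, i)
        records.append(dbprep.generate_conformers(rec, max_confs=4, seed=11))
    return ScreenDB(records=records, prep_params={"max_confs": 4, "seed": 11})
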