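"""Hit-list serialization: SDF, CSV, XLSX and paginated PDF reports, plus a
viewer-session export for 3D alignments.

The PDF report shows one hit per row: the 2D depiction on the left (with
substructure matches highlighted, or an atomic similarity map for
fingerprint searches) and the textual information (id, SMILES, query,
scores) on the right.  A PDF can only be generated in addition to an SDF,
Excel or CSV file — it is a visualization of a table, not the table itself.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdDepictor
from rdkit.Chem.Draw import rdMolDraw2D

from .models import (
    MoleculeRecord,
    ScreenDB,
    ShapeHit,
    SimilarityHit,
    SubstructureHit,
    VScreenError,
)

TABLE_FORMATS = ("sdf", "csv", "xlsx")
ALL_FORMATS = TABLE_FORMATS + ("pdf",)

HIGHLIGHT_RED = (1.0, 0.3, 0.3)


@dataclass
class ReportSpec:
    formats: tuple[str, ...] = ("csv",)
    rows_per_page: int = 4  # PDF pagination
    highlight_color: tuple[float, float, float] = HIGHLIGHT_RED
    similarity_maps: bool = False
    query_label: str = ""

    def __post_init__(self) -> None:
        unknown = [f for f in self.formats if f not in ALL_FORMATS]
        if unknown:
            raise VScreenError(f"unknown report format(s) {unknown}")
        if "pdf" in self.formats and not any(f in self.formats for f in TABLE_FORMATS):
            raise VScreenError(
                "a pdf can only be generated in addition to an sdf, excel or csv file"
            )


def _records_by_id(db) -> dict[str, MoleculeRecord]:
    records = db.records if isinstance(db, ScreenDB) else db
    return {r.record_id: r for r in records}


def _hit_row(hit, record: MoleculeRecord, query_label: str) -> dict:
    row = {
        "record_id": hit.record_id,
        "smiles": record.canonical_smiles,
        "query": query_label,
    }
    if isinstance(hit, SubstructureHit):
        row["n_matches"] = hit.n_matches
        row["matched_atoms"] = ";".join(",".join(map(str, m)) for m in hit.matches)
    elif isinstance(hit, SimilarityHit):
        row["coefficient"] = hit.coefficient
        row["score"] = repr(hit.score)
        row["rank"] = hit.rank
    elif isinstance(hit, ShapeHit):
        row["shape_sim"] = repr(hit.shape_sim)
        row["pharm_sim"] = repr(hit.pharm_sim)
        row["combo"] = repr(hit.combo)
        row["query_conf"] = hit.best_query_conf
        row["db_conf"] = hit.best_db_conf
    return row


def _hit_mol(hit, record: MoleculeRecord) -> Chem.Mol:
    """Molecule to serialize for one hit: the aligned 3D pose for shape
    hits, a 2D depiction-ready copy otherwise."""
    if isinstance(hit, ShapeHit):
        mol = Chem.Mol(record.mol)
        mol.RemoveAllConformers()
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, (x, y, z) in enumerate(hit.aligned_coords):
            conf.SetAtomPosition(i, (float(x), float(y), float(z)))
        mol.AddConformer(conf, assignId=True)
        return mol
    mol = Chem.Mol(record.mol)
    rdDepictor.Compute2DCoords(mol)
    return mol


def _depiction_png(hit, record: MoleculeRecord, spec: ReportSpec,
                   query: MoleculeRecord | None) -> bytes:
    if spec.similarity_maps and isinstance(hit, SimilarityHit) and query is not None:
        return _similarity_map_png(query, record)
    mol = Chem.Mol(record.mol)
    rdDepictor.Compute2DCoords(mol)
    drawer = rdMolDraw2D.MolDraw2DCairo(350, 300)
    highlight_atoms: list[int] = []
    highlight_bonds: list[int] = []
    if isinstance(hit, SubstructureHit):
        atoms = sorted({a for m in hit.matches for a in m})
        highlight_atoms = atoms
        aset = set(atoms)
        for bond in mol.GetBonds():
            if bond.GetBeginAtomIdx() in aset and bond.GetEndAtomIdx() in aset:
                highlight_bonds.append(bond.GetIdx())
    color = spec.highlight_color
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, mol,
        highlightAtoms=highlight_atoms,
        highlightBonds=highlight_bonds,
        highlightAtomColors={a: color for a in highlight_atoms},
        highlightBondColors={b: color for b in highlight_bonds},
    )
    drawer.FinishDrawing()
    return drawer.GetDrawingText()


def _similarity_map_png(query: MoleculeRecord, record: MoleculeRecord) -> bytes:
    """Render the bit-removal atomic contribution weights as a 2D similarity
    map (green = contributes positively to the similarity)."""
    import matplotlib
    matplotlib.use("Agg")
    from rdkit.Chem.Draw import SimilarityMaps

    from .fpsim import similarity_map_weights

    weights = similarity_map_weights(query, record)
    mol = Chem.Mol(record.mol)
    rdDepictor.Compute2DCoords(mol)
    drawer = rdMolDraw2D.MolDraw2DCairo(350, 300)
    SimilarityMaps.GetSimilarityMapFromWeights(mol, list(weights), draw2d=drawer)
    drawer.FinishDrawing()
    return drawer.GetDrawingText()


def write_hits(
    hits: Sequence,
    db,
    spec: ReportSpec,
    out_prefix: str,
    query: MoleculeRecord | None = None,
) -> list[Path]:
    """Write the hit list in every requested format.

    Returns the written paths.  Tabular formats are deterministic for fixed
    input (identical bytes on rewrite); the record-id sets of all formats
    are identical by construction.  Empty hit lists produce header-only
    CSV/XLSX and are an error for PDF/SDF.
    """
    by_id = _records_by_id(db)
    spec = spec  # validated in __post_init__
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = [_hit_row(h, by_id[h.record_id], spec.query_label) for h in hits]
    columns = list(rows[0].keys()) if rows else ["record_id", "smiles", "query"]
    df = pd.DataFrame(rows, columns=columns)
    written: list[Path] = []

    if "csv" in spec.formats:
        path = out_prefix.with_suffix(".csv")
        df.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    if "xlsx" in spec.formats:
        path = out_prefix.with_suffix(".xlsx")
        df.to_excel(path, index=False)
        written.append(path)
    if "sdf" in spec.formats:
        if not hits:
            raise VScreenError("cannot write an SDF for an empty hit list")
        path = out_prefix.with_suffix(".sdf")
        writer = Chem.SDWriter(str(path))
        try:
            for hit, row in zip(hits, rows):
                mol = _hit_mol(hit, by_id[hit.record_id])
                mol.SetProp("_Name", hit.record_id)
                for k, v in row.items():
                    mol.SetProp(k, str(v))
                writer.write(mol)
        finally:
            writer.close()
        written.append(path)
    if "pdf" in spec.formats:
        if not hits:
            raise VScreenError("cannot build a PDF report for an empty hit list")
        path = out_prefix.with_suffix(".pdf")
        _write_pdf(hits, rows, by_id, spec, path, query)
        written.append(path)
    return written


def _write_pdf(hits, rows, by_id, spec: ReportSpec, path: Path,
               query: MoleculeRecord | None) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages
    from PIL import Image

    rpp = max(1, spec.rows_per_page)
    metadata = {"CreationDate": datetime(2000, 1, 1), "ModDate": datetime(2000, 1, 1)}
    with PdfPages(path, metadata=metadata) as pdf:
        for start in range(0, len(hits), rpp):
            page_hits = list(zip(hits, rows))[start:start + rpp]
            fig, axes = plt.subplots(rpp, 2, figsize=(8.27, 11.69),
                                     gridspec_kw={"width_ratios": [1, 1.2]})
            axes = np.atleast_2d(axes)
            for ax in axes.ravel():
                ax.axis("off")
            for i, (hit, row) in enumerate(page_hits):
                png = _depiction_png(hit, by_id[hit.record_id], spec, query)
                img = Image.open(io.BytesIO(png))
                axes[i][0].imshow(img)
                text = "\n".join(f"{k}: {v}" for k, v in row.items())
                axes[i][1].text(0.0, 0.5, text, fontsize=8, va="center",
                                family="monospace", wrap=True)
            pdf.savefig(fig)
            plt.close(fig)


# ---------------------------------------------------------------------------
# 3D alignment session export
# ---------------------------------------------------------------------------


def write_session(
    query: MoleculeRecord,
    hits: Sequence[ShapeHit],
    db,
    out_prefix: str,
    max_hits: int = 10,
) -> Path:
    """Export the aligned top hits for visual inspection.

    Writes ``<prefix>_query.sdf`` (the query conformer of the best hit),
    ``<prefix>_hits.sdf`` (aligned hit poses with score tags) and a plain
    -text viewer script ``<prefix>_session.pml`` that loads both and colors
    the query green and the hits blue.  Overwrites deterministically.
    """
    hits = list(hits)[:max_hits]
    if not hits:
        raise VScreenError("session export needs at least one shape hit")
    for h in hits:
        if h.aligned_coords is None or len(h.aligned_coords) == 0:
            raise VScreenError(f"hit {h.record_id} has no aligned coordinates")
    by_id = _records_by_id(db)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    qpath = Path(f"{out_prefix}_query.sdf")
    qconf_id = hits[0].best_query_conf
    qmol = query.to_mol(with_conformers=True)
    qmol.SetProp("_Name", query.record_id)
    writer = Chem.SDWriter(str(qpath))
    try:
        writer.write(qmol, confId=qconf_id if qmol.GetNumConformers() else -1)
    finally:
        writer.close()

    hpath = Path(f"{out_prefix}_hits.sdf")
    writer = Chem.SDWriter(str(hpath))
    try:
        for hit in hits:
            mol = _hit_mol(hit, by_id[hit.record_id])
            mol.SetProp("_Name", hit.record_id)
            mol.SetProp("shape_sim", repr(hit.shape_sim))
            mol.SetProp("pharm_sim", repr(hit.pharm_sim))
            mol.SetProp("combo", repr(hit.combo))
            writer.write(mol)
    finally:
        writer.close()

    spath = Path(f"{out_prefix}_session.pml")
    lines = [
        "# alignment session: query (green) vs aligned hits (blue)",
        f"load {qpath.name}, {query.record_id}",
        f"load {hpath.name}, hits, multiplex=1",
        f"color green, {query.record_id}",
        "color blue, hits*",
        "show_as sticks",
        "zoom",
    ]
    for hit in hits:
        lines.append(f"# hit {hit.record_id}: combo={hit.combo:.4f}")
    spath.write_text("\n".join(lines) + "\n")
    return spath
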