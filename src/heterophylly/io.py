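"""Tab-separated readers/writers for every pipeline artifact.

All formats are headered TSV; gene identifiers are opaque strings.  Readers
validate structure (duplicate ids, non-integer counts, malformed headers)
and report the offending line number; ``write_x`` then ``read_x`` is the
identity on every type.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import OrthologyMap
from .de import REQUIRED_METADATA_COLUMNS, CountMatrix
from .morphometrics import CellContour

__all__ = [
    "read_counts", "write_counts",
    "read_orthology", "write_orthology",
    "read_deg_table", "write_deg_table",
    "read_contours", "write_contours",
    "read_annotation", "write_annotation",
    "read_table", "write_table",
]


class ParseError(ValueError):
    """Malformed input file; message names the file and the line."""


def _require_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: header lacks required columns {missing}")


def write_counts(counts: CountMatrix, counts_path, lengths_path, metadata_path) -> None:
    counts.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    counts.lengths.rename("effective_length").rename_axis("gene_id").to_csv(lengths_path, sep="\t")
    counts.metadata.to_csv(metadata_path, sep="\t", index=False)


def read_counts(counts_path, lengths_path, metadata_path) -> CountMatrix:
    table = pd.read_csv(counts_path, sep="\t", dtype={0: str})
    if table.columns[0] != "gene_id":
        raise ParseError(f"{counts_path}: first header column must be 'gene_id'")
    dup = table["gene_id"].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2  # +1 header, +1 one-based
        raise ParseError(f"{counts_path}:{line}: duplicate gene id {table['gene_id'][dup].iloc[0]!r}")
    table = table.set_index("gene_id")
    for col in table.columns:
        vals = table[col]
        if not np.issubdtype(vals.dtype, np.integer):
            bad = vals.index[~vals.apply(lambda v: float(v).is_integer())]
            if len(bad):
                line = int(table.index.get_loc(bad[0])) + 2
                raise ParseError(f"{counts_path}:{line}: non-integer count in sample {col!r}")
            table[col] = vals.astype(np.int64)

    lengths = pd.read_csv(lengths_path, sep="\t", dtype={0: str})
    _require_columns(lengths, ["gene_id", "effective_length"], lengths_path)
    lengths = lengths.set_index("gene_id")["effective_length"].astype(float)

    metadata = pd.read_csv(metadata_path, sep="\t", dtype=str)
    _require_columns(metadata, REQUIRED_METADATA_COLUMNS, metadata_path)
    metadata["replicate"] = metadata["replicate"].astype(int)
    return CountMatrix(table, lengths, metadata)


def write_orthology(ortho: OrthologyMap, path) -> None:
    table = ortho.links.copy()
    if ortho.orphans:
        orphan_rows = pd.DataFrame(
            {"ct_gene": "", "cp_gene": list(ortho.orphans), "relation": "orphan"}
        )
        table = pd.concat([table, orphan_rows], ignore_index=True)
    table.to_csv(path, sep="\t", index=False)


def read_orthology(path) -> OrthologyMap:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(table, ["ct_gene", "cp_gene", "relation"], path)
    orphans = table.loc[table["relation"] == "orphan", "cp_gene"].tolist()
    links = table[table["relation"] != "orphan"].reset_index(drop=True)
    return OrthologyMap(links=links, orphans=orphans)


DEG_COLUMNS = ["gene_id", "comparison", "log2fc", "pvalue", "qvalue", "call"]


def write_deg_table(table: pd.DataFrame, path) -> None:
    table[DEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_deg_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "comparison": str, "call": str})
    _require_columns(table, DEG_COLUMNS, path)
    dup = table["gene_id"].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2
        raise ParseError(f"{path}:{line}: duplicate gene id in DEG table")
    out = table.set_index("gene_id", drop=False)
    out.index.name = None
    return out


def write_contours(contours, path) -> None:
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.vertices):
            rows.append({"cell_id": c.cell_id, "group": c.group, "vertex_index": i, "x": x, "y": y})
    pd.DataFrame(rows, columns=["cell_id", "group", "vertex_index", "x", "y"]).to_csv(
        path, sep="\t", index=False
    )


def read_contours(path) -> list:
    table = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "group": str})
    _require_columns(table, ["cell_id", "group", "vertex_index", "x", "y"], path)
    contours = []
    for cell_id, block in table.groupby("cell_id", sort=False):
        block = block.sort_values("vertex_index")
        contours.append(
            CellContour(
                block[["x", "y"]].to_numpy(float),
                cell_id=cell_id,
                group=block["group"].iloc[0],
            )
        )
    return contours


def write_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "go_terms": str}, keep_default_na=False)
    _require_columns(table, ["gene_id", "has_orf", "is_tf"], path)
    table = table.set_index("gene_id")
    for col in ("has_orf", "is_tf"):
        table[col] = table[col].astype(str).str.lower().isin(["true", "1"])
    if "go_terms" not in table.columns:
        table["go_terms"] = ""
    return table


def write_table(table: pd.DataFrame, path, index: bool = True) -> None:
    """Generic TSV writer for report/enrichment/descriptor tables."""
    table.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
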