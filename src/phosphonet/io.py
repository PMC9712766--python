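"""Readers and writers for the pipeline's external formats.

Tabular inputs are plain TSV with a header row.  A site table carries the
fixed columns ``site_id, protein_id, residue, position`` (optionally
``window`` and ``localization_prob``); every remaining column is treated as a
sample intensity column.  Empty cells and ``"NA"`` are missing values; an
explicit 0 intensity is treated as missing with a warning (the label-free
quantification convention: 0 means "not observed", not "absent protein").

Term sets use the GMT dialect (``term_id TAB description TAB member...``),
sequences standard FASTA, and networks export to GraphML, SIF or node/edge
TSV tables (all Cytoscape-importable).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .core import SampleDesign, validate_site_table

logger = logging.getLogger("phosphonet")

SITE_META_COLUMNS = ["site_id", "protein_id", "residue", "position", "window", "localization_prob"]
_NA_VALUES = ["", "NA"]


def load_column_map(path: str | Path) -> dict[str, str]:
    """Load a YAML mapping of {input column name -> canonical column name}."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, dict):
        raise ValueError("column map must be a YAML mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def _read_intensity_block(df: pd.DataFrame, sample_cols: list[str], what: str) -> pd.DataFrame:
    mat = df[sample_cols].apply(pd.to_numeric, errors="raise").astype(float)
    if (mat.to_numpy() < 0).any():
        bad = mat.index[(mat < 0).any(axis=1)].tolist()
        raise ValueError(f"negative {what} intensity in rows: {bad}")
    if not np.isfinite(mat.to_numpy()[~np.isnan(mat.to_numpy())]).all():
        raise ValueError(f"non-finite {what} intensity encountered")
    n_zero = int((mat == 0).sum().sum())
    if n_zero:
        logger.warning("%d zero %s intensities treated as missing", n_zero, what)
        mat = mat.mask(mat == 0)
    return mat


def read_site_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a phosphosite TSV into (site table, site x sample intensity matrix)."""
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False, dtype={0: str})
    if column_map:
        df = df.rename(columns=column_map)
    meta_cols = [c for c in SITE_META_COLUMNS if c in df.columns]
    table = df[meta_cols].copy()
    table["site_id"] = table["site_id"].astype(str)
    table["position"] = table["position"].astype(int)
    validate_site_table(table)
    sample_cols = [c for c in df.columns if c not in SITE_META_COLUMNS]
    mat = _read_intensity_block(df.set_index(df["site_id"].to_numpy()), sample_cols, "site")
    mat.index.name = "site_id"
    return table.reset_index(drop=True), mat


def write_site_table(path: str | Path, table: pd.DataFrame, intensities: pd.DataFrame) -> None:
    validate_site_table(table)
    meta_cols = [c for c in SITE_META_COLUMNS if c in table.columns]
    out = table[meta_cols].set_index("site_id").join(intensities, how="left")
    out.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_protein_table(path: str | Path) -> pd.DataFrame:
    """Read a protein TSV (protein_id + sample columns) into an intensity matrix."""
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False, dtype={0: str})
    if "protein_id" not in df.columns:
        raise ValueError("protein table must have a protein_id column")
    ids = df["protein_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"duplicate protein_id values: {sorted(set(ids[ids.duplicated()]))}")
    sample_cols = [c for c in df.columns if c != "protein_id"]
    mat = _read_intensity_block(df.set_index(ids.to_numpy()), sample_cols, "protein")
    mat.index.name = "protein_id"
    return mat


def write_protein_table(path: str | Path, intensities: pd.DataFrame) -> None:
    out = intensities.copy()
    out.index.name = "protein_id"
    out.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("design table needs sample_id and group columns")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in design table")
    return SampleDesign(dict(zip(df["sample_id"], df["group"])))


def write_design(path: str | Path, design: SampleDesign) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Parse a GMT file into {term_id: (term_name, member set)}.

    Duplicate members within a line are deduplicated (set semantics); a line
    with fewer than three fields is an error reported with its line number.
    """
    terms: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            term_id, name, *members = fields
            if term_id in terms:
                raise ValueError(f"GMT line {lineno}: duplicate term_id {term_id!r}")
            member_set = {m for m in members if m}
            if not member_set:
                raise ValueError(f"GMT line {lineno}: term {term_id!r} has no members")
            terms[term_id] = (name, member_set)
    if not terms:
        logger.warning("GMT file %s is empty", path)
    return terms


def write_gmt(path: str | Path, terms: dict[str, tuple[str, set[str]]]) -> None:
    with open(path, "w") as fh:
        for term_id, (name, members) in terms.items():
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences; id = first whitespace token of the header."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(path: str | Path, seqs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in seqs.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --- network serialization -------------------------------------------------

NETWORK_FORMATS = ("graphml", "sif", "tables")


def _clean_attrs(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if v is None:
            continue
        if isinstance(v, float) and np.isnan(v):
            continue
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        out[k] = v
    return out


def write_network(net: nx.DiGraph, path: str | Path, fmt: str = "graphml") -> list[Path]:
    """Export a typed network; returns the paths written.

    ``graphml`` round-trips through :func:`read_network_graphml`; ``sif``
    writes ``source TAB interaction TAB target`` lines; ``tables`` writes
    Cytoscape-importable node and edge attribute TSVs.
    """
    path = Path(path)
    if fmt == "graphml":
        clean = nx.DiGraph()
        for n, d in net.nodes(data=True):
            clean.add_node(n, **_clean_attrs(d))
        for u, v, d in net.edges(data=True):
            clean.add_edge(u, v, **_clean_attrs(d))
        nx.write_graphml(clean, path)
        return [path]
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in sorted(net.edges(data=True)):
                fh.write(f"{u}\t{d.get('edge_type', 'interacts')}\t{v}\n")
        return [path]
    if fmt == "tables":
        node_path = path.with_suffix(".nodes.tsv")
        edge_path = path.with_suffix(".edges.tsv")
        nodes = pd.DataFrame(
            [{"id": n, **_clean_attrs(d)} for n, d in sorted(net.nodes(data=True))]
        )
        edges = pd.DataFrame(
            [
                {"source": u, "target": v, **_clean_attrs(d)}
                for u, v, d in sorted(net.edges(data=True))
            ]
        )
        nodes.to_csv(node_path, sep="\t", index=False, na_rep="NA")
        edges.to_csv(edge_path, sep="\t", index=False, na_rep="NA")
        return [node_path, edge_path]
    raise ValueError(f"unknown network format {fmt!r}; expected one of {NETWORK_FORMATS}")


def read_network_graphml(path: str | Path) -> nx.DiGraph:
    g = nx.read_graphml(path)
    return nx.DiGraph(g)
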