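"""Readers and writers for every on-disk format the pipeline touches.

All tables are tab-separated with a mandatory header row.  Gene identifiers
are opaque case-sensitive strings; no namespace (HGNC, Ensembl, ...) is
assumed.  Gene sets use the GMT dialect: one set per line, tab-separated
name, description, then member genes.
"""
from __future__ import annotations

import logging
import os
import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    CountMatrix,
    CoexpressionNetwork,
    GeneAnnotation,
    GeneSetCollection,
    LevelAssignment,
    RegulatoryTable,
    SampleDesign,
)

logger = logging.getLogger("stagewise")

_METADATA_COLUMNS = ["sample_id", "stage", "replicate", "batch"]
_TRR_COLUMNS = ["tf", "target", "source"]


def read_sample_metadata(path: str) -> SampleDesign:
    """Read the sample-metadata TSV (sample_id, stage, replicate, batch)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"metadata {path} is missing columns {missing}; expected header "
            f"{_METADATA_COLUMNS}"
        )
    df["stage"] = df["stage"].astype(int)
    return SampleDesign.from_frame(df)


def read_counts(path: str, metadata_path: str) -> CountMatrix:
    """Read a gene x sample raw count TSV together with its sample metadata.

    The first column of the counts file is the gene id; the remaining
    columns are samples.  Columns are re-ordered to match the metadata rows.
    Non-integer or negative entries are rejected with the offending cell
    named.
    """
    design = read_sample_metadata(metadata_path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    for sid in df.columns:
        if sid not in design.sample_ids:
            raise ValueError(f"sample {sid!r} in counts file is missing from metadata")
    for sid in design.sample_ids:
        if sid not in df.columns:
            raise ValueError(f"sample {sid!r} in metadata is missing from counts file")
    df = df[list(design.sample_ids)]
    arr = df.to_numpy()
    bad = ~np.isfinite(arr.astype(float)) | (arr.astype(float) != np.floor(arr.astype(float)))
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    cm = CountMatrix(counts=df.astype(np.int64), design=design)
    logger.info("read_counts: %d genes x %d samples from %s", cm.n_genes, cm.n_samples, path)
    return cm


def write_counts(cm: CountMatrix, counts_path: str, metadata_path: str) -> None:
    cm.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    cm.design.to_frame().to_csv(metadata_path, sep="\t", index=False)


def read_tf_list(path: str) -> GeneAnnotation:
    """Plain-text TF list, one gene id per line; blank lines ignored."""
    with open(path) as fh:
        genes = [line.strip() for line in fh]
    return GeneAnnotation(tf_genes=frozenset(g for g in genes if g))


def write_tf_list(annotation: GeneAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(annotation.tf_genes):
            fh.write(g + "\n")


def read_gene_sets(path: str) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member genes..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, frozenset(m for m in members if m))
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_regulatory_table(path: str) -> RegulatoryTable:
    """Read a TF -> target regulatory TSV with tf, target, source columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TRR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"regulatory table {path} is missing columns {missing}; expected "
            f"header {_TRR_COLUMNS}"
        )
    table = RegulatoryTable.from_records(df[_TRR_COLUMNS].itertuples(index=False, name=None))
    if table.self_loops:
        logger.warning(
            "read_regulatory_table: %d self-loop(s) kept, e.g. %s",
            len(table.self_loops),
            table.self_loops[0],
        )
    return table


def write_regulatory_table(table: RegulatoryTable, path: str) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str) -> str:
    """Write any result table as TSV (no index)."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def write_level_assignment(assignment: LevelAssignment, path: str) -> str:
    return write_table(assignment.to_frame(), path)


def network_tables(graph: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for an (optionally annotated) network.

    Edge attributes ``pcc``, ``trr_supported`` and ``source_labels`` are
    emitted when present; ``source_labels`` is serialized comma-joined.
    """
    node_rows = []
    for n, d in sorted(graph.nodes(data=True)):
        node_rows.append({"gene": n, **{k: d[k] for k in sorted(d)}})
    node_df = pd.DataFrame(node_rows, columns=None if node_rows else ["gene"])
    edge_rows = []
    for u, v, d in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1])):
        a, b = sorted((u, v))
        row: dict[str, object] = {"gene_a": a, "gene_b": b}
        for k in sorted(d):
            val = d[k]
            if k == "source_labels":
                val = ",".join(sorted(val))
            row[k] = val
        edge_rows.append(row)
    cols = ["gene_a", "gene_b"]
    if edge_rows:
        cols += [c for c in edge_rows[0] if c not in cols]
    edge_df = pd.DataFrame(edge_rows, columns=cols)
    return node_df, edge_df


def write_network(graph: nx.Graph, node_path: str, edge_path: str) -> tuple[str, str]:
    node_df, edge_df = network_tables(graph)
    return write_table(node_df, node_path), write_table(edge_df, edge_path)


def read_network(node_path: str, edge_path: str) -> nx.Graph:
    """Rebuild a network from its node/edge tables (inverse of write_network)."""
    g = nx.Graph()
    node_df = pd.read_csv(node_path, sep="\t", dtype={"gene": str})
    for _, row in node_df.iterrows():
        attrs = {k: row[k] for k in node_df.columns if k != "gene" and pd.notna(row[k])}
        g.add_node(row["gene"], **attrs)
    edge_df = pd.read_csv(edge_path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    for _, row in edge_df.iterrows():
        attrs = {}
        for k in edge_df.columns:
            if k in ("gene_a", "gene_b") or pd.isna(row[k]):
                continue
            if k == "source_labels":
                attrs[k] = frozenset(s for s in str(row[k]).split(",") if s)
            else:
                attrs[k] = row[k]
        if "source_labels" in edge_df.columns and "source_labels" not in attrs:
            attrs["source_labels"] = frozenset()
        g.add_edge(row["gene_a"], row["gene_b"], **attrs)
    return g


def write_network_pair(
    net: CoexpressionNetwork, out_dir: str, prefix: str
) -> tuple[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    return write_network(
        net.graph,
        os.path.join(out_dir, f"{prefix}_nodes.tsv"),
        os.path.join(out_dir, f"{prefix}_edges.tsv"),
    )
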