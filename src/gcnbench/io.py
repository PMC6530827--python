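"""Readers and writers for the interchange formats.

Everything tabular is TSV (expression matrices, sample designs,
partitions, annotations, regulatory edge lists); networks round-trip as
weighted edge-list TSV or GraphML (Cytoscape-compatible). Writers accept
a ``meta`` mapping that is emitted as ``#``-prefixed header comments
(tool version, config hash, seed); readers skip such comments.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .community import Partition
from .enrichment import AnnotationTable, EnrichmentResult
from .errors import ParseError
from .network import DirectedRegNet, Network, canonical_edge

__all__ = [
    "read_expression", "write_expression",
    "read_design", "write_design",
    "read_network", "write_network",
    "read_partition", "write_partition",
    "read_annotations", "write_annotations",
    "read_regnet", "write_regnet",
    "write_enrichment",
]


def _header_lines(meta: Mapping[str, object] | None) -> list[str]:
    items = {"tool": f"gcnbench v{__version__}"}
    if meta:
        items.update({str(k): v for k, v in meta.items()})
    return ["# " + " | ".join(f"{k}={v}" for k, v in items.items())]


def _data_lines(path: str) -> list[tuple[int, str]]:
    """(1-based line number, content) for non-comment non-blank lines."""
    try:
        with open(path) as fh:
            raw = fh.readlines()
    except FileNotFoundError:
        raise ParseError(f"{path}: file not found")
    return [
        (i, line.rstrip("\n"))
        for i, line in enumerate(raw, start=1)
        if line.strip() and not line.startswith("#")
    ]


# -- expression matrices ----------------------------------------------------

def read_expression(path: str) -> pd.DataFrame:
    """Genes × samples TSV: gene-id first column, sample-id header row."""
    lines = _data_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty expression file")
    header = lines[0][1].split("\t")
    samples = header[1:]
    if not samples:
        raise ParseError(f"{path}:{lines[0][0]}: header has no sample columns")
    if len(set(samples)) != len(samples):
        raise ParseError(f"{path}: duplicate sample ids in header")
    genes, rows = [], []
    seen: set[str] = set()
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, found {len(fields)}"
            )
        gene = fields[0]
        if gene in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        seen.add(gene)
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})")
        genes.append(gene)
    if not genes:
        raise ParseError(f"{path}: no gene rows")
    return pd.DataFrame(rows, index=genes, columns=samples)


def write_expression(matrix: pd.DataFrame, path: str,
                     meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("gene_id\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for gene, row in zip(matrix.index, matrix.to_numpy()):
            fh.write(str(gene) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


# -- sample design ----------------------------------------------------------

def read_design(path: str) -> pd.DataFrame:
    lines = _data_lines(path)
    if len(lines) < 2:
        raise ParseError(f"{path}: empty design file")
    header = lines[0][1].split("\t")
    if header[:3] != ["sample_id", "condition_id", "replicate"]:
        raise ParseError(f"{path}:{lines[0][0]}: expected columns sample_id, condition_id, replicate")
    records = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 fields")
        records.append((fields[0], fields[1], int(fields[2])))
    df = pd.DataFrame(records, columns=["sample_id", "condition_id", "replicate"])
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    return df.set_index("sample_id")


def write_design(design: pd.DataFrame, path: str,
                 meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("sample_id\tcondition_id\treplicate\n")
        for sid, row in design.iterrows():
            fh.write(f"{sid}\t{row['condition_id']}\t{row['replicate']}\n")


# -- networks ---------------------------------------------------------------

def _infer_format(path: str, fmt: str | None) -> str:
    if fmt:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext == ".graphml":
        return "graphml"
    if ext in (".tsv", ".txt", ".edges"):
        return "edgelist_tsv"
    raise ParseError(f"{path}: cannot infer network format from extension {ext!r}")


def read_network(path: str, fmt: str | None = None) -> Network:
    fmt = _infer_format(path, fmt)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        if g.is_directed():
            raise ParseError(
                f"{path}: GraphML is directed; collapse with benchmark.undirect_network first"
            )
        for a, b in nx.selfloop_edges(g):
            raise ParseError(f"{path}: self-loop on node {a!r}")
        return Network.from_networkx(g)
    if fmt != "edgelist_tsv":
        raise ParseError(f"unknown network format {fmt!r}")
    net = Network()
    lines = _data_lines(path)
    for lineno, line in lines:
        fields = line.split("\t")
        if fields[0] in ("gene_a", "source"):  # optional header row
            continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected at least 2 fields")
        a, b = fields[0], fields[1]
        w = float(fields[2]) if len(fields) > 2 else 1.0
        if a == b:
            raise ParseError(f"{path}:{lineno}: self-loop on {a!r}")
        if net.has_edge(a, b):
            raise ParseError(f"{path}:{lineno}: duplicate edge {canonical_edge(a, b)}")
        net.add_edge(a, b, w)
    return net


def write_network(net: Network, path: str, fmt: str | None = None,
                  meta: Mapping[str, object] | None = None) -> None:
    fmt = _infer_format(path, fmt)
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
        return
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in net:  # canonical lexicographic order
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


# -- partitions -------------------------------------------------------------

def read_partition(path: str, network: Network | None = None) -> Partition:
    lines = _data_lines(path)
    genes, labels = [], []
    for lineno, line in lines:
        fields = line.split("\t")
        if fields[0] == "gene":
            continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected (gene, module_id)")
        genes.append(fields[0])
        labels.append(int(fields[1]))
    if not genes:
        raise ParseError(f"{path}: empty partition file")
    return Partition.from_labels(genes, labels, network=network, method="external")


def write_partition(partition: Partition, path: str,
                    meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("gene\tmodule_id\n")
        for gene in sorted(partition.module_of):
            fh.write(f"{gene}\t{partition.module_of[gene]}\n")


# -- annotations ------------------------------------------------------------

def read_annotations(path: str, fmt: str | None = None) -> AnnotationTable:
    """(gene, term) TSV or GMT gene-set file (term, description, genes...)."""
    if fmt is None:
        fmt = "gmt" if path.lower().endswith(".gmt") else "tsv"
    pairs: list[tuple[str, str]] = []
    lines = _data_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty annotation file")
    for lineno, line in lines:
        fields = line.split("\t")
        if fmt == "gmt":
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT rows need term, description, genes")
            term = fields[0]
            pairs.extend((g, term) for g in fields[2:] if g)
        else:
            if fields[0] == "gene":
                continue
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected (gene, term)")
            pairs.append((fields[0], fields[1]))
    return AnnotationTable.from_pairs(pairs)


def write_annotations(table: AnnotationTable, path: str,
                      meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("gene\tterm\n")
        for gene in sorted(table.gene_terms):
            for term in sorted(table.gene_terms[gene]):
                fh.write(f"{gene}\t{term}\n")


# -- directed regulatory networks ------------------------------------------

def read_regnet(path: str) -> DirectedRegNet:
    """Two/three-column TSV (regulator, target[, sign])."""
    lines = _data_lines(path)
    edges = []
    for lineno, line in lines:
        fields = line.split("\t")
        if fields[0] in ("regulator", "tf"):
            continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected (regulator, target)")
        if fields[0] == fields[1]:
            raise ParseError(f"{path}:{lineno}: self-edge on {fields[0]!r}")
        edges.append((fields[0], fields[1]))
    if not edges:
        raise ParseError(f"{path}: no regulatory edges")
    return DirectedRegNet(edges=edges)


def write_regnet(regnet: DirectedRegNet, path: str,
                 meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("regulator\ttarget\n")
        for reg, tgt in regnet.edges:
            fh.write(f"{reg}\t{tgt}\n")


# -- enrichment tables ------------------------------------------------------

def write_enrichment(results: Iterable[EnrichmentResult], path: str,
                     meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("module\tterm\tk\tn\tK\tN\tp\tq\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.module}\t{r.term}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.p:.6g}\t{r.q:.6g}\t{int(r.significant)}\n"
            )


def write_truth(truth, outdir: str, meta: Mapping[str, object] | None = None) -> None:
    """Sidecar TSVs for the planted ground truth of a simulation."""
    with open(os.path.join(outdir, "truth_modules.tsv"), "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("gene\tmodule\n")
        for gene in sorted(truth.module_of):
            fh.write(f"{gene}\t{truth.module_of[gene]}\n")
    with open(os.path.join(outdir, "truth_edges.tsv"), "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(truth.true_edges):
            fh.write(f"{a}\t{b}\n")
    with open(os.path.join(outdir, "truth_flags.tsv"), "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("gene\tflag\n")
        for g in truth.noisy_genes:
            fh.write(f"{g}\tnoisy\n")
        for g in truth.low_signal_genes:
            fh.write(f"{g}\tlow_signal\n")
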