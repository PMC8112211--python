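"""Readers and writers for the plain-text formats the pipeline consumes.

Formats:

* expression TSV — genes x samples, first column gene id, header = sample ids;
  companion two-column TSV of sample -> condition (case/control);
* signature TSV — columns gene, direction, magnitude, support;
* perturbation panel TSV — long format with columns compound, cell_line,
  experiment, gene, score; or GCT 1.2/1.3 (one record per data column, column
  ids "compound|cell_line|experiment");
* PPI edge list — two-column TSV or SIF (node1 interaction node2);
* protein sets — two-column TSV (label, protein id);
* node expression — two-column TSV (protein, median TPM);
* dose matrix CSV — first row/column are dose labels, body is viability or
  inhibition (declared by an optional ``# values: viability`` header comment).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .signatures import ExpressionCohort, PerturbationPanel, SignedSignature
from .network import ProteinSet
from .synergy import DoseResponseMatrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_signature_tsv",
    "write_signature_tsv",
    "read_panel_tsv",
    "write_panel_tsv",
    "read_gct",
    "write_gct",
    "read_edge_list",
    "write_edge_list",
    "read_protein_sets",
    "write_protein_sets",
    "read_node_expression",
    "read_dose_matrix_csv",
    "write_dose_matrix_csv",
]


# -- expression cohorts -----------------------------------------------------

def read_expression_tsv(
    expression_path: str | Path, conditions_path: str | Path, units: str = "counts"
) -> ExpressionCohort:
    values = pd.read_csv(expression_path, sep="\t", index_col=0)
    cond = pd.read_csv(conditions_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionCohort(values, cond, units=units)


def write_expression_tsv(
    cohort: ExpressionCohort, expression_path: str | Path, conditions_path: str | Path
) -> None:
    cohort.values.to_csv(expression_path, sep="\t")
    cohort.conditions.rename("condition").to_frame().to_csv(
        conditions_path, sep="\t", index_label="sample"
    )


# -- signatures -------------------------------------------------------------

def read_signature_tsv(path: str | Path, name: str | None = None) -> SignedSignature:
    frame = pd.read_csv(path, sep="\t", index_col="gene")
    return SignedSignature(frame, name=name or Path(path).stem)


def write_signature_tsv(sig: SignedSignature, path: str | Path) -> None:
    sig.frame.to_csv(path, sep="\t", index_label="gene")


# -- perturbation panels ----------------------------------------------------

def read_panel_tsv(path: str | Path) -> PerturbationPanel:
    long = pd.read_csv(path, sep="\t")
    required = {"compound", "cell_line", "experiment", "gene", "score"}
    if not required.issubset(long.columns):
        raise ValueError(f"panel TSV needs columns {sorted(required)}")
    wide = long.pivot_table(
        index=["compound", "cell_line", "experiment"],
        columns="gene",
        values="score",
        sort=True,
    )
    return PerturbationPanel(wide)


def write_panel_tsv(panel: PerturbationPanel, path: str | Path) -> None:
    long = (
        panel.scores.stack()
        .rename("score")
        .reset_index()
        .rename(columns={"level_3": "gene"})
    )
    long.columns = ["compound", "cell_line", "experiment", "gene", "score"]
    long.to_csv(path, sep="\t", index=False)


# -- GCT 1.2 / 1.3 ----------------------------------------------------------

def read_gct(path: str | Path) -> PerturbationPanel:
    """Minimal GCT 1.2/1.3 reader; column ids are "compound|cell_line|experiment"."""
    with open(path) as fh:
        version = fh.readline().strip()
        dims = fh.readline().split("\t")
        if version not in ("#1.2", "#1.3"):
            raise ValueError(f"unsupported GCT version line {version!r}")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        n_rmeta = int(dims[2]) if version == "#1.3" and len(dims) > 2 else 0
        n_cmeta = int(dims[3]) if version == "#1.3" and len(dims) > 3 else 0
        header = fh.readline().rstrip("\n").split("\t")
        col_ids = header[2:] if version == "#1.2" else header[1 + n_rmeta :]
        for _ in range(n_cmeta):
            fh.readline()
        records, genes = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0] == "":
                continue
            genes.append(parts[0])
            offset = 2 if version == "#1.2" else 1 + n_rmeta
            records.append([float(v) for v in parts[offset : offset + n_cols]])
    if len(genes) != n_rows:
        warnings.warn(
            f"GCT declared {n_rows} rows but contains {len(genes)}", stacklevel=2
        )
    mat = np.asarray(records)
    index = pd.MultiIndex.from_tuples(
        [tuple(c.split("|", 2)) for c in col_ids],
        names=["compound", "cell_line", "experiment"],
    )
    wide = pd.DataFrame(mat.T, index=index, columns=pd.Index(genes, name="gene"))
    return PerturbationPanel(wide.sort_index())


def write_gct(panel: PerturbationPanel, path: str | Path) -> None:
    """GCT 1.2 writer, columns "compound|cell_line|experiment"."""
    mat = panel.scores.to_numpy().T
    col_ids = ["|".join(map(str, idx)) for idx in panel.scores.index]
    genes = list(panel.scores.columns)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{len(genes)}\t{len(col_ids)}\n")
        fh.write("NAME\tDescription\t" + "\t".join(col_ids) + "\n")
        for g, row in zip(genes, mat):
            fh.write(g + "\tna\t" + "\t".join(format(v, ".6g") for v in row) + "\n")


# -- graphs and protein sets ------------------------------------------------

def read_edge_list(path: str | Path, dedupe: bool = True) -> nx.Graph:
    """Two-column TSV or SIF (node1 [interaction] node2); returns a simple graph."""
    graph = nx.Graph()
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) == 2:
                u, v = parts
            elif len(parts) >= 3:  # SIF: node1 interaction node2 [node3 ...]
                u, v = parts[0], parts[2]
            else:
                raise ValueError(f"unparseable edge line: {line!r}")
            if parts[0].lower() in ("source", "node1", "protein1") and n_lines == 0:
                continue  # header row
            if u == v:
                continue
            n_lines += 1
            graph.add_edge(u, v)
    if n_lines > graph.number_of_edges() and dedupe:
        warnings.warn(
            f"edge list had {n_lines - graph.number_of_edges()} duplicate edge(s); "
            "deduplicated",
            stacklevel=2,
        )
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted((sorted(map(str, e)) for e in graph.edges())):
            fh.write(f"{u}\t{v}\n")


def read_protein_sets(path: str | Path) -> dict[str, ProteinSet]:
    """Two-column TSV (label, protein); one ProteinSet per label."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["label", "protein"], dtype=str)
    if frame["label"].iloc[0] == "label":
        frame = frame.iloc[1:]
    sets = {}
    for label, grp in frame.groupby("label", sort=True):
        sets[label] = ProteinSet(label, grp["protein"].tolist())
    return sets


def write_protein_sets(sets: Iterable[ProteinSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tprotein\n")
        for s in sets:
            for member in sorted(map(str, s.members)):
                fh.write(f"{s.label}\t{member}\n")


def read_node_expression(path: str | Path) -> dict[str, float]:
    frame = pd.read_csv(path, sep="\t", header=None, names=["protein", "tpm"])
    if str(frame["protein"].iloc[0]).lower() in ("protein", "gene", "node"):
        frame = frame.iloc[1:]
    return dict(zip(frame["protein"].astype(str), frame["tpm"].astype(float)))


# -- dose matrices ----------------------------------------------------------

def read_dose_matrix_csv(
    path: str | Path,
    drug_a: str = "drugA",
    drug_b: str = "drugB",
    values: str | None = None,
) -> DoseResponseMatrix:
    """Checkerboard CSV: first row/column dose labels; body viability or inhibition.

    The scale is taken from a ``# values: viability`` (or ``inhibition``)
    comment on the first line, overridable via ``values``; default inhibition.
    """
    declared = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "viability" in first.lower():
                declared = "viability"
            elif "inhibition" in first.lower():
                declared = "inhibition"
    scale = values or declared or "inhibition"
    frame = pd.read_csv(path, comment="#", index_col=0)
    doses_a = frame.index.to_numpy(dtype=float)
    doses_b = frame.columns.to_numpy(dtype=float)
    body = frame.to_numpy(dtype=float)
    if scale == "viability":
        return DoseResponseMatrix.from_viability(
            drug_a, drug_b, doses_a, doses_b, body
        )
    return DoseResponseMatrix(drug_a, drug_b, doses_a, doses_b, body)


def write_dose_matrix_csv(matrix: DoseResponseMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(
        matrix.response, index=matrix.doses_a, columns=matrix.doses_b
    )
    with open(path, "w") as fh:
        fh.write(f"# values: inhibition; drugs: {matrix.drug_a} x {matrix.drug_b}\n")
        frame.to_csv(fh)
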