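"""Readers and writers for the pipeline's plain-text dialects.

Matrices and networks travel as TSV (expression: gene rows x sample columns
with a two-column sample-metadata sheet; networks: two-column edge lists or
SIF), dose-response tables as CSV with the fixed column set
``drug1_dose, drug2_dose, drug3_dose, effect_type, effect_value,
control_value, batch``.  Loaders validate shapes, ids and numeric types and
report offending rows; identifiers are opaque strings.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ScreenCounts

__all__ = [
    "read_expression", "write_expression",
    "read_network", "write_network",
    "read_counts", "write_counts",
    "read_orthologs",
    "read_doseresponse", "write_doseresponse",
]

logger = logging.getLogger(__name__)

DOSE_COLUMNS = ["drug1_dose", "drug2_dose", "drug3_dose",
                "effect_type", "effect_value", "control_value", "batch"]
EFFECT_TYPES = {"cell_number", "apoptotic_index", "radiance"}


def _require_file(path) -> Path:
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(p)
    if p.stat().st_size == 0:
        raise ValueError(f"{p} is empty")
    return p


def _numeric_or_raise(df: pd.DataFrame, what: str) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.any().any():
        r, c = np.nonzero(bad.to_numpy())
        loc = (df.index[r[0]], df.columns[c[0]])
        raise ValueError(f"non-numeric value in {what} at row {loc[0]!r}, "
                         f"column {loc[1]!r}")
    if out.isna().any().any():
        r, c = np.nonzero(out.isna().to_numpy())
        raise ValueError(f"missing value in {what} at row {df.index[r[0]]!r}, "
                         f"column {df.columns[c[0]]!r}")
    return out


def read_expression(matrix_path, metadata_path) -> ExpressionMatrix:
    """TSV matrix (first column gene id, header sample ids) + sample metadata
    TSV (sample id, condition)."""
    values = pd.read_csv(_require_file(matrix_path), sep="\t", index_col=0)
    values = _numeric_or_raise(values, "expression matrix")
    values.index.name = None
    meta = pd.read_csv(_require_file(metadata_path), sep="\t", index_col=0)
    if "condition" not in meta.columns:
        raise ValueError("sample metadata needs a 'condition' column")
    return ExpressionMatrix(values=values, condition=meta["condition"])


def write_expression(expr: ExpressionMatrix, matrix_path, metadata_path) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    expr.condition.rename("condition").to_csv(metadata_path, sep="\t",
                                              index_label="sample_id")


def read_network(path) -> nx.Graph:
    """Two-column TSV edge list, or SIF (source, relation, target).

    Self-loops are rejected; duplicate edges deduplicated with a warning.
    """
    p = _require_file(path)
    rows = []
    with open(p) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if not any(parts):
                continue
            if len(parts) == 2:
                a, b = parts
            elif len(parts) == 3:  # SIF: node relation node
                a, _, b = parts
            else:
                raise ValueError(f"{p}:{ln}: expected 2 (TSV) or 3 (SIF) columns, "
                                 f"got {len(parts)}")
            if a == b:
                raise ValueError(f"{p}:{ln}: self-loop on {a!r}")
            rows.append((a, b))
    if rows and rows[0] in (("source", "target"), ("gene_a", "gene_b")):
        rows = rows[1:]
    net = nx.Graph()
    net.add_edges_from(rows)
    if net.number_of_edges() < len(rows):
        logger.warning("%s: %d duplicate edges collapsed", p,
                       len(rows) - net.number_of_edges())
    return net


def write_network(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")


def read_counts(counts_path, metadata_path) -> ScreenCounts:
    """Counts TSV (shrna_id, gene, one column per sample) + sample metadata
    TSV (sample_id, cell_line, timepoint, replicate)."""
    raw = pd.read_csv(_require_file(counts_path), sep="\t", index_col=0)
    if "gene" not in raw.columns:
        raise ValueError("counts table needs a 'gene' column after shrna_id")
    gene_of = raw["gene"]
    counts = _numeric_or_raise(raw.drop(columns="gene"), "count table")
    counts.index.name = None
    gene_of.index.name = None
    neg = counts < 0
    if neg.any().any():
        r, c = np.nonzero(neg.to_numpy())
        raise ValueError(f"negative count at row {counts.index[r[0]]!r}, "
                         f"column {counts.columns[c[0]]!r}")
    meta = pd.read_csv(_require_file(metadata_path), sep="\t", index_col=0)
    need = {"cell_line", "timepoint", "replicate"}
    if not need <= set(meta.columns):
        raise ValueError(f"sample metadata needs columns {sorted(need)}")
    return ScreenCounts(counts=counts, gene_of=gene_of, samples=meta)


def write_counts(sc: ScreenCounts, counts_path, metadata_path) -> None:
    out = sc.counts.copy()
    out.insert(0, "gene", sc.gene_of)
    out.to_csv(counts_path, sep="\t", index_label="shrna_id")
    sc.samples.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_orthologs(path) -> dict[str, str]:
    """Two-column TSV (species-A id, species-B id), filtered to one-to-one.

    Ids appearing in more than one pair on either side are dropped entirely
    (logged), leaving a bijective map.
    """
    pairs = pd.read_csv(_require_file(path), sep="\t", header=None,
                        names=["a", "b"], dtype=str, comment="#")
    if {"a", "b"} <= set(pairs.iloc[0].values) or tuple(pairs.iloc[0]) in (
            ("species_a", "species_b"),):
        pairs = pairs.iloc[1:]
    dup_a = pairs["a"].duplicated(keep=False)
    dup_b = pairs["b"].duplicated(keep=False)
    dropped = int((dup_a | dup_b).sum())
    if dropped:
        logger.info("dropped %d many-to-many ortholog pairs", dropped)
    kept = pairs[~(dup_a | dup_b)]
    return dict(zip(kept["a"], kept["b"]))


def read_doseresponse(path) -> pd.DataFrame:
    """Dose-response/combination CSV in the standard dialect."""
    table = pd.read_csv(_require_file(path))
    missing = [c for c in DOSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"dose-response table missing columns: {missing}")
    num = ["drug1_dose", "drug2_dose", "drug3_dose", "effect_value",
           "control_value"]
    table[num] = _numeric_or_raise(table[num], "dose-response table")
    if (table[["drug1_dose", "drug2_dose", "drug3_dose"]] < 0).any().any():
        raise ValueError("doses must be non-negative")
    bad = set(table["effect_type"]) - EFFECT_TYPES
    if bad:
        raise ValueError(f"unknown effect_type values: {sorted(bad)}")
    return table


def write_doseresponse(table: pd.DataFrame, path) -> None:
    table[DOSE_COLUMNS].to_csv(path, index=False)
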