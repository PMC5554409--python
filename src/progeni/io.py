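"""Readers/writers for the tabular formats and dataset-bundle loading.

Formats:

- network: whitespace/tab-separated edge list ``gene_a gene_b weight``,
  ``#`` comments and an optional header line;
- expression: TSV, first column sample IDs, header row gene IDs;
- response: long-format TSV with columns ``sample``, ``treatment``,
  ``value``;
- rankings: TSV ``rank gene_id score abs_pcc is_rcg off_network``.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .network import GeneNetwork
from .prioritize import RANKING_COLUMNS, ResponseVector
from .simulate import SimulationTruth

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_network(path, weight_threshold: float | None = None) -> GeneNetwork:
    """Parse an edge-list file into a :class:`GeneNetwork`.

    Malformed lines are reported with their line numbers.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            if not _is_number(parts[2]):
                if not edges and lineno <= 2:  # header line
                    continue
                raise ValueError(f"{path}:{lineno}: weight {parts[2]!r} is not numeric")
            edges.append((parts[0], parts[1], float(parts[2])))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    return GeneNetwork.from_edges(edges, weight_threshold=weight_threshold)


def write_network(network: GeneNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        n = network.n_nodes
        A = network.adjacency
        for i in range(n):
            for j in range(i + 1, n):
                if A[i, j] > 0:
                    fh.write(
                        f"{network.node_ids[i]}\t{network.node_ids[j]}\t"
                        f"{_FLOAT_FMT % A[i, j]}\n"
                    )


def read_expression(path, transpose: bool = False) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(data=df, stage="raw")


def write_expression(X: ExpressionMatrix, path) -> None:
    X.data.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="sample")


RESPONSE_COLUMNS = ["sample", "treatment", "value"]


def read_response(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "treatment": str})
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: response table lacks column(s) {missing}")
    return df[RESPONSE_COLUMNS]


def write_response(table: pd.DataFrame, path) -> None:
    table[RESPONSE_COLUMNS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def select_treatment(table: pd.DataFrame, treatment: str) -> ResponseVector:
    sub = table.loc[table["treatment"] == treatment]
    if sub.empty:
        known = sorted(table["treatment"].unique())
        raise ValueError(f"treatment {treatment!r} not found; available: {known}")
    values = pd.Series(
        sub["value"].to_numpy(dtype=float), index=sub["sample"].to_numpy()
    )
    return ResponseVector(values, treatment_id=treatment)


def load_bundle(
    network_path,
    expression_path,
    response_path,
    treatment: str,
    weight_threshold: float | None = None,
    transpose: bool = False,
) -> tuple[GeneNetwork, ExpressionMatrix, ResponseVector, dict]:
    """Load and align the three inputs; returns objects plus a load report."""
    network = read_network(network_path, weight_threshold=weight_threshold)
    X = read_expression(expression_path, transpose=transpose)
    table = read_response(response_path)
    d = select_treatment(table, treatment)

    known = set(X.sample_ids)
    unmatched = [s for s in d.sample_ids if s not in known]
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} response record(s) reference unknown samples; dropped"
        )
        d = ResponseVector(
            d.values.drop(index=unmatched), treatment_id=d.treatment_id
        )
    shared_genes = set(X.gene_ids) & set(network.node_ids)
    if not shared_genes:
        raise ValueError("no overlap between expression and network")
    shared_samples = [s for s in X.sample_ids if s in set(d.sample_ids)]
    if not shared_samples:
        raise ValueError("no overlap between expression and response samples")
    report = {
        "n_network_genes": network.n_nodes,
        "n_expressed_genes": len(X.gene_ids),
        "n_shared_genes": len(shared_genes),
        "n_off_network_genes": len(X.gene_ids) - len(shared_genes),
        "n_response_samples": len(d.sample_ids),
        "n_unmatched_response_samples": len(unmatched),
        "n_shared_samples": len(shared_samples),
    }
    logger.info("load report: %s", report)
    return network, X, d, report


def write_ranking(ranked: pd.DataFrame, path) -> None:
    """Ranked-list TSV; content is byte-identical across reruns."""
    ranked[RANKING_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_ranking(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def load_config(path) -> dict:
    """Load a YAML run configuration (flat mapping of option defaults)."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(config).__name__}")
    return config


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def write_dataset(
    out_dir,
    network: GeneNetwork,
    X: ExpressionMatrix,
    d: ResponseVector,
    truth: SimulationTruth | None = None,
) -> dict:
    """Write a simulated bundle (network, expression, response, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "network.tsv",
        "expression": out / "expression.tsv",
        "response": out / "response.tsv",
    }
    write_network(network, paths["network"])
    write_expression(X, paths["expression"])
    table = pd.DataFrame(
        {
            "sample": d.sample_ids,
            "treatment": d.treatment_id or "treatment",
            "value": d.values.to_numpy(),
        }
    )
    write_response(table, paths["response"])
    if truth is not None:
        paths["truth"] = out / "truth.json"
        write_json(truth.to_dict(), paths["truth"])
    return {k: str(v) for k, v in paths.items()}
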