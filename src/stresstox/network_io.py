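"""Regulator-network export in SIF, GraphML and TSV."""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = ["export_network", "read_network_tsv"]

_FORMATS = ("sif", "graphml", "tsv")

_COLUMNS = ["regulator", "protein", "protein_direction", "regulator_direction"]


def export_network(edges: pd.DataFrame, path, fmt: str = "tsv") -> None:
    """Write a (regulator, protein, directions) edge table.

    SIF uses ``activates`` when the protein moves with the regulator and
    ``affects`` otherwise; GraphML carries both direction attributes;
    TSV round-trips losslessly.
    """
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}")
    missing = [c for c in _COLUMNS if c not in edges.columns]
    if missing:
        raise ValueError(f"edge table missing columns: {missing}")
    if fmt == "tsv":
        edges[_COLUMNS].to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for _, row in edges.iterrows():
                rel = (
                    "activates"
                    if row["protein_direction"] == row["regulator_direction"]
                    else "affects"
                )
                fh.write(f"{row['regulator']}\t{rel}\t{row['protein']}\n")
    else:
        g = nx.DiGraph()
        for _, row in edges.iterrows():
            g.add_node(row["regulator"], kind="regulator",
                       direction=row["regulator_direction"])
            if row["protein"] not in g or g.nodes[row["protein"]].get("kind") != "regulator":
                g.add_node(row["protein"], kind="protein",
                           direction=row["protein_direction"])
            g.add_edge(row["regulator"], row["protein"],
                       protein_direction=row["protein_direction"],
                       regulator_direction=row["regulator_direction"])
        nx.write_graphml(g, path)


def read_network_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and list(df.columns) != _COLUMNS:
        df = pd.DataFrame(columns=_COLUMNS)
    return df
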