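"""Readers and writers for the package's line-oriented file formats.

GMT for gene sets, TSV for expression matrices and covariance matrices,
two-column edge lists (or GraphML) for networks, JSON sidecars for ground
truth.  Readers reject malformed input rather than coercing it; every writer
produces files its reader round-trips.
"""

from __future__ import annotations

import configparser
import json
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import GroupedExpression, Pathway, PathwayCollection
from .network import GeneNetwork
from .simulators import SimulationDesign

__all__ = [
    "read_gmt", "write_gmt",
    "read_expression_tsv", "write_expression_tsv",
    "read_edge_list", "write_edge_list", "read_graphml", "read_network",
    "write_covariance_tsv",
    "write_truth_json", "read_truth_json",
    "read_grid_config",
]


# ---------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> PathwayCollection:
    """GMT dialect: name TAB description TAB gene TAB gene ..."""
    pathways = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
            )
        name, _desc, *genes = fields
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            warnings.warn(
                f"{path}:{lineno}: duplicate genes in set {name!r} collapsed",
                RuntimeWarning,
                stacklevel=2,
            )
        pathways.append(Pathway(name, deduped))
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for pw in collection:
            fh.write("\t".join([pw.name, description, *pw.genes]) + "\n")


# ---------------------------------------------------------------- expression TSV

def read_expression_tsv(path: str | Path) -> GroupedExpression:
    """First header field is a caption; remaining header fields are the two
    group labels, one per sample column; first column holds gene ids."""
    frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    labels = np.asarray(frame.columns.str.replace(r"\.\d+$", "", regex=True))
    distinct = list(dict.fromkeys(labels.tolist()))
    if len(distinct) != 2:
        raise ValueError(
            f"{path}: expected exactly 2 distinct sample labels, got {distinct!r}"
        )
    try:
        values = frame.to_numpy(dtype=float)
        if not np.isnan(values).any():
            return GroupedExpression(values, list(frame.index), labels)
    except (TypeError, ValueError):
        pass
    # slow path only to name the offending cell
    values = np.empty(frame.shape, dtype=float)
    for i, (gene, row) in enumerate(frame.iterrows()):
        for j, cell in enumerate(row):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ValueError(f"{path}: missing cell at gene {gene!r}, column {j + 1}")
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at gene {gene!r}, "
                    f"column {j + 1}"
                ) from None
    return GroupedExpression(values, list(frame.index), labels)


def write_expression_tsv(data: GroupedExpression, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(map(str, data.group_labels)) + "\n")
        for gene, row in zip(data.gene_ids, data.values):
            fh.write(gene + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------- networks

def read_edge_list(path: str | Path) -> GeneNetwork:
    """Whitespace-separated two-column edge list; '#' starts a comment."""
    edges: list[tuple[str, str]] = []
    nodes: dict[str, None] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {parts!r}")
        a, b = parts
        nodes.setdefault(a)
        nodes.setdefault(b)
        edges.append((a, b))
    return GeneNetwork(list(nodes), edges)


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\n")
        for a, b in network.edges():
            fh.write(f"{a}\t{b}\n")


def read_graphml(path: str | Path) -> GeneNetwork:
    g = nx.read_graphml(path)
    return GeneNetwork.from_networkx(nx.Graph(g))


def read_network(path: str | Path) -> GeneNetwork:
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        return read_graphml(path)
    return read_edge_list(path)


def write_covariance_tsv(sigma: np.ndarray, gene_ids: list[str],
                         path: str | Path) -> None:
    frame = pd.DataFrame(sigma, index=gene_ids, columns=gene_ids)
    frame.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------- truth sidecar

def write_truth_json(pathways: PathwayCollection, path: str | Path) -> None:
    payload = {
        pw.name: {
            "truly_de": bool(pw.truly_de),
            "realized_detection_call": pw.realized_detection_call,
            "size": pw.size,
        }
        for pw in pathways
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth_json(path: str | Path) -> dict[str, dict]:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------- grid config

def _parse_list(text: str, cast) -> list:
    return [cast(tok) for tok in text.replace(",", " ").split()]


def read_grid_config(path: str | Path) -> dict:
    """Flat INI config describing a simulation grid.

    Section ``[grid]`` mirrors SimulationDesign fields (list-valued where a
    grid is wanted): ``sim_type``, ``n_per_group``, ``detection_call``,
    ``rho``, ``pathway_sizes``, ``pathways_per_size``, ``n_background``,
    ``effect_size``, ``alpha``; section ``[run]`` holds ``methods``,
    ``n_runs`` and ``permutations``.
    """
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(path)
    grid = parser["grid"] if parser.has_section("grid") else parser["DEFAULT"]
    run = parser["run"] if parser.has_section("run") else parser["DEFAULT"]
    sim_type = grid.get("sim_type", "II").strip()
    n_values = _parse_list(grid.get("n_per_group", "20"), int)
    dc_values = _parse_list(grid.get("detection_call", "0"), float)
    rho_values = _parse_list(grid.get("rho", "0"), float)
    sizes = tuple(_parse_list(grid.get("pathway_sizes", "20 40 60 80 100"), int))
    designs = [
        SimulationDesign(
            sim_type=sim_type,
            n_per_group=n,
            rho=rho,
            detection_call=dc,
            effect_size=float(grid.get("effect_size", "1.0")),
            pathway_sizes=sizes,
            pathways_per_size=int(grid.get("pathways_per_size", "10")),
            n_background=int(grid.get("n_background", "7000")),
            alpha=float(grid.get("alpha", "0.05")),
        )
        for n in n_values
        for dc in dc_values
        for rho in rho_values
    ]
    return {
        "designs": designs,
        "methods": _parse_list(run.get("methods", "sum_t_square"), str),
        "n_runs": int(run.get("n_runs", "5")),
        "permutations": int(run.get("permutations", "1000")),
    }
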