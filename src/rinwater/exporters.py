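"""Serialization of RINs, centrality results and differential reports.

Formats: SIF edge lists and TSV node-attribute tables (loadable by standard
graph visualization tools), per-analysis centrality TSVs, JSON differential
reports, and the four-column wet/dry × RCA/BCA Z-score table layout used for
per-residue comparisons.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .centrality import CENTRAL_Z_THRESHOLD, CentralityResult
from .differential import DifferentialReport
from .rin import RIN

__all__ = [
    "write_sif",
    "read_sif",
    "write_node_table",
    "write_centrality_tsv",
    "write_differential_json",
    "write_added_table_tsv",
    "export_z_table",
    "write_run_metadata",
]


def write_sif(rin: RIN, path: str | Path) -> None:
    """SIF edge list: ``label <tab> contact <tab> label`` (canonical order);
    isolated nodes emitted as bare-label lines."""
    lines = []
    for u, v in sorted(tuple(sorted(e)) for e in rin.graph.edges):
        lines.append(f"{u}\tcontact\t{v}\n")
    for n in sorted(nx.isolates(rin.graph)):
        lines.append(f"{n}\n")
    Path(path).write_text("".join(lines))


def read_sif(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    for line in Path(path).read_text().splitlines():
        parts = line.split("\t")
        if len(parts) >= 3:
            g.add_edge(parts[0], parts[2])
        elif parts and parts[0]:
            g.add_node(parts[0])
    return g


def write_node_table(rin: RIN, path: str | Path) -> None:
    """TSV node attributes: label, kind, chain, interface, degree."""
    rows = [
        {
            "label": n,
            "kind": d.get("kind", ""),
            "chain": d.get("chain", ""),
            "interface": bool(d.get("interface", False)),
            "degree": rin.graph.degree[n],
        }
        for n, d in sorted(rin.graph.nodes(data=True))
    ]
    pd.DataFrame(rows, columns=["label", "kind", "chain", "interface", "degree"]).to_csv(
        path, sep="\t", index=False
    )


def write_centrality_tsv(
    result: CentralityResult, path: str | Path, threshold: float = CENTRAL_Z_THRESHOLD
) -> None:
    """TSV: label, kind, chain, raw, z, central."""
    df = result.to_frame()
    df["central"] = df["z"] >= threshold
    df = df.sort_values("z", ascending=False, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_differential_json(report: DifferentialReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")


def write_added_table_tsv(report: DifferentialReport, path: str | Path) -> None:
    """Added-central-node table: one column per method plus Union and
    Intersection, columns padded to equal length."""
    cols = report.table_added()
    width = max((len(v) for v in cols.values()), default=0)
    padded = {k: v + [""] * (width - len(v)) for k, v in cols.items()}
    pd.DataFrame(padded).to_csv(path, sep="\t", index=False)


def export_z_table(
    results: dict[tuple[str, str], CentralityResult],
    labels: list[str],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-residue Z table with columns BCA/RCA × dry/wet.

    ``results`` maps (condition, method) — e.g. ("dry", "BCA") — to a
    centrality result. Unknown labels raise KeyError.
    """
    order = [("dry", "BCA"), ("dry", "RCA"), ("wet", "BCA"), ("wet", "RCA")]
    rows = []
    for label in labels:
        row: dict[str, object] = {"label": label}
        for cond, method in order:
            res = results.get((cond, method))
            if res is None:
                continue
            if label not in res.z:
                raise KeyError(f"label {label!r} absent from {cond} {method} analysis")
            row[f"z_{method.lower()}_{cond}"] = res.z[label]
        rows.append(row)
    cols = ["label"] + [
        f"z_{m.lower()}_{c}" for c, m in order if (c, m) in results
    ]
    df = pd.DataFrame(rows, columns=cols)
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.3f")
    return df


def write_run_metadata(path: str | Path, **fields) -> None:
    """Reproducibility record: thresholds, policies, versions, node/edge
    counts. Timestamps are deliberately excluded so reruns are byte-stable."""
    from . import __version__

    payload = {"rinwater_version": __version__, **fields}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
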