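"""Wet-vs-dry comparison of centrality results.

Quantifies how including water nodes changes the central-residue set of a
protein complex: added/lost central nodes per method, union/intersection
across methods, the per-residue Z-score shift ΔZ = Z_wet − Z_dry with its
summary statistics, the Z statistics of the water nodes themselves, the
interface-restricted view, and water-removal robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .centrality import CENTRAL_Z_THRESHOLD, CentralityResult, bca, central_nodes, rca
from .rin import RIN, remove_water_nodes

__all__ = [
    "DifferentialReport",
    "ExclusionPolicy",
    "diff_central",
    "combine_methods",
    "delta_z_stats",
    "added_residue_shift",
    "interface_report",
    "water_removal_experiment",
    "compare",
]


@dataclass(frozen=True)
class ExclusionPolicy:
    """Labels to drop from report *tables* (never from computations).

    Typical use: affinity-tag residues whose centrality is a construct
    artifact rather than biology.
    """

    excluded: dict[str, str] = field(default_factory=dict)  # label -> reason

    def apply(self, labels: Iterable[str]) -> set[str]:
        return {l for l in labels if l not in self.excluded}


@dataclass
class MethodDiff:
    method: str
    added: set[str]
    lost: set[str]


@dataclass
class DeltaZStats:
    """Summary of the residue Z shift and the water Z distribution."""

    mean_delta_z: float
    sigma_delta_z: float
    mean_water_z: float | None
    sigma_water_z: float | None
    delta_z: dict[str, float]
    n_residues: int
    n_waters: int


@dataclass
class DifferentialReport:
    structure_id: str
    threshold: float
    per_method: dict[str, MethodDiff]
    union_added: set[str]
    intersection_added: set[str]
    stats: dict[str, DeltaZStats]
    added_shift: dict[str, float | None]
    interface: dict | None = None
    exclusions: ExclusionPolicy | None = None

    def table_added(self) -> dict[str, list[str]]:
        """Table-style view of added central nodes (exclusions applied)."""
        pol = self.exclusions or ExclusionPolicy()
        cols = {m: sorted(pol.apply(d.added)) for m, d in self.per_method.items()}
        cols["Union"] = sorted(pol.apply(self.union_added))
        cols["Intersection"] = sorted(pol.apply(self.intersection_added))
        return cols

    def to_dict(self) -> dict:
        out = {
            "structure_id": self.structure_id,
            "z_threshold": self.threshold,
            "per_method": {
                m: {"added": sorted(d.added), "lost": sorted(d.lost)}
                for m, d in self.per_method.items()
            },
            "union_added": sorted(self.union_added),
            "intersection_added": sorted(self.intersection_added),
            "stats": {
                m: {
                    "mean_delta_z": s.mean_delta_z,
                    "sigma_delta_z": s.sigma_delta_z,
                    "mean_water_z": s.mean_water_z,
                    "sigma_water_z": s.sigma_water_z,
                    "n_residues": s.n_residues,
                    "n_waters": s.n_waters,
                }
                for m, s in self.stats.items()
            },
            "added_residue_shift": self.added_shift,
        }
        if self.interface is not None:
            out["interface"] = self.interface
        if self.exclusions:
            out["excluded_labels"] = dict(self.exclusions.excluded)
        return out


def diff_central(
    wet: CentralityResult,
    dry: CentralityResult,
    threshold: float = CENTRAL_Z_THRESHOLD,
) -> MethodDiff:
    """Added = central in wet but not dry (waters can only appear here);
    lost = central in dry but not wet."""
    if wet.method != dry.method:
        raise ValueError(f"method mismatch: {wet.method} vs {dry.method}")
    cw = set(central_nodes(wet, threshold).labels)
    cd = set(central_nodes(dry, threshold).labels)
    return MethodDiff(method=wet.method, added=cw - cd, lost=cd - cw)


def combine_methods(rca_added: set[str], bca_added: set[str]) -> tuple[set[str], set[str]]:
    """(union, intersection) of the two methods' added sets."""
    return rca_added | bca_added, rca_added & bca_added


def delta_z_stats(wet: CentralityResult, dry: CentralityResult) -> DeltaZStats:
    """ΔZ = Z_wet − Z_dry over residue nodes (waters lack dry values), plus
    the mean/SD of Z_wet over the water nodes. SDs are population SDs."""
    if wet.method != dry.method:
        raise ValueError(f"method mismatch: {wet.method} vs {dry.method}")
    common = [
        l
        for l in wet.labels
        if l in dry.z and wet.node_kind.get(l, "residue") == "residue"
    ]
    if not common:
        raise ValueError("no residue nodes shared between wet and dry results")
    dz = {l: wet.z[l] - dry.z[l] for l in common}
    arr = np.array(list(dz.values()))
    waters = [l for l in wet.labels if wet.node_kind.get(l) == "water"]
    wz = np.array([wet.z[l] for l in waters]) if waters else None
    return DeltaZStats(
        mean_delta_z=float(arr.mean()),
        sigma_delta_z=float(arr.std(ddof=0)),
        mean_water_z=float(wz.mean()) if wz is not None else None,
        sigma_water_z=float(wz.std(ddof=0)) if wz is not None else None,
        delta_z=dz,
        n_residues=len(common),
        n_waters=len(waters),
    )


def added_residue_shift(added: Iterable[str], stats: DeltaZStats) -> float | None:
    """How far (in SDs of the global ΔZ) the added central residues' mean ΔZ
    sits above the global mean ΔZ. Water nodes are ignored; ``None`` when the
    global spread is zero or no added residue has a ΔZ."""
    vals = [stats.delta_z[l] for l in added if l in stats.delta_z]
    if not vals:
        return None
    if stats.sigma_delta_z == 0.0:
        return None
    return float((np.mean(vals) - stats.mean_delta_z) / stats.sigma_delta_z)


def interface_report(report: DifferentialReport, interface: set[str]) -> DifferentialReport:
    """Annotate added/lost labels with interface membership and count the
    interface residues in the union of added sets (waters excluded)."""
    pol = report.exclusions or ExclusionPolicy()
    union_res = {
        l
        for l in pol.apply(report.union_added)
        if not l.startswith("Hoh")
    }
    report.interface = {
        "interface_residues": sorted(interface),
        "union_interface_residues": sorted(union_res & interface),
        "union_interface_count": len(union_res & interface),
        "per_method_interface": {
            m: sorted(pol.apply(d.added) & interface) for m, d in report.per_method.items()
        },
    }
    return report


def compare(
    wet_results: dict[str, CentralityResult],
    dry_results: dict[str, CentralityResult],
    threshold: float = CENTRAL_Z_THRESHOLD,
    exclusions: ExclusionPolicy | None = None,
    structure_id: str = "",
) -> DifferentialReport:
    """Full wet-vs-dry differential report over one or more methods.

    ``wet_results``/``dry_results`` map method name ("RCA"/"BCA") to the
    corresponding :class:`CentralityResult`.
    """
    methods = sorted(wet_results)
    if sorted(dry_results) != methods:
        raise ValueError("wet and dry results must cover the same methods")
    per_method: dict[str, MethodDiff] = {}
    stats: dict[str, DeltaZStats] = {}
    shift: dict[str, float | None] = {}
    for m in methods:
        d = diff_central(wet_results[m], dry_results[m], threshold)
        per_method[m] = d
        st = delta_z_stats(wet_results[m], dry_results[m])
        stats[m] = st
        shift[m] = added_residue_shift(d.added, st)
    if len(methods) >= 2:
        union, inter = combine_methods(per_method[methods[0]].added, per_method[methods[1]].added)
        for m in methods[2:]:
            union |= per_method[m].added
            inter &= per_method[m].added
    else:
        union = set(per_method[methods[0]].added)
        inter = set(per_method[methods[0]].added)
    return DifferentialReport(
        structure_id=structure_id or wet_results[methods[0]].rin_metadata.get("structure_id", ""),
        threshold=threshold,
        per_method=per_method,
        union_added=union,
        intersection_added=inter,
        stats=stats,
        added_shift=shift,
        exclusions=exclusions,
    )


def water_removal_experiment(
    rin_wet: RIN,
    selector: str | Sequence[str] = "max_degree",
    k: int | None = None,
    methods: Sequence[str] = ("RCA", "BCA"),
    threshold: float = CENTRAL_Z_THRESHOLD,
    restrict_to: Iterable[str] | None = None,
) -> dict:
    """Remove selected waters, recompute centralities, and compare the
    central *residue* sets before and after (water nodes excluded from the
    comparison). Returns per-method before/after sets and their symmetric
    difference."""
    fns = {"RCA": rca, "BCA": bca}
    reduced = remove_water_nodes(rin_wet, selector=selector, k=k, restrict_to=restrict_to)
    out: dict = {"removed": reduced.metadata["water_removal"]["removed"], "per_method": {}}
    for m in methods:
        before = fns[m](rin_wet)
        after = fns[m](reduced)
        cb = {
            l
            for l in central_nodes(before, threshold).labels
            if before.node_kind.get(l) == "residue"
        }
        ca = {
            l
            for l in central_nodes(after, threshold).labels
            if after.node_kind.get(l) == "residue"
        }
        out["per_method"][m] = {
            "before": sorted(cb),
            "after": sorted(ca),
            "symmetric_difference": sorted(cb ^ ca),
            "unchanged": cb == ca,
        }
    return out
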