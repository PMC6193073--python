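"""Residue interaction network (RIN) construction and interface annotation.

A RIN is an undirected contact graph over residues and, optionally,
crystallographic waters. Residue–residue edges use a 5 Å any-heavy-atom-pair
cutoff, water–water and water–residue edges a 3.5 Å cutoff; contact thresholds
are strict (<) while the 7 Å protein–protein interface definition is inclusive
(≤, "within"). Four variants are supported:

``dry``
    residues only (waters dropped before edge detection);
``wet``
    residues and all waters;
``wet_uniform``
    as wet, but a single 3.5 Å cutoff for every contact (control for the
    asymmetric thresholds);
``interface_waters``
    as wet, keeping only the waters adjacent to at least one interface
    residue, with edges recomputed among the survivors.

Neighbor search is KD-tree based; a brute-force all-pairs check on small
structures is the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Residue, ResidueKind, Structure, StructureError

__all__ = [
    "ContactThresholds",
    "RIN",
    "VARIANTS",
    "min_atom_distance",
    "build_rin",
    "annotate_interface",
    "interface_waters",
    "remove_water_nodes",
]

VARIANTS = ("dry", "wet", "wet_uniform", "interface_waters")


@dataclass(frozen=True)
class ContactThresholds:
    """Distance cutoffs in Å.

    d_rr : residue–residue contact (strict <), default 5.0.
    d_w : water–water and water–residue contact (strict <), default 3.5.
    d_int : interface membership (inclusive ≤), default 7.0.
    """

    d_rr: float = 5.0
    d_w: float = 3.5
    d_int: float = 7.0

    def __post_init__(self) -> None:
        if min(self.d_rr, self.d_w, self.d_int) <= 0:
            raise ValueError("thresholds must be strictly positive")


@dataclass
class RIN:
    """An undirected contact graph with node attributes and build metadata.

    ``graph`` node attributes: ``kind`` ("residue"|"water"), ``chain``,
    ``interface`` (bool). ``metadata`` records thresholds, variant tag and
    source structure id.
    """

    graph: nx.Graph
    metadata: dict = field(default_factory=dict)

    @property
    def variant(self) -> str:
        return self.metadata.get("variant", "")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def water_nodes(self) -> list[str]:
        return [n for n, k in self.graph.nodes(data="kind") if k == "water"]

    @property
    def residue_nodes(self) -> list[str]:
        return [n for n, k in self.graph.nodes(data="kind") if k == "residue"]

    @property
    def interface_residues(self) -> set[str]:
        return {
            n
            for n, d in self.graph.nodes(data=True)
            if d.get("interface") and d.get("kind") == "residue"
        }

    def degree(self, label: str) -> int:
        return self.graph.degree[label]

    def copy(self) -> "RIN":
        return RIN(graph=self.graph.copy(), metadata=dict(self.metadata))


def min_atom_distance(a: Residue, b: Residue) -> float:
    """Minimum Euclidean distance over all heavy-atom pairs of two residues."""
    ca, cb = a.coords, b.coords
    if ca.size == 0 or cb.size == 0:
        raise StructureError("residue without atoms")
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    return float(d.min())


def _atom_table(residues: Sequence[Residue]) -> tuple[np.ndarray, np.ndarray]:
    """Stack all atom coordinates; return (coords, residue-index per atom)."""
    coords = np.concatenate([r.coords for r in residues])
    idx = np.concatenate(
        [np.full(len(r.atoms), i, dtype=np.intp) for i, r in enumerate(residues)]
    )
    return coords, idx


def _contact_pairs(
    residues: Sequence[Residue], cutoff: float, strict: bool = True
) -> set[tuple[int, int]]:
    """Residue-index pairs whose minimum atom distance is below ``cutoff``.

    KD-tree candidate generation at the cutoff radius, then an exact distance
    check so the strict/inclusive boundary convention is honored regardless of
    the tree's own convention.
    """
    if len(residues) < 2:
        return set()
    coords, idx = _atom_table(residues)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    out: set[tuple[int, int]] = set()
    if len(pairs) == 0:
        return out
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    keep = d < cutoff if strict else d <= cutoff
    for (i, j) in pairs[keep]:
        ri, rj = int(idx[i]), int(idx[j])
        if ri != rj:
            out.add((min(ri, rj), max(ri, rj)))
    return out


def _mixed_contact_pairs(
    residues: Sequence[Residue], t: ContactThresholds, uniform: bool
) -> set[tuple[int, int]]:
    """All contact pairs under kind-dependent cutoffs (or a uniform d_w)."""
    d_rr = t.d_w if uniform else t.d_rr
    d_w = t.d_w
    wide = max(d_rr, d_w)
    coords, idx = _atom_table(residues)
    is_water = np.array([r.kind is ResidueKind.WATER for r in residues])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=wide, output_type="ndarray")
    out: set[tuple[int, int]] = set()
    if len(pairs) == 0:
        return out
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    ri = idx[pairs[:, 0]]
    rj = idx[pairs[:, 1]]
    involves_water = is_water[ri] | is_water[rj]
    cut = np.where(involves_water, d_w, d_rr)
    keep = (d < cut) & (ri != rj)
    for a, b in zip(ri[keep], rj[keep]):
        out.add((min(int(a), int(b)), max(int(a), int(b))))
    return out


def build_rin(
    s: Structure,
    variant: str = "wet",
    thresholds: ContactThresholds | None = None,
    chain_groups: tuple[Iterable[str], Iterable[str]] | None = None,
) -> RIN:
    """Build a RIN of the requested variant from a structure.

    ``chain_groups`` (two disjoint chain-id groups) is required for the
    ``interface_waters`` variant and optional otherwise; when given, interface
    flags are set on the nodes. If omitted for a two-chain structure needing
    annotation, the structure's two chains are used.
    """
    t = thresholds or ContactThresholds()
    if variant not in VARIANTS:
        raise ValueError(f"unknown RIN variant {variant!r}; expected one of {VARIANTS}")
    if len(s.residues) < 2:
        raise StructureError("need at least 2 residues to build a RIN")

    if variant == "dry":
        residues = list(s.protein_residues)
    else:
        residues = list(s.residues)

    interface: set[str] = set()
    if chain_groups is not None:
        interface = annotate_interface(s, chain_groups, t.d_int)
    elif variant == "interface_waters":
        chains = s.chains
        if len(chains) != 2:
            raise StructureError(
                "interface_waters variant needs chain_groups for structures "
                f"with {len(chains)} chains"
            )
        chain_groups = ([chains[0]], [chains[1]])
        interface = annotate_interface(s, chain_groups, t.d_int)

    uniform = variant == "wet_uniform"
    g = _graph_from_residues(residues, t, uniform, interface)

    if variant == "interface_waters":
        wet = RIN(graph=g, metadata={})
        keep_waters = interface_waters(wet, interface)
        drop = [w for w in wet.water_nodes if w not in keep_waters]
        g.remove_nodes_from(drop)
        # edges among survivors are a subgraph of the wet edges under the
        # same thresholds, so no recomputation is needed beyond removal

    meta = {
        "variant": variant,
        "structure_id": s.id,
        "d_rr": t.d_w if uniform else t.d_rr,
        "d_w": t.d_w,
        "d_int": t.d_int,
        "interface_annotated": bool(interface) or chain_groups is not None,
    }
    return RIN(graph=g, metadata=meta)


def _graph_from_residues(
    residues: Sequence[Residue],
    t: ContactThresholds,
    uniform: bool,
    interface: set[str],
) -> nx.Graph:
    g = nx.Graph()
    for r in residues:
        g.add_node(
            r.label,
            kind=r.kind.value,
            chain=r.chain_id,
            interface=r.label in interface,
        )
    if any(r.kind is ResidueKind.WATER for r in residues):
        pairs = _mixed_contact_pairs(residues, t, uniform)
    else:
        pairs = _contact_pairs(residues, t.d_w if uniform else t.d_rr)
    for i, j in pairs:
        g.add_edge(residues[i].label, residues[j].label)
    return g


def annotate_interface(
    s: Structure,
    chain_groups: tuple[Iterable[str], Iterable[str]],
    d_int: float = 7.0,
) -> set[str]:
    """Protein residues with any heavy atom within ``d_int`` Å (inclusive) of
    the other chain group. Waters never define the interface."""
    g1, g2 = (set(g) for g in chain_groups)
    if not g1 or not g2:
        raise StructureError("both chain groups must be non-empty")
    if g1 & g2:
        raise StructureError(f"chain groups overlap: {sorted(g1 & g2)}")
    r1 = [r for r in s.protein_residues if r.chain_id in g1]
    r2 = [r for r in s.protein_residues if r.chain_id in g2]
    if not r1 or not r2:
        missing = "first" if not r1 else "second"
        raise StructureError(f"no protein residues in {missing} chain group")

    c1, i1 = _atom_table(r1)
    c2, i2 = _atom_table(r2)
    t1, t2 = cKDTree(c1), cKDTree(c2)
    # pad the query radius, then test inclusively on exact distances
    pairs = t1.query_ball_tree(t2, r=d_int * (1 + 1e-12) + 1e-9)
    out: set[str] = set()
    for a1, neighbors in enumerate(pairs):
        if not neighbors:
            continue
        d = np.linalg.norm(c2[neighbors] - c1[a1], axis=1)
        hits = np.asarray(neighbors)[d <= d_int]
        if hits.size:
            out.add(r1[int(i1[a1])].label)
            for a2 in hits:
                out.add(r2[int(i2[a2])].label)
    return out


def interface_waters(rin: RIN, interface: set[str] | None = None) -> set[str]:
    """Waters adjacent (one RIN edge) to at least one interface residue."""
    iface = interface if interface is not None else rin.interface_residues
    out: set[str] = set()
    for w in rin.water_nodes:
        if any(nb in iface for nb in rin.graph.neighbors(w)):
            out.add(w)
    return out


def remove_water_nodes(
    rin: RIN,
    selector: str | Sequence[str] = "max_degree",
    k: int | None = None,
    restrict_to: Iterable[str] | None = None,
) -> RIN:
    """Remove selected water nodes (with incident edges) from a wet RIN.

    Selectors: ``"max_degree"`` removes the single highest-degree water
    (ties broken by lexicographic label), ``"degree_ge"`` removes waters of
    degree ≥ ``k``, or an explicit list of water labels. ``restrict_to``
    limits the candidate waters (e.g. to interface waters). The removed
    labels and selector are recorded in the result metadata.
    """
    waters = set(rin.water_nodes)
    if restrict_to is not None:
        waters &= set(restrict_to)
    if isinstance(selector, str):
        if selector == "max_degree":
            if not waters:
                removed: list[str] = []
            else:
                removed = [min(waters, key=lambda w: (-rin.degree(w), w))]
        elif selector == "degree_ge":
            if k is None:
                raise ValueError("degree_ge selector requires k")
            removed = sorted(w for w in waters if rin.degree(w) >= k)
        else:
            raise ValueError(f"unknown selector {selector!r}")
    else:
        removed = list(selector)
        bad = [w for w in removed if w not in set(rin.water_nodes)]
        if bad:
            raise ValueError(f"not water nodes of this RIN: {bad}")
    out = rin.copy()
    out.graph.remove_nodes_from(removed)
    out.metadata = {
        **rin.metadata,
        "water_removal": {
            "selector": selector if isinstance(selector, str) else "explicit",
            "k": k,
            "removed": sorted(removed),
        },
    }
    return out
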