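"""Contact detection, RIN variants, interface annotation, water removal."""

import itertools

import networkx as nx
import numpy as np
import pytest

from rinwater import (
    ContactThresholds,
    StructureError,
    annotate_interface,
    build_rin,
    interface_waters,
    min_atom_distance,
    remove_water_nodes,
)
from rinwater.synthetic import SynthParams, generate_complex

from conftest import make_residue, make_structure


class TestMinAtomDistance:
    @pytest.mark.parametrize(
        "ca, cb, expected",
        [
            ([(0, 0, 0)], [(4.9, 0, 0)], 4.9),
            ([(0, 0, 0), (10, 0, 0)], [(3, 4, 0)], 5.0),
            ([(1, 2, 3)], [(1, 2, 3)], 0.0),
        ],
    )
    def test_examples(self, ca, cb, expected):
        a = make_residue("A", 1, "GLY", ca)
        b = make_residue("A", 2, "ALA", cb)
        assert min_atom_distance(a, b) == pytest.approx(expected)


def two_res_one_water(d_water=3.4):
    """r1 at origin, r2 at 4.9 Å, water at d_water from r1 (far from r2)."""
    return make_structure(
        [
            make_residue("A", 1, "GLY", [(0, 0, 0)]),
            make_residue("A", 2, "ALA", [(4.9, 0, 0)]),
            make_residue("A", 100, "HOH", [(-d_water, 0, 0)]),
        ]
    )


class TestBuildRin:
    def test_wet_vs_dry_edges(self):
        s = two_res_one_water(3.4)
        wet = build_rin(s, "wet")
        dry = build_rin(s, "dry")
        assert set(map(frozenset, wet.graph.edges)) == {
            frozenset({"Gly1.A", "Ala2.A"}),
            frozenset({"Gly1.A", "Hoh100.A"}),
        }
        assert set(map(frozenset, dry.graph.edges)) == {frozenset({"Gly1.A", "Ala2.A"})}
        assert dry.water_nodes == []

    @pytest.mark.parametrize(
        "d, connected",
        [(3.499, True), (3.5, False), (3.501, False)],
    )
    def test_water_contact_is_strictly_below(self, d, connected):
        wet = build_rin(two_res_one_water(d), "wet")
        assert wet.graph.has_edge("Gly1.A", "Hoh100.A") is connected

    @pytest.mark.parametrize("d, connected", [(4.999, True), (5.0, False)])
    def test_residue_contact_is_strictly_below(self, d, connected):
        s = make_structure(
            [
                make_residue("A", 1, "GLY", [(0, 0, 0)]),
                make_residue("A", 2, "ALA", [(d, 0, 0)]),
            ]
        )
        rin = build_rin(s, "dry")
        assert rin.graph.has_edge("Gly1.A", "Ala2.A") is connected

    def test_uniform_variant_shrinks_residue_cutoff(self):
        s = two_res_one_water(3.4)
        uni = build_rin(s, "wet_uniform")
        # 4.9 Å residue pair is out of reach at the uniform 3.5 Å cutoff
        assert not uni.graph.has_edge("Gly1.A", "Ala2.A")
        assert uni.graph.has_edge("Gly1.A", "Hoh100.A")
        assert uni.metadata["d_rr"] == 3.5

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="variant"):
            build_rin(two_res_one_water(), "moist")

    def test_single_residue_is_error(self):
        s = make_structure([make_residue("A", 1, "GLY", [(0, 0, 0)])])
        with pytest.raises(StructureError):
            build_rin(s, "dry")


class TestInterface:
    def two_chain(self, gap):
        return make_structure(
            [
                make_residue("A", 1, "GLY", [(0, 0, 0)]),
                make_residue("A", 2, "ALA", [(0, 30, 0)]),
                make_residue("B", 1, "SER", [(gap, 0, 0)]),
            ]
        )

    @pytest.mark.parametrize(
        "gap, labels",
        [
            (6.9, {"Gly1.A", "Ser1.B"}),
            (7.0, {"Gly1.A", "Ser1.B"}),  # "within" is inclusive
            (7.1, set()),
            (50.0, set()),
        ],
    )
    def test_inclusive_seven_angstrom_rule(self, gap, labels):
        s = self.two_chain(gap)
        assert annotate_interface(s, (["A"], ["B"]), 7.0) == labels

    def test_empty_group_is_error(self):
        with pytest.raises(StructureError):
            annotate_interface(self.two_chain(5), (["A"], ["Z"]))

    def test_overlapping_groups_are_error(self):
        with pytest.raises(StructureError):
            annotate_interface(self.two_chain(5), (["A"], ["A", "B"]))


class TestInterfaceWaters:
    def fixture_rin(self):
        s = make_structure(
            [
                make_residue("A", 1, "GLY", [(0, 0, 0)]),      # interface
                make_residue("A", 2, "ALA", [(0, 20, 0)]),     # far from B
                make_residue("B", 1, "SER", [(6, 0, 0)]),      # interface
                make_residue("A", 100, "HOH", [(0, 3, 0)]),    # bonded to Gly1.A
                make_residue("A", 101, "HOH", [(0, 17.5, 0)]),  # bonded to Ala2.A only
                make_residue("A", 102, "HOH", [(0, 6, 0)]),    # bonded to Hoh100 only
            ]
        )
        return build_rin(s, "wet", chain_groups=(["A"], ["B"]))

    def test_adjacency_rule(self):
        rin = self.fixture_rin()
        iface = rin.interface_residues
        assert iface == {"Gly1.A", "Ser1.B"}
        assert interface_waters(rin, iface) == {"Hoh100.A"}

    def test_water_chained_through_water_is_excluded(self):
        rin = self.fixture_rin()
        assert "Hoh102.A" not in interface_waters(rin)

    def test_dry_rin_has_no_interface_waters(self, wet_dry_small):
        _, dry = wet_dry_small
        assert interface_waters(dry, dry.interface_residues) == set()

    def test_variant_matches_explicit_filter(self):
        s = make_structure(
            [
                make_residue("A", 1, "GLY", [(0, 0, 0)]),
                make_residue("A", 2, "ALA", [(0, 20, 0)]),
                make_residue("B", 1, "SER", [(6, 0, 0)]),
                make_residue("A", 100, "HOH", [(0, 3, 0)]),
                make_residue("A", 101, "HOH", [(0, 17.5, 0)]),
            ]
        )
        wet = build_rin(s, "wet", chain_groups=(["A"], ["B"]))
        ifw = build_rin(s, "interface_waters", chain_groups=(["A"], ["B"]))
        assert set(ifw.water_nodes) == interface_waters(wet, wet.interface_residues)
        # surviving edges are exactly the wet edges among survivors
        survivors = set(ifw.nodes)
        expected = {frozenset(e) for e in wet.graph.edges if set(e) <= survivors}
        assert {frozenset(e) for e in ifw.graph.edges} == expected


class TestRemoveWaters:
    def graded_rin(self):
        # w1 bonded to 3 residues+..., w2 lower degree, w3 isolated-ish
        residues = [make_residue("A", i, "GLY", [(3.0 * i, 0, 0)]) for i in range(1, 9)]
        waters = [
            make_residue("A", 100, "HOH", [(3.0, 2.0, 0)]),   # near several residues
            make_residue("A", 101, "HOH", [(12.0, 3.0, 0)]),  # near one
            make_residue("A", 102, "HOH", [(0, 50, 0)]),      # no contacts
        ]
        return build_rin(make_structure(residues + waters), "wet")

    def test_max_degree_selector(self):
        rin = self.graded_rin()
        degs = {w: rin.degree(w) for w in rin.water_nodes}
        top = min(degs, key=lambda w: (-degs[w], w))
        out = remove_water_nodes(rin, "max_degree")
        assert out.metadata["water_removal"]["removed"] == [top]
        assert top not in out.graph

    def test_degree_ge_selector(self):
        rin = self.graded_rin()
        out = remove_water_nodes(rin, "degree_ge", k=1)
        expect = sorted(w for w in rin.water_nodes if rin.degree(w) >= 1)
        assert out.metadata["water_removal"]["removed"] == expect

    def test_explicit_selector(self):
        rin = self.graded_rin()
        out = remove_water_nodes(rin, ["Hoh102.A"])
        assert "Hoh102.A" not in out.graph
        assert set(rin.water_nodes) - set(out.water_nodes) == {"Hoh102.A"}

    def test_explicit_nonwater_is_error(self):
        rin = self.graded_rin()
        with pytest.raises(ValueError):
            remove_water_nodes(rin, ["Gly1.A"])
        with pytest.raises(ValueError):
            remove_water_nodes(rin, ["Hoh999.A"])

    def test_residue_nodes_untouched(self):
        rin = self.graded_rin()
        out = remove_water_nodes(rin, "degree_ge", k=0)
        assert set(out.residue_nodes) == set(rin.residue_nodes)
        assert out.water_nodes == []


def brute_force_edges(structure, t=ContactThresholds()):
    """All-pairs contact detection; the independent oracle for the KD-tree path."""
    edges = set()
    for a, b in itertools.combinations(structure.residues, 2):
        d = min(
            float(np.linalg.norm(np.asarray(pa.coord) - np.asarray(pb.coord)))
            for pa in a.atoms
            for pb in b.atoms
        )
        water = "HOH" in (a.res_name, b.res_name)
        cutoff = t.d_w if water else t.d_rr
        if d < cutoff:
            edges.add(frozenset({a.label, b.label}))
    return edges


class TestGraphProperties:
    def test_kdtree_matches_brute_force(self):
        s = generate_complex(SynthParams(n_res_per_chain=8, n_waters=25, seed=3))
        assert sum(len(r.atoms) for r in s.residues) <= 200
        wet = build_rin(s, "wet")
        assert {frozenset(e) for e in wet.graph.edges} == brute_force_edges(s)

    def test_wet_preserves_residue_residue_edges(self, wet_dry_small):
        wet, dry = wet_dry_small
        waters = set(wet.water_nodes)
        wet_rr = {frozenset(e) for e in wet.graph.edges if not (set(e) & waters)}
        assert wet_rr == {frozenset(e) for e in dry.graph.edges}

    def test_edge_monotonicity_in_thresholds(self, synth_small):
        lo = build_rin(synth_small, "wet", ContactThresholds(d_rr=4.0, d_w=3.0))
        hi = build_rin(synth_small, "wet", ContactThresholds(d_rr=6.0, d_w=4.0))
        assert {frozenset(e) for e in lo.graph.edges} <= {frozenset(e) for e in hi.graph.edges}

    def test_no_self_edges_and_symmetry(self, wet_dry_small):
        wet, _ = wet_dry_small
        assert all(u != v for u, v in wet.graph.edges)
        assert not wet.graph.is_directed()

    def test_interface_waters_subset(self, wet_dry_small):
        wet, _ = wet_dry_small
        assert interface_waters(wet, wet.interface_residues) <= set(wet.water_nodes)
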