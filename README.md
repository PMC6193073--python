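# rinwater

Water-inclusive residue interaction networks for protein complexes.

Crystal structures of protein–protein complexes resolve ordered water
molecules on the surface and at the interface, yet residue interaction
network (RIN) analyses conventionally discard them. `rinwater` builds RINs
**with and without** crystallographic waters, scores every node with two
shortest-path centralities, and quantifies what the waters change: which
residues become central, how far the Z-score distribution shifts, and how
robust the result is to removing individual waters. It is aimed at
structural bioinformaticians studying protein–protein interfaces,
water-mediated contacts, and hotspot residues.

## The model

A RIN node is a residue or a water (HOH) molecule; an edge is a detected
contact. Residue–residue contacts: minimum heavy-atom pair distance
**< 5 Å**; water–water and water–residue contacts: **< 3.5 Å**. Interface
residues have any atom **≤ 7 Å** from the partner chain group; an interface
water is one adjacent to an interface residue in the RIN. Variants: `dry`
(no waters), `wet` (all waters), `interface_waters`, and a `wet_uniform`
control using 3.5 Å for every contact.

Two centrality analyses score each node *i* of a network *G*, and each
raw score is standardized over all nodes of the same network
(z = (x − μ)/σ, population σ; nodes with z ≥ 2 are *central*):

- **RCA** (residue centrality): `raw_i = L(G − i) − L(G)`, the change in
  average shortest path length upon removing the node, `L` averaged over
  connected node pairs;
- **BCA** (betweenness centrality): unnormalized Brandes betweenness, the
  number of shortest paths between other node pairs passing through *i*.

The differential analysis reports per method the central nodes *added* and
*lost* by the wet network versus the dry one, their union and intersection
across methods, and the per-residue shift ΔZ = Z_wet − Z_dry with summary
statistics (waters, which have no dry counterpart, are summarized by their
wet Z distribution instead). See `docs/methods.md` for conventions and
design choices.

## Worked example

Generate a synthetic two-chain complex with a 120-water shell and run the
full pipeline (with a real structure you would pass your own PDB file and,
for example, `--chains B,E --groups B:E`):

```sh
rinwater synth --n-res 30 --n-waters 120 --seed 7 --out demo.pdb
rinwater run demo.pdb --groups A:B --removal degree_ge:5 --out-dir demo-out
```

prints

```
wrote demo.pdb: 60 residues, 120 waters
added central nodes (wet vs dry):
  BCA: Asn23.A, Asn23.B, Hoh1117.A, Leu11.A, Leu11.B, Met13.A, Phe14.A, Pro15.B, Val20.A
  RCA: Hoh1117.A, Leu11.A, Phe14.A, Phe14.B, Pro15.B, Tyr19.A, Val20.A
  Union: Asn23.A, Asn23.B, Hoh1117.A, Leu11.A, Leu11.B, Met13.A, Phe14.A, Phe14.B, Pro15.B, Tyr19.A, Val20.A
  Intersection: Hoh1117.A, Leu11.A, Phe14.A, Pro15.B, Val20.A
  BCA: mean dZ=0.9216 (sd 0.679), water Z mean=-0.461
  RCA: mean dZ=0.6308 (sd 1.029), water Z mean=-0.315
artifacts in demo-out
```

Reading the output: including the waters made ten residues (and one water,
`Hoh1117.A`) newly central under at least one method; residue Z-scores
shifted up by a mean ΔZ of 0.63 (RCA) and 0.92 (BCA), compensated by the
water nodes' negative mean Z (they sit at the network's periphery). The
output directory holds, per variant, a Cytoscape-loadable SIF edge list and
node-attribute TSV; per method, a centrality TSV; plus `differential.json`,
the added-central-node table, a wet/dry × RCA/BCA Z table for the added
residues, the water-removal comparison, and `run_metadata.json` recording
every threshold and policy.

The same machinery is available as a library:

```python
import rinwater as rw

s = rw.generate_complex(rw.SynthParams(seed=7))          # or rw.parse_pdb("file.pdb")
wet = rw.build_rin(s, "wet", chain_groups=(["A"], ["B"]))
dry = rw.build_rin(s, "dry")
report = rw.compare({"RCA": rw.rca(wet), "BCA": rw.bca(wet)},
                    {"RCA": rw.rca(dry), "BCA": rw.bca(dry)})
print(sorted(report.union_added))
```

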