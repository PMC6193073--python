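# Methods

## Model

`rinwater` represents a protein complex as a residue interaction network
(RIN): an undirected graph whose nodes are amino-acid residues and,
optionally, crystallographic water molecules (HOH records), and whose edges
are spatial contacts. A residue–residue contact exists when the minimum
distance over all heavy-atom pairs of the two residues is **below 5 Å**; a
water–water or water–residue contact when it is **below 3.5 Å** (roughly the
donor–acceptor distance of a hydrogen bond). Contact thresholds are strict
(`<`); the **7 Å interface** rule ("any atom within 7 Å of any atom of the
partner group") is inclusive (`≤`). Boundary cases are measure-zero in real
coordinates, but the conventions are fixed so they are testable.

Four network variants are built from one structure:

| variant | nodes | thresholds |
|---|---|---|
| `dry` | residues only | 5 Å |
| `wet` | residues + all waters | 5 / 3.5 Å |
| `wet_uniform` | residues + waters | 3.5 Å for everything (control) |
| `interface_waters` | residues + waters adjacent to ≥1 interface residue | 5 / 3.5 Å |

An *interface water* is a water node with at least one RIN edge to an
interface residue. In the `interface_waters` variant the surviving edge set
is exactly the wet edge set restricted to surviving nodes (identical
thresholds make recomputation and subgraph restriction equivalent);
water–water edges among survivors are retained.

## Centrality analyses

Two node scores are computed per network, each standardized to a Z-score
over **all nodes of that network** — waters included when present. That
shared normalization population is deliberate: residue Z-scores in wet
networks shift upward precisely because the peripheral water nodes occupy
the low end of the same distribution.

**RCA (residue centrality)** — raw score of node *i* is
`L(G − i) − L(G)`, where `L` is the average shortest path length and
`G − i` removes the node with its incident edges. `L` averages over
*connected* node pairs only; pairs split across components are excluded from
numerator and denominator, and a graph with no connected pair has `L = 0`.
Removal-induced disconnection therefore enters through the changed pair set
rather than through an infinity or an arbitrary penalty — the simplest
convention that is well-defined on disconnected inputs. Positive raw (and
Z) means removal lengthens communication. Distances come from BFS
(`scipy.sparse.csgraph`), recomputed exactly per removal; no approximation.

**BCA (betweenness centrality)** — raw score is unnormalized Brandes
betweenness over unordered node pairs (networkx). The normalization choice
is immaterial: Z-scores are invariant under positive affine rescaling of the
raw values, a property the test suite asserts.

**Z-scores** use the population (not sample) standard deviation; when the
raw values have zero spread all Z are set to 0. A node is *central* when
Z ≥ 2 (inclusive).

The exact removal-centrality convention used by the original desktop
implementation of these analyses (difference vs relative change of `L`,
disconnection handling) is not published; the conventions above are this
package's own, recorded in every result's metadata, and can shift absolute
Z values slightly relative to numbers produced by other tools.

## Differential analysis

For a wet/dry pair of results per method: *added* central nodes
(central in wet, not in dry — waters can only appear here), *lost* central
nodes, the union and intersection of the added sets across methods, and
ΔZ = Z_wet − Z_dry per residue node (waters have no dry counterpart, so they
are excluded from ΔZ and summarized separately via the mean/SD of their wet
Z). The *added-residue shift* is
`(mean ΔZ of added central residues − μ(ΔZ)) / σ(ΔZ)` — how far, in global
SDs, the added residues' shift exceeds the global one; it is `None` when
σ(ΔZ) = 0. The interface view counts the union's members (waters excluded)
that are interface residues.

Water-removal experiments delete selected waters from the wet network —
the single maximum-degree water (ties broken by lexicographic label), all
waters of degree ≥ k, or an explicit list, optionally restricted to
interface waters — recompute both centralities, and compare the central
*residue* sets before and after.

Label exclusions (e.g. affinity-tag residues, which can score as central for
construct rather than biological reasons) are a reporting policy only: they
remove rows from tables and never enter any computation, an invariant the
tests check by recomputation.

## Structure handling

Parsing is delegated to gemmi; the package owns the policy: heavy atoms only
(hydrogens/deuteriums dropped — X-ray inputs rarely resolve them and their
inclusion would change contact counts), altloc groups resolved to the
highest-occupancy conformer with ties broken by altloc code order, non-water
HETATM entities (ions, buffer molecules) dropped by default with a switch to
keep them, water names WAT/DOD/H2O aliased to HOH, first model only. Node
labels are `<ResName><number><icode>.<chain>` (`Arg98.B`, `Hoh354.A`) and
must be unique. Chain selection keeps, by default, **all** waters in the
file regardless of their chain label, since deposition practice for water
chain ids varies; the alternative (waters of the selected chains only) is
available and the choice is recorded in metadata. Interface annotation uses
protein atoms only.

## Synthetic complexes

The generator emulates only the geometry the pipeline consumes: two chains
of clustered pseudo heavy atoms (3 per residue within 1.5 Å of a center;
centers 3.8 Å apart along a serpentine fold, so each chain's dry subgraph is
connected by construction), facing surfaces separated by a 5 Å gap (a
populated 7 Å interface with few direct cross-chain contacts), and waters
placed by rejection sampling in a 2.8–3.4 Å shell around the protein with a
2.6 Å minimum water–water spacing — so every water has a contact under the
3.5 Å rule and no two ordered waters clash. Defaults (30 residues/chain,
120 waters) give wet networks of 180 nodes, about a third of the size of a
real two-chain complex with its solvation shell; generation is deterministic
given the seed, and placement failure after a bounded retry budget raises.

What the generator does **not** model: side-chain chemistry and packing
heterogeneity, hydrogen-bond geometry, buried waters, crystallographic
disorder. Passing the synthetic suite therefore demonstrates that the
*pipeline* reproduces the qualitative wet-vs-dry phenomenology on inputs
with realistic contact statistics — denser wet networks, peripheral
low-degree waters with predominantly sub-threshold Z, a net gain of central
residues with an above-average ΔZ — not that any particular real complex
yields particular Z values.

## Problem sizes and numerical choices

The statistical tests and the acceptance script use 20 replicate complexes
at the generator defaults (180-node wet networks), a size chosen to make a
full 4-analysis replicate sub-second while keeping water and residue node
counts in a crystal-structure-like ratio. Oracle tests compare BCA against
exhaustive shortest-path enumeration on 200 random connected graphs of ≤ 8
nodes and RCA against a naive remove-and-recompute oracle on graphs of ≤ 30
nodes. Floating-point comparisons in oracle tests use 1e-9–1e-10 absolute
tolerance; results are bit-reproducible across runs for identical inputs.

One scale effect is worth naming: on real complexes, removing the dozen-odd
high-degree interface waters left the central residue sets exactly
unchanged. On 180-node synthetic networks the same experiment usually
changes the central set by one or two residues — removing nodes shrinks the
Z-normalization population, which flips residues sitting near the Z = 2
boundary, and a small network has proportionally more of those. The
acceptance report therefore includes both the exact-invariance rate and the
mean size of the central-set change.

## Limitations

- Contact definitions are purely geometric; no energy, hydrogen-bond
  geometry, or surface-based (Voronoi) edge definitions, and no edge weights.
- Only RCA and BCA; no closeness/eigenvector/current-flow centralities and
  no approximate betweenness.
- PDB input only (fixed-column), first model of multi-model files; no mmCIF,
  no assembly generation, no structure download.
- Sequence-adjacent residues are connected like any other pair (their
  backbone atoms are always within 5 Å); no covalent-exclusion rule is
  applied.
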