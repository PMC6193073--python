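"""Normalized structure model and PDB reading/writing.

The pipeline consumes a flat, filtered view of a crystal structure: protein
residues and crystallographic waters, each a group of heavy atoms with 3D
coordinates. Parsing is delegated to :mod:`gemmi`; this module owns the
filtering policy (hydrogen removal, altloc resolution, HETATM handling,
water-name aliasing) and the node-labeling convention ``<ResName><num>.<chain>``
(e.g. ``Arg98.B``, ``Hoh354.A``) used throughout the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "FilterPolicy",
    "ResidueKind",
    "StructureError",
    "WATER_ALIASES",
    "parse_pdb",
    "select_chains",
    "filter_components",
    "write_pdb",
]

#: Residue names treated as water and normalized to HOH.
WATER_ALIASES = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(ValueError):
    """Raised when a structure violates the model's preconditions."""


class ResidueKind(str, Enum):
    RESIDUE = "residue"
    WATER = "water"


@dataclass(frozen=True)
class Atom:
    """A heavy atom: name, element symbol, coordinates in Å, occupancy, altloc."""

    name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coord):
            raise StructureError(f"non-finite coordinate on atom {self.name!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(
                f"occupancy {self.occupancy} outside [0, 1] on atom {self.name!r}"
            )


@dataclass(frozen=True)
class Residue:
    """A residue or water molecule: chain, author number, name, atoms.

    ``kind`` is water iff the (normalized) residue name is HOH. The node
    label is ``<ResName><seq_number><icode>.<chain_id>`` with the residue
    name title-cased, matching the naming used for crystal structures
    (``Arg98.B``, ``Hoh354.A``).
    """

    chain_id: str
    seq_number: int
    res_name: str
    kind: ResidueKind
    atoms: tuple[Atom, ...]
    icode: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"residue {self.res_name}{self.seq_number} has no atoms")
        is_water_name = self.res_name.upper() in WATER_ALIASES or self.res_name.upper() == "HOH"
        if (self.kind is ResidueKind.WATER) != (self.res_name.upper() == "HOH"):
            raise StructureError(
                f"kind/name mismatch: {self.res_name!r} with kind={self.kind.value}"
                + ("" if not is_water_name else " (alias names must be normalized to HOH)")
            )

    @property
    def label(self) -> str:
        return f"{self.res_name.capitalize()}{self.seq_number}{self.icode.strip()}.{self.chain_id}"

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float64 coordinate array."""
        return np.asarray([a.coord for a in self.atoms], dtype=np.float64)


@dataclass
class Structure:
    """An ordered collection of residues with a free-text identifier."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.residues]
        if len(labels) != len(set(labels)):
            seen: set[str] = set()
            dup = next(l for l in labels if l in seen or seen.add(l))  # type: ignore[func-returns-value]
            raise StructureError(f"duplicate node label {dup!r}")

    @property
    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.kind is ResidueKind.RESIDUE]

    @property
    def waters(self) -> list[Residue]:
        return [r for r in self.residues if r.kind is ResidueKind.WATER]

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.protein_residues:
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FilterPolicy:
    """What survives parsing.

    remove_hydrogens : drop H/D atoms (crystal structures rarely resolve them,
        and their inclusion would change contact counts).
    keep_hetero : retain non-water HETATM entities (ions, cryoprotectants) as
        residue-kind nodes; off by default.
    water_aliases : residue names normalized to HOH.
    """

    remove_hydrogens: bool = True
    keep_hetero: bool = False
    water_aliases: frozenset[str] = frozenset(WATER_ALIASES)


def _resolve_altlocs(atoms: Sequence[Atom]) -> tuple[Atom, ...]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc code."""
    by_name: dict[str, Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
        elif (a.occupancy, _altloc_rank(a.altloc)) > (
            prev.occupancy,
            _altloc_rank(prev.altloc),
        ):
            by_name[a.name] = a
    return tuple(by_name.values())


def _altloc_rank(code: str) -> int:
    # earlier altloc code wins a tie: 'A' outranks 'B'
    return -ord(code) if code else 1


def parse_pdb(path: str | Path, policy: FilterPolicy | None = None) -> Structure:
    """Read a PDB file into a filtered :class:`Structure`.

    All ATOM records become protein residues; HETATM records named HOH (or an
    alias) become single-oxygen water nodes; other HETATMs follow
    ``policy.keep_hetero``. Only the first model of a multi-model file is used.

    Raises
    ------
    StructureError
        If no protein residue survives parsing.
    OSError
        If the file cannot be read.
    """
    policy = policy or FilterPolicy()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    residues: list[Residue] = []
    model = st[0]
    for chain in model:
        for res in chain:
            name = res.name.strip().upper()
            is_water = name in policy.water_aliases
            is_het = res.het_flag == "H"
            if is_het and not is_water and not policy.keep_hetero:
                continue
            atoms: list[Atom] = []
            for at in res:
                elem = at.element.name.upper()
                if policy.remove_hydrogens and elem in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        name=at.name,
                        element=elem,
                        coord=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        altloc=at.altloc if at.altloc != "\x00" else "",
                    )
                )
            atoms = list(_resolve_altlocs(atoms))
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    res_name="HOH" if is_water else name,
                    kind=ResidueKind.WATER if is_water else ResidueKind.RESIDUE,
                    atoms=tuple(atoms),
                    icode=res.seqid.icode.strip(),
                )
            )
    struct = Structure(id=path.stem, residues=residues, metadata={"source": str(path)})
    if not struct.protein_residues:
        raise StructureError(f"{path}: no protein residues parsed")
    return struct


def select_chains(
    s: Structure,
    chains: Iterable[str],
    keep_waters: str = "all",
) -> Structure:
    """Restrict protein residues to ``chains``.

    ``keep_waters``: ``"all"`` retains every water regardless of its chain
    label (default — crystallographic waters are often deposited under their
    own chain or the nearest protein chain); ``"selected"`` keeps only waters
    whose chain label is in the set. The policy is recorded in the output
    metadata.
    """
    chain_set = set(chains)
    if not chain_set:
        raise StructureError("empty chain selection")
    if keep_waters not in ("all", "selected"):
        raise ValueError(f"unknown water policy {keep_waters!r}")
    kept: list[Residue] = []
    for r in s.residues:
        if r.kind is ResidueKind.WATER:
            if keep_waters == "all" or r.chain_id in chain_set:
                kept.append(r)
        elif r.chain_id in chain_set:
            kept.append(r)
    out = Structure(
        id=s.id,
        residues=kept,
        metadata={**s.metadata, "chain_selection": sorted(chain_set), "water_policy": keep_waters},
    )
    if not out.protein_residues:
        raise StructureError(f"no protein residue in chains {sorted(chain_set)}")
    return out


def filter_components(s: Structure, policy: FilterPolicy | None = None) -> Structure:
    """Re-apply a filtering policy to an in-memory structure.

    Used when a structure was built programmatically rather than parsed.
    Hydrogens are dropped, altloc groups resolved to the highest-occupancy
    conformer, and non-water hetero entities follow the policy switch
    (the parser cannot re-decide hetero status here, so ``keep_hetero`` only
    matters at parse time).
    """
    policy = policy or FilterPolicy()
    kept: list[Residue] = []
    for r in s.residues:
        atoms = tuple(
            a
            for a in r.atoms
            if not (policy.remove_hydrogens and a.element.upper() in ("H", "D"))
        )
        atoms = _resolve_altlocs(atoms)
        if atoms:
            kept.append(replace(r, atoms=atoms))
    return Structure(id=s.id, residues=kept, metadata=dict(s.metadata))


_PDB_LINE = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:>3s} "
    "{chain:1s}{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
    "{occ:6.2f}{bfac:6.2f}          {element:>2s}\n"
)


def _atom_name_field(name: str, element: str) -> str:
    # PDB columns 13-16: one-letter elements start at column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a minimal fixed-column PDB file (ATOM/HETATM/TER/END).

    Sufficient for round-tripping synthetic fixtures and filtered structures;
    no header, connectivity or anisotropic records are emitted.
    """
    path = Path(path)
    serial = 0
    lines: list[str] = []
    last_chain: str | None = None
    for r in s.residues:
        if last_chain is not None and r.chain_id != last_chain and r.kind is ResidueKind.RESIDUE:
            lines.append("TER\n")
        if r.kind is ResidueKind.RESIDUE:
            last_chain = r.chain_id
        record = "HETATM" if r.kind is ResidueKind.WATER else "ATOM"
        for a in r.atoms:
            serial += 1
            lines.append(
                _PDB_LINE.format(
                    record=record,
                    serial=serial % 100000,
                    name=_atom_name_field(a.name, a.element),
                    altloc=a.altloc or " ",
                    resname=r.res_name,
                    chain=r.chain_id,
                    resseq=r.seq_number,
                    icode=r.icode or " ",
                    x=a.coord[0],
                    y=a.coord[1],
                    z=a.coord[2],
                    occ=a.occupancy,
                    bfac=0.0,
                    element=a.element,
                )
            )
    lines.append("END\n")
    path.write_text("".join(lines))
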