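import numpy as np
import pytest

from rinwater import (
    Atom,
    Residue,
    ResidueKind,
    Structure,
    SynthParams,
    build_rin,
    generate_complex,
)


def make_residue(chain, num, name, coords, atom_names=None):
    """Build a residue (or water, when name is HOH) from raw coordinates."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    names = atom_names or [f"C{i}" if name != "HOH" else "O" for i in range(len(coords))]
    kind = ResidueKind.WATER if name == "HOH" else ResidueKind.RESIDUE
    atoms = tuple(
        Atom(name=n, element="O" if name == "HOH" else "C", coord=tuple(c))
        for n, c in zip(names, coords)
    )
    return Residue(chain_id=chain, seq_number=num, res_name=name, kind=kind, atoms=atoms)


def make_structure(residues, sid="toy"):
    return Structure(id=sid, residues=list(residues))


@pytest.fixture(scope="session")
def synth_small():
    """Compact complex: 2 x 12 residues + 40 waters (fast per-test input)."""
    return generate_complex(SynthParams(n_res_per_chain=12, n_waters=40, seed=11))


@pytest.fixture(scope="session")
def synth_default():
    """Study-scale complex at generator defaults (30 res/chain, 120 waters)."""
    return generate_complex(SynthParams(seed=7))


@pytest.fixture(scope="session")
def wet_dry_small(synth_small):
    groups = (["A"], ["B"])
    wet = build_rin(synth_small, "wet", chain_groups=groups)
    dry = build_rin(synth_small, "dry", chain_groups=groups)
    return wet, dry
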