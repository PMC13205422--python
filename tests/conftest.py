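"""Shared fixtures: small hand-built molecular systems with known answers."""

import numpy as np
import pytest

from gelmesh.system import MolecularSystem
from gelmesh.topology import ACIDIC, build_bis, build_chain


def make_pair_system(distance: float, same_molecule: bool = False,
                     box: float = 30.0) -> MolecularSystem:
    """Two reactive CH sites ``distance`` Å apart, each carried by a
    minimal chain monomer (CA-CB-CC), in one or two molecules."""
    atoms = []
    bonds = []
    for k, x0 in enumerate((0.0, distance)):
        base = len(atoms)
        mol = 0 if same_molecule else k
        for name, dy in (("CA", -1.5), ("CB", 0.0), ("CC", 1.5)):
            atoms.append({
                "name": name, "element": "C", "mass": 13.0,
                "position": (10.0 + x0, 10.0 + dy, 10.0),
                "residue_label": "NIPAM", "resid": k if same_molecule else 0,
                "mol_id": mol,
                "reactive_site": name == "CB",
            })
        bonds += [(base, base + 1), (base + 1, base + 2)]
    return MolecularSystem.from_lists(atoms, bonds, (box, box, box))


@pytest.fixture
def pair_within_cutoff():
    return make_pair_system(3.4)


@pytest.fixture
def pair_beyond_cutoff():
    return make_pair_system(3.6)


@pytest.fixture(scope="session")
def small_packed():
    """Two short chains + a few BIS packed loosely; used by cross-linking
    and pruning tests (session-scoped: construction only, never mutated
    in place — run_crosslinking copies)."""
    from gelmesh.topology import pack_system

    chains = [build_chain(6, 1, ACIDIC, seed=s) for s in (0, 1)]
    return pack_system(chains, 6, density=0.5, tolerance=2.0, seed=7)


@pytest.fixture(scope="session")
def bis_molecule():
    return build_bis(seed=0)
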