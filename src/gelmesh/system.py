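"""Molecular system container and chemical reference data.

The package works at a united-atom level of description: heavy atoms carry
their bonded hydrogens implicitly (CH/CH2/CH3 masses), except for polar
hydrogens that participate in hydrogen bonding, which may be represented
explicitly when a builder chooses to.  The analysis layers only need
topology and geometry, not force-field energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

RESIDUE_LABELS = ("NIPAM", "AAC", "BIS", "IBU", "WAT", "ION", "OTHER")

#: Bondi van der Waals radii (Å) by element.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "CL": 1.75,
    "NA": 2.27,
    "X": 1.70,  # fallback
}

#: Standard atomic masses (g/mol) for bare elements.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "CL": 35.45,
    "NA": 22.990,
}


def vdw_radius(element: str) -> float:
    return BONDI_RADII.get(element.upper(), BONDI_RADII["X"])


class InvalidSystemError(ValueError):
    """Raised when a MolecularSystem violates its structural invariants."""


@dataclass
class MolecularSystem:
    """A periodic molecular configuration with explicit connectivity.

    Atom attributes are stored as parallel arrays of length ``n_atoms``.
    ``mol_ids`` identify molecules (chains, cross-linkers, drug or solvent
    molecules); intermolecular tests compare these ids, and cross-linking
    merges topology but deliberately keeps the original ids so provenance
    survives bond formation.
    """

    elements: np.ndarray
    names: np.ndarray
    residue_labels: np.ndarray
    resids: np.ndarray
    mol_ids: np.ndarray
    positions: np.ndarray
    vdw_radii: np.ndarray
    masses: np.ndarray
    reactive_site: np.ndarray
    reacted: np.ndarray
    protonated: np.ndarray
    bonds: np.ndarray  # (M, 2) int, each row sorted
    box: np.ndarray  # (3,) Å

    # -- construction -------------------------------------------------

    @classmethod
    def from_lists(cls, atoms, bonds, box) -> "MolecularSystem":
        """Build from a list of atom dicts and a list of (i, j) bonds."""
        n = len(atoms)

        def col(key, default, dtype):
            return np.asarray([a.get(key, default) for a in atoms], dtype=dtype)

        elements = col("element", "C", object)
        sys_ = cls(
            elements=elements,
            names=col("name", "X", object),
            residue_labels=col("residue_label", "OTHER", object),
            resids=col("resid", 0, int),
            mol_ids=col("mol_id", 0, int),
            positions=np.asarray([a["position"] for a in atoms], float).reshape(n, 3),
            vdw_radii=np.asarray(
                [a.get("vdw_radius", vdw_radius(str(e))) for a, e in zip(atoms, elements)], float
            ),
            masses=np.asarray(
                [a.get("mass", ELEMENT_MASSES.get(str(e).upper(), 12.011)) for a, e in zip(atoms, elements)],
                float,
            ),
            reactive_site=col("reactive_site", False, bool),
            reacted=col("reacted", False, bool),
            protonated=col("protonated", False, bool),
            bonds=normalize_bonds(bonds),
            box=np.asarray(box, float),
        )
        sys_.validate()
        return sys_

    # -- invariants ----------------------------------------------------

    def validate(self) -> None:
        n = self.n_atoms
        if not np.all(np.isfinite(self.positions)):
            raise InvalidSystemError("non-finite coordinates")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise InvalidSystemError("box lengths must be positive")
        if len(self.bonds):
            if self.bonds.min() < 0 or self.bonds.max() >= n:
                raise InvalidSystemError("bond endpoint out of range")
            key = self.bonds[:, 0] * n + self.bonds[:, 1]
            if len(np.unique(key)) != len(key):
                raise InvalidSystemError("duplicate bonds")
            if np.any(self.bonds[:, 0] == self.bonds[:, 1]):
                raise InvalidSystemError("self-bond")
        if np.any(self.reacted & ~self.reactive_site):
            raise InvalidSystemError("reacted flag on a non-reactive site")

    # -- convenience ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def copy(self) -> "MolecularSystem":
        return replace(
            self,
            **{
                f: getattr(self, f).copy()
                for f in (
                    "elements", "names", "residue_labels", "resids", "mol_ids",
                    "positions", "vdw_radii", "masses", "reactive_site",
                    "reacted", "protonated", "bonds", "box",
                )
            },
        )

    def bonded_neighbors(self, i: int) -> np.ndarray:
        """Indices of atoms bonded to atom ``i``."""
        if not len(self.bonds):
            return np.empty(0, int)
        hit = self.bonds[np.any(self.bonds == i, axis=1)]
        return hit[hit != i]

    def select(self, mask: np.ndarray) -> "MolecularSystem":
        """Subset atoms by boolean mask, re-indexing bonds consistently."""
        mask = np.asarray(mask, bool)
        index_map = -np.ones(self.n_atoms, int)
        index_map[mask] = np.arange(int(mask.sum()))
        keep_bond = mask[self.bonds[:, 0]] & mask[self.bonds[:, 1]] if len(self.bonds) else np.empty(0, bool)
        new_bonds = index_map[self.bonds[keep_bond]] if len(self.bonds) else self.bonds
        out = replace(
            self,
            elements=self.elements[mask],
            names=self.names[mask],
            residue_labels=self.residue_labels[mask],
            resids=self.resids[mask],
            mol_ids=self.mol_ids[mask],
            positions=self.positions[mask],
            vdw_radii=self.vdw_radii[mask],
            masses=self.masses[mask],
            reactive_site=self.reactive_site[mask],
            reacted=self.reacted[mask],
            protonated=self.protonated[mask],
            bonds=normalize_bonds(new_bonds),
            box=self.box.copy(),
        )
        out.validate()
        return out


def normalize_bonds(bonds) -> np.ndarray:
    """Canonicalize a bond list: int array, rows sorted, unique, ordered."""
    arr = np.asarray(list(bonds), int).reshape(-1, 2)
    if len(arr) == 0:
        return arr
    arr = np.sort(arr, axis=1)
    arr = np.unique(arr, axis=0)
    return arr


def merge_systems(systems: list[MolecularSystem], box) -> MolecularSystem:
    """Concatenate systems into one periodic box, offsetting ids."""
    if not systems:
        raise ValueError("nothing to merge")
    offset = 0
    mol_offset = 0
    parts: dict[str, list] = {f: [] for f in (
        "elements", "names", "residue_labels", "resids", "mol_ids", "positions",
        "vdw_radii", "masses", "reactive_site", "reacted", "protonated")}
    bonds = []
    for s in systems:
        for f in parts:
            val = getattr(s, f)
            if f == "mol_ids":
                val = val + mol_offset
            parts[f].append(val)
        if len(s.bonds):
            bonds.append(s.bonds + offset)
        offset += s.n_atoms
        mol_offset += int(s.mol_ids.max()) + 1 if s.n_atoms else 0
    merged = MolecularSystem(
        elements=np.concatenate(parts["elements"]),
        names=np.concatenate(parts["names"]),
        residue_labels=np.concatenate(parts["residue_labels"]),
        resids=np.concatenate(parts["resids"]),
        mol_ids=np.concatenate(parts["mol_ids"]),
        positions=np.vstack(parts["positions"]),
        vdw_radii=np.concatenate(parts["vdw_radii"]),
        masses=np.concatenate(parts["masses"]),
        reactive_site=np.concatenate(parts["reactive_site"]),
        reacted=np.concatenate(parts["reacted"]),
        protonated=np.concatenate(parts["protonated"]),
        bonds=normalize_bonds(np.vstack(bonds) if bonds else np.empty((0, 2), int)),
        box=np.asarray(box, float),
    )
    merged.validate()
    return merged
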