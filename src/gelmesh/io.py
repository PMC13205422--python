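"""Structure, trajectory and table I/O.

Coordinate formats (PDB v3.3, GRO, XYZ) are read and written through
MDAnalysis, which normalizes all coordinates to Å internally (GRO files
are stored in nm and converted on read, ×10).  Connectivity and the
builder's per-atom state travel in a JSON sidecar
``<file>.bonds.json`` — ``{"atoms": [...], "bonds": [[i, j], ...]}`` with
0-based atom ids — because the text coordinate formats cannot carry them.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .system import MolecularSystem, RESIDUE_LABELS, vdw_radius, ELEMENT_MASSES
from .trajectory import Trajectory


class ParseError(ValueError):
    pass


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".bonds.json")


def write_structure(system: MolecularSystem, path, with_sidecar: bool = True) -> None:
    """Write coordinates as PDB/GRO/XYZ (by extension) plus JSON sidecar."""
    path = Path(path)
    n = system.n_atoms
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    u.add_TopologyAttr("names", [str(s) for s in system.names])
    u.add_TopologyAttr("resnames", [_resname(l) for l in system.residue_labels])
    u.add_TopologyAttr("resids", np.asarray(system.resids, int) + 1)
    u.add_TopologyAttr("elements", [str(e) for e in system.elements])
    u.add_TopologyAttr("masses", system.masses)
    u.atoms.positions = system.positions.astype(np.float32)
    u.dimensions = [*system.box, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    if with_sidecar:
        sidecar = {
            "atoms": [
                {
                    "id": i,
                    "element": str(system.elements[i]),
                    "name": str(system.names[i]),
                    "residue_label": str(system.residue_labels[i]),
                    "resid": int(system.resids[i]),
                    "mol_id": int(system.mol_ids[i]),
                    "mass": float(system.masses[i]),
                    "vdw_radius": float(system.vdw_radii[i]),
                    "reactive_site": bool(system.reactive_site[i]),
                    "reacted": bool(system.reacted[i]),
                    "protonated": bool(system.protonated[i]),
                }
                for i in range(n)
            ],
            "bonds": [[int(a), int(b)] for a, b in system.bonds],
        }
        _sidecar_path(path).write_text(json.dumps(sidecar))


def _resname(label: str) -> str:
    # PDB residue-name column is 4 chars wide
    return {"NIPAM": "NIP", "AAC": "AAC", "BIS": "BIS", "IBU": "IBU",
            "WAT": "SOL", "ION": "ION"}.get(str(label), "OTH")


_LABEL_FROM_RESNAME = {"NIP": "NIPAM", "NIPA": "NIPAM", "AAC": "AAC", "BIS": "BIS",
                       "IBU": "IBU", "SOL": "WAT", "WAT": "WAT", "HOH": "WAT",
                       "ION": "ION", "NA": "ION", "CL": "ION", "OTH": "OTHER"}


def read_structure(path, box=None) -> MolecularSystem:
    """Read a PDB/GRO/XYZ structure (Å), merging the JSON sidecar if present.

    Unknown residue names map to the ``OTHER`` label with a warning.  XYZ
    files carry no box; pass ``box`` explicitly for them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as err:  # noqa: BLE001 - normalize parser errors
        raise ParseError(f"cannot parse {path}: {err}") from err
    n = len(u.atoms)
    sidecar = None
    if _sidecar_path(path).exists():
        sidecar = json.loads(_sidecar_path(path).read_text())
    if box is None:
        dims = u.dimensions
        if dims is None or not np.all(dims[:3] > 0):
            raise ParseError(f"{path} carries no box; pass box= explicitly")
        box = dims[:3]

    def attr(name, default):
        try:
            return [str(v) for v in getattr(u.atoms, name)]
        except (AttributeError, mda.exceptions.NoDataError):
            return [default] * n

    elements = attr("elements", "")
    names = attr("names", "X")
    if not any(elements):
        elements = [_guess_element(nm) for nm in names]
    resnames = attr("resnames", "OTH")
    labels = []
    for rn in resnames:
        lab = _LABEL_FROM_RESNAME.get(rn.upper().strip())
        if lab is None:
            if rn.upper().strip() in RESIDUE_LABELS:
                lab = rn.upper().strip()
            else:
                warnings.warn(f"unknown residue name {rn!r}; labeling OTHER")
                lab = "OTHER"
        labels.append(lab)
    atoms = []
    for i in range(n):
        entry = {
            "element": elements[i] or "C",
            "name": names[i],
            "residue_label": labels[i],
            "resid": int(u.atoms.resids[i]) - 1 if hasattr(u.atoms, "resids") else 0,
            "mol_id": 0,
            "position": u.atoms.positions[i].astype(float),
            "mass": ELEMENT_MASSES.get((elements[i] or "C").upper(), 12.011),
            "vdw_radius": vdw_radius(elements[i] or "C"),
        }
        if sidecar is not None:
            entry.update({k: sidecar["atoms"][i][k] for k in
                          ("element", "name", "residue_label", "resid", "mol_id",
                           "mass", "vdw_radius", "reactive_site", "reacted", "protonated")})
        atoms.append(entry)
    bonds = sidecar["bonds"] if sidecar else []
    return MolecularSystem.from_lists(atoms, bonds, np.asarray(box, float))


def _guess_element(name: str) -> str:
    for cand in (name[:2].capitalize(), name[:1].upper()):
        if cand.upper() in ELEMENT_MASSES:
            return cand.upper() if len(cand) == 1 else cand.upper()
    return "C"


# ---------------------------------------------------------------------------
# trajectories and index groups
# ---------------------------------------------------------------------------

def read_index_groups(path) -> dict:
    """Parse an index file: one ``name: space-separated 0-based ids`` per line."""
    groups = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ParseError(f"{path}:{ln}: expected 'name: ids'")
        name, ids = line.split(":", 1)
        groups[name.strip()] = np.asarray(ids.split(), int)
    return groups


def write_index_groups(groups: dict, path) -> None:
    lines = [f"{name}: {' '.join(map(str, np.asarray(idx, int)))}" for name, idx in groups.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path, groups, box=None, dt_ps: float = 1.0,
                    mol_ids=None, unwrapped: bool = False) -> Trajectory:
    """Read a multi-frame coordinate file (multi-model PDB, GRO series or
    XYZ) into a :class:`Trajectory`.

    ``groups`` is a dict or an index-file path.  Frame times come from the
    reader when available, else ``dt_ps`` spacing.  A ``<file>.box.json``
    sidecar (written by :func:`write_xyz_trajectory`) supplies boxes,
    times and the unwrapped flag for box-less formats.
    """
    if not isinstance(groups, dict):
        groups = read_index_groups(groups)
    sidecar_times = None
    box_sidecar = Path(str(path) + ".box.json")
    if box_sidecar.exists():
        meta = json.loads(box_sidecar.read_text())
        if box is None:
            box = None  # per-frame boxes below
            sidecar_boxes = np.asarray(meta["boxes"], float)
        else:
            sidecar_boxes = None
        sidecar_times = np.asarray(meta.get("times_ps", []), float)
        unwrapped = bool(meta.get("unwrapped", unwrapped))
    else:
        sidecar_boxes = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords, boxes, times = [], [], []
        for k, ts in enumerate(u.trajectory):
            coords.append(u.atoms.positions.astype(float).copy())
            if box is not None:
                boxes.append(np.asarray(box, float))
            elif sidecar_boxes is not None:
                boxes.append(sidecar_boxes[k])
            elif ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                boxes.append(ts.dimensions[:3].astype(float).copy())
            else:
                raise ParseError(f"{path} frame {k}: no box; pass box=")
            times.append(ts.time if ts.time and ts.time > 0 else k * dt_ps)
    if sidecar_times is not None and len(sidecar_times) == len(coords):
        times = sidecar_times
    times = np.asarray(times, float)
    if np.any(np.diff(times) <= 0):
        times = np.arange(len(coords)) * dt_ps
    n = coords[0].shape[0]
    return Trajectory(
        times=times, coordinates=np.stack(coords), boxes=np.stack(boxes),
        groups=groups,
        mol_ids=np.arange(n) if mol_ids is None else np.asarray(mol_ids, int),
        unwrapped=unwrapped,
    )


def write_xyz_trajectory(traj: Trajectory, path, names=None) -> None:
    """Plain multi-frame XYZ with a JSON box sidecar (Å)."""
    path = Path(path)
    names = names or ["C"] * traj.n_atoms
    with path.open("w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame t= {traj.times[k]:.3f} ps\n")
            for nm, (x, y, z) in zip(names, traj.coordinates[k]):
                fh.write(f"{nm} {x:.5f} {y:.5f} {z:.5f}\n")
    Path(str(path) + ".box.json").write_text(json.dumps(
        {"boxes": traj.boxes.tolist(), "times_ps": traj.times.tolist(),
         "unwrapped": traj.unwrapped}))


# ---------------------------------------------------------------------------
# release tables
# ---------------------------------------------------------------------------

def read_release_csv(path):
    """Long-format release CSV → dict of system_id → ReleaseProfile.

    Columns: system_id, time_h, release_pct[, sd_pct, urea, ...].
    """
    import pandas as pd

    from .release import ReleaseProfile

    df = pd.read_csv(path)
    out = {}
    for sid, grp in df.groupby("system_id"):
        grp = grp.sort_values("time_h")
        out[str(sid)] = ReleaseProfile(
            system_id=str(sid),
            times_h=grp["time_h"].to_numpy(float),
            cumulative_pct=grp["release_pct"].to_numpy(float),
            sd_pct=grp["sd_pct"].to_numpy(float) if "sd_pct" in grp else None,
            metadata={c: grp[c].iloc[0] for c in grp.columns
                      if c not in ("system_id", "time_h", "release_pct", "sd_pct")},
        )
    return out
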