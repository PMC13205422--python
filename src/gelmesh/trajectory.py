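"""Trajectory statistics: diffusion (MSD/Einstein), dissociated fraction,
radial number density, and geometric hydrogen-bond counting.

All analyses operate on a :class:`Trajectory`: ordered frames with a
periodic orthorhombic box and named index groups (polymer / drug / water).
Times are in ps, coordinates in Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import min_image_vectors, wrap_positions
from .units import A2_PER_PS_TO_1E7_CM2_S


class EmptySelectionError(ValueError):
    pass


class UndefinedFractionError(ValueError):
    pass


class WrapAmbiguityError(ValueError):
    pass


@dataclass
class Trajectory:
    """Ordered frames plus per-atom static metadata.

    ``mol_ids`` partition atoms into molecules; drug statistics are
    computed per molecule.  ``unwrapped`` must be true for MSD analysis
    (wrapped coordinates lose displacement history).
    """

    times: np.ndarray            # (n_frames,) ps, strictly increasing
    coordinates: np.ndarray      # (n_frames, n_atoms, 3) Å
    boxes: np.ndarray            # (n_frames, 3) Å
    groups: dict                 # name -> atom index array
    mol_ids: np.ndarray          # (n_atoms,)
    masses: np.ndarray | None = None
    radii: np.ndarray | None = None
    unwrapped: bool = False
    hbond_topology: dict | None = None  # {'donors','hydrogens','acceptors','donor_of_hydrogen'}
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        self.coordinates = np.asarray(self.coordinates, float)
        self.boxes = np.asarray(self.boxes, float)
        n = self.coordinates.shape[1]
        if self.masses is None:
            self.masses = np.ones(n)
        if self.radii is None:
            self.radii = np.full(n, 1.7)
        self.groups = {k: np.asarray(v, int) for k, v in self.groups.items()}

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def window_frames(self, window: tuple[float, float] | None) -> np.ndarray:
        """Frame indices whose times fall in ``window`` (default: final 10 ns)."""
        if window is None:
            window = (self.times[-1] - 10_000.0, self.times[-1])
        return np.flatnonzero((self.times >= window[0]) & (self.times <= window[1]))


def group_molecules(traj: Trajectory, group: str) -> list[np.ndarray]:
    """Atom index arrays of the individual molecules within a named group."""
    sel = traj.groups[group]
    if len(sel) == 0:
        raise EmptySelectionError(f"group {group!r} is empty")
    mols = traj.mol_ids[sel]
    return [sel[mols == m] for m in np.unique(mols)]


# ---------------------------------------------------------------------------
# minimum-distance series and dissociated fraction
# ---------------------------------------------------------------------------

def min_distance_series(traj: Trajectory, drug: str = "drug",
                        polymer: str = "polymer") -> np.ndarray:
    """Per-drug-molecule, per-frame minimum atom–atom minimum-image
    distance (Å) to the polymer group.  Shape (n_molecules, n_frames)."""
    poly = traj.groups[polymer]
    if len(poly) == 0:
        raise EmptySelectionError("polymer group is empty")
    drug_mols = group_molecules(traj, drug)
    out = np.empty((len(drug_mols), traj.n_frames))
    for k in range(traj.n_frames):
        box = traj.boxes[k]
        tree = cKDTree(wrap_positions(traj.coordinates[k][poly], box), boxsize=box)
        for m, atoms in enumerate(drug_mols):
            d, _ = tree.query(wrap_positions(traj.coordinates[k][atoms], box), k=1)
            out[m, k] = d.min()
    return out


def dissociated_fraction(traj: Trajectory, drug: str = "drug", polymer: str = "polymer",
                         cutoff: float = 5.0,
                         window: tuple[float, float] | None = None):
    """Percent of drug molecules whose window-averaged minimum distance to
    the polymer *exceeds* ``cutoff`` (equality keeps a molecule associated),
    plus the per-molecule boolean labels."""
    if len(traj.groups.get(drug, ())) == 0:
        raise UndefinedFractionError("no drug molecules")
    frames = traj.window_frames(window)
    series = min_distance_series(traj, drug, polymer)[:, frames]
    # strict exceedance with an fp guard: an average at exactly the cutoff
    # keeps the molecule associated
    labels = series.mean(axis=1) > cutoff + 1e-9
    return 100.0 * labels.sum() / len(labels), labels


# ---------------------------------------------------------------------------
# MSD / Einstein diffusion
# ---------------------------------------------------------------------------

@dataclass
class MsdCurve:
    lags: np.ndarray       # ps
    msd: np.ndarray        # Å^2
    n_origins: np.ndarray  # time origins contributing at each lag


@dataclass
class DiffusionEstimate:
    D: float               # 10^-7 cm^2 s^-1
    slope: float           # Å^2 / ps
    window: tuple          # (lag_min, lag_max) ps
    r_squared: float


def _autocorr_fft(x: np.ndarray) -> np.ndarray:
    n = len(x)
    f = np.fft.fft(x, 2 * n)
    return np.fft.ifft(f * f.conjugate())[:n].real


def _msd_single_fft(r: np.ndarray) -> np.ndarray:
    """Multiple-time-origin MSD of one walker, O(n log n) via FFT."""
    n = len(r)
    d = (r * r).sum(axis=1)
    s2 = sum(_autocorr_fft(r[:, i]) for i in range(3))
    q = 2.0 * d.sum()
    s1 = np.empty(n)
    for m in range(n):
        if m:
            q -= d[m - 1] + d[n - m]
        s1[m] = q / (n - m)
    return s1 - 2.0 * s2 / (n - np.arange(n))


def molecule_com(traj: Trajectory, group: str) -> np.ndarray:
    """Center-of-mass positions per molecule: (n_frames, n_mol, 3)."""
    mols = group_molecules(traj, group)
    out = np.empty((traj.n_frames, len(mols), 3))
    for m, atoms in enumerate(mols):
        w = traj.masses[atoms]
        out[:, m, :] = np.einsum("fij,i->fj", traj.coordinates[:, atoms, :], w) / w.sum()
    return out


def msd(traj: Trajectory, group: str = "drug", max_lag: float | None = None,
        origin_stride: int = 1) -> MsdCurve:
    """Center-of-mass MSD averaged over molecules and sliding time origins.

    ``max_lag`` defaults to one tenth of the trajectory span, the usual
    rule that keeps every lag averaged over many effectively independent
    origins (at lag τ a trajectory of span T contributes ~T/τ independent
    displacement segments, so τ ≪ T is required for a well-conditioned
    Einstein fit).
    """
    if not traj.unwrapped:
        raise WrapAmbiguityError(
            "MSD needs unwrapped coordinates; wrapped input loses displacements")
    com = molecule_com(traj, group)
    n = traj.n_frames
    span = traj.times[-1] - traj.times[0]
    if max_lag is None:
        max_lag = span / 10
    lags = traj.times - traj.times[0]
    n_lags = int(np.searchsorted(lags, max_lag, side="right"))
    if origin_stride == 1:
        acc = np.zeros(n)
        for m in range(com.shape[1]):
            acc += _msd_single_fft(com[:, m, :])
        curve = acc[:n_lags] / com.shape[1]
        n_origins = (n - np.arange(n))[:n_lags]
    else:
        origins = np.arange(0, n, origin_stride)
        curve = np.zeros(n_lags)
        n_origins = np.zeros(n_lags, int)
        for lag_idx in range(n_lags):
            o = origins[origins + lag_idx < n]
            disp = com[o + lag_idx] - com[o]
            curve[lag_idx] = np.mean((disp ** 2).sum(axis=2))
            n_origins[lag_idx] = len(o)
    return MsdCurve(lags=lags[:n_lags], msd=curve, n_origins=n_origins)


def fit_diffusion(curve: MsdCurve, window: tuple[float, float] | None = None) -> DiffusionEstimate:
    """Einstein-relation fit: D = slope/6 over a linear lag window.

    The default window is the final 10% of available lags.  The slope is an
    ordinary least-squares fit (with intercept); D is converted from
    Å^2/ps to 10^-7 cm^2 s^-1.
    """
    if window is None:
        window = (0.9 * curve.lags[-1], curve.lags[-1])
    mask = (curve.lags >= window[0]) & (curve.lags <= window[1])
    if mask.sum() < 3:
        raise ValueError("need at least 3 lag points in the fit window")
    x, y = curve.lags[mask], curve.msd[mask]
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope < 0:
        warnings.warn("negative MSD slope; D reported as fitted")
    d = slope / 6.0 * A2_PER_PS_TO_1E7_CM2_S
    return DiffusionEstimate(D=float(d), slope=float(slope),
                             window=(float(window[0]), float(window[1])),
                             r_squared=float(r2))


# ---------------------------------------------------------------------------
# radial number density
# ---------------------------------------------------------------------------

@dataclass
class RadialDensity:
    bin_edges: np.ndarray   # Å
    counts: np.ndarray      # mean molecules per bin per frame
    density: np.ndarray     # counts / shell volume (Å^-3)


def radial_density(traj: Trajectory, drug: str = "drug", polymer: str = "polymer",
                   bin_width: float = 1.0,
                   window: tuple[float, float] | None = None) -> RadialDensity:
    """Radial number density of drug-molecule centers of mass relative to
    the polymer center of mass, averaged over the window frames.

    Bins span [0, half box diagonal] so every molecule lands in a bin and
    per-frame counts sum exactly to the number of drug molecules.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    frames = traj.window_frames(window)
    drug_com = molecule_com(traj, drug)
    poly = traj.groups[polymer]
    if len(poly) == 0:
        raise EmptySelectionError("polymer group is empty")
    w = traj.masses[poly]
    rmax = float(np.linalg.norm(traj.boxes.max(axis=0)) / 2) + bin_width
    edges = np.arange(0.0, rmax + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    for k in frames:
        pcom = (traj.coordinates[k][poly] * w[:, None]).sum(axis=0) / w.sum()
        d = np.linalg.norm(
            min_image_vectors(drug_com[k] - pcom, traj.boxes[k]), axis=1)
        counts += np.histogram(d, bins=edges)[0]
    counts /= len(frames)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    return RadialDensity(bin_edges=edges, counts=counts, density=counts / shell)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class HBondCounts:
    d_cut: float
    angle_cut: float
    counts: dict            # category -> time-averaged count
    per_frame: dict         # category -> (n_frames,) series


class HBondTopologyError(ValueError):
    pass


def _atom_category(i: int, groups: dict) -> str | None:
    for name, idx in groups.items():
        if i in idx:
            return name
    return None


def hydrogen_bonds_frame(positions: np.ndarray, box, donors, hydrogens,
                         donor_of_hydrogen: dict, acceptors,
                         d_cut: float = 3.5, angle_cut: float = 35.0,
                         groups: dict | None = None) -> dict:
    """Count hydrogen bonds in one frame by the geometric criterion
    d(D···A) <= ``d_cut`` and angle(H–D···A) <= ``angle_cut``.

    Returns a dict mapping category (``"donorgroup-acceptorgroup"``, or
    ``"all"`` without groups) to counts.  Each donor–H pair is tested
    against every acceptor, so bridging donors can count twice by design.
    """
    positions = np.asarray(positions, float)
    box = np.asarray(box, float)
    donors = np.asarray(donors, int)
    acceptors = np.asarray(acceptors, int)
    group_sets = {k: set(np.asarray(v).tolist()) for k, v in (groups or {}).items()}
    for h in hydrogens:
        if int(h) not in donor_of_hydrogen:
            raise HBondTopologyError(f"hydrogen {h} has no parent donor")
    counts: dict[str, float] = {}
    if len(donors) == 0 or len(acceptors) == 0:
        return counts
    eps = 1e-9  # fp guard so exact-boundary geometries satisfy the <= criteria
    tree = cKDTree(wrap_positions(positions[acceptors], box), boxsize=box)
    for h in hydrogens:
        d_idx = int(donor_of_hydrogen[int(h)])
        near = tree.query_ball_point(wrap_positions(positions[d_idx], box), r=d_cut + eps)
        for a_pos in near:
            a_idx = int(acceptors[a_pos])
            if a_idx == d_idx or a_idx == int(h):
                continue
            v_da = min_image_vectors(positions[a_idx] - positions[d_idx], box)
            v_dh = min_image_vectors(positions[int(h)] - positions[d_idx], box)
            if np.linalg.norm(v_da) > d_cut + eps:
                continue
            cosang = np.dot(v_da, v_dh) / (np.linalg.norm(v_da) * np.linalg.norm(v_dh))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle <= angle_cut + eps:
                if group_sets:
                    gd = next((g for g, s in group_sets.items() if d_idx in s), None)
                    ga = next((g for g, s in group_sets.items() if a_idx in s), None)
                    if gd is None or ga is None:
                        continue
                    key = f"{gd}-{ga}"
                else:
                    key = "all"
                counts[key] = counts.get(key, 0) + 1
    return counts


def hydrogen_bonds(traj: Trajectory, d_cut: float = 3.5, angle_cut: float = 35.0,
                   categories: tuple = (("polymer", "polymer"), ("polymer", "drug"),
                                        ("drug", "polymer"), ("polymer", "water"),
                                        ("water", "polymer")),
                   window: tuple[float, float] | None = None) -> HBondCounts:
    """Categorized hydrogen-bond counts averaged over the window frames.

    Donor/hydrogen/acceptor metadata comes from ``traj.hbond_topology``.
    Symmetric category pairs (e.g. polymer–drug and drug–polymer) are
    merged into one canonical label.
    """
    if not traj.hbond_topology:
        raise HBondTopologyError("trajectory carries no hydrogen-bond topology")
    topo = traj.hbond_topology
    frames = traj.window_frames(window)
    canon = {}
    for a, b in categories:
        canon[f"{a}-{b}"] = "-".join(sorted((a, b), key=lambda g: (g != "polymer", g)))
    series: dict[str, np.ndarray] = {}
    for fi, k in enumerate(frames):
        raw = hydrogen_bonds_frame(
            traj.coordinates[k], traj.boxes[k], topo["donors"], topo["hydrogens"],
            topo["donor_of_hydrogen"], topo["acceptors"],
            d_cut=d_cut, angle_cut=angle_cut, groups=traj.groups)
        for key, val in raw.items():
            label = canon.get(key)
            if label is None:
                continue
            series.setdefault(label, np.zeros(len(frames)))[fi] += val
    return HBondCounts(
        d_cut=d_cut, angle_cut=angle_cut,
        counts={k: float(v.mean()) for k, v in series.items()},
        per_frame=series,
    )
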