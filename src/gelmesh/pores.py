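"""Periodic pore descriptors: pore limiting diameter (PLD) and maximum
pore diameter (MPD), plus steric-sieving classification against drug
molecular dimensions.

The box is discretized into a cubic lattice and each node is assigned its
minimum-image distance to the nearest atomic van der Waals surface
(negative inside an atom).  MPD is twice the largest node value — the
largest spherical probe that fits anywhere.  PLD is the diameter of the
largest probe that can percolate through the pore network across the
periodic boundaries: nodes with clearance >= d/2 are cluster-labeled with
periodic 6-connectivity (Hoshen–Kopelman union-find with image-offset
tracking), and a cluster wrapping around any box dimension percolates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import wrap_positions

#: ibuprofen molecular dimensions (Å) along its principal axes, from a
#: quantum-chemical 0.0015 a.u. electron-density surface; carried as
#: package constants (X <= Y <= Z).
IBU_DIMS_ANGSTROM = (6.78, 7.47, 12.03)

STERIC_LABELS = ("bottleneck_limited", "bottleneck_with_free_pockets", "transition", "free")


class TooCoarseGridError(ValueError):
    pass


class InsufficientFramesError(ValueError):
    pass


@dataclass
class DistanceGrid:
    """Clearance field: distance from lattice nodes to the nearest atom
    surface under periodic boundaries (negative inside atoms)."""

    spacing: float
    values: np.ndarray  # (nx, ny, nz)
    box: np.ndarray

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class MoleculeDims:
    """Molecular extents along principal axes, ascending (X <= Y <= Z), Å."""

    X: float
    Y: float
    Z: float

    def __post_init__(self):
        if not (0 < self.X <= self.Y <= self.Z):
            raise ValueError("dims must be positive and ascending")


IBU_DIMS = MoleculeDims(*IBU_DIMS_ANGSTROM)


@dataclass
class PoreMetrics:
    """Per-frame PLD/MPD with aggregate mean ± SD and a steric label."""

    per_frame: list  # (frame_time_ps, pld, mpd)
    mean_pld: float
    sd_pld: float
    mean_mpd: float
    sd_mpd: float
    steric_state: str


def distance_grid(positions: np.ndarray, box, spacing: float,
                  radii: np.ndarray, cap: float | None = None) -> DistanceGrid:
    """Sample min over atoms of (minimum-image distance − vdW radius) on a
    regular lattice spanning the box.

    With no atoms every node takes a sentinel value capped at half the box
    diagonal (or ``cap``).
    """
    box = np.asarray(box, float)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > box.min() / 4:
        raise TooCoarseGridError(f"spacing {spacing} too coarse for box {box}")
    dims = np.maximum(np.round(box / spacing).astype(int), 1)
    axes = [np.arange(n) * (L / n) for n, L in zip(dims, box)]
    if cap is None:
        # cap clearance at half the smallest edge: probe diameters are
        # never reported beyond the box edge
        cap = float(box.min() / 2)
    grid = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([g.ravel() for g in grid], axis=1)
    positions = np.asarray(positions, float).reshape(-1, 3)
    if len(positions) == 0:
        values = np.full(tuple(dims), cap)
        return DistanceGrid(spacing=spacing, values=values, box=box)
    radii = np.broadcast_to(np.asarray(radii, float), (len(positions),))
    values = np.full(len(nodes), np.inf)
    wrapped = wrap_positions(positions, box)
    # exact per-radius-class nearest-surface search: with one KD-tree per
    # distinct radius, nearest center <=> nearest surface within the class
    for r in np.unique(radii):
        tree = cKDTree(wrapped[radii == r], boxsize=box)
        d, _ = tree.query(nodes, k=1)
        values = np.minimum(values, d - r)
    values = np.minimum(values, cap)
    return DistanceGrid(spacing=spacing, values=values.reshape(tuple(dims)), box=box)


def max_pore_diameter(grid: DistanceGrid) -> float:
    """Twice the largest positive clearance; 0 when the box is fully occupied."""
    vmax = float(grid.values.max())
    return 2.0 * vmax if vmax > 0 else 0.0


# ---------------------------------------------------------------------------
# periodic percolation labeling
# ---------------------------------------------------------------------------

class _UnionFindOffsets:
    """Union-find over cluster labels tracking the lattice-image offset of
    each label relative to its root (the Hoshen–Kopelman extension for
    periodic percolation detection)."""

    def __init__(self, n: int):
        self.parent = np.arange(n)
        self.offset = np.zeros((n, 3), int)  # offset of node relative to its parent
        self.percolates = np.zeros(3, bool)

    def find(self, i: int) -> tuple[int, np.ndarray]:
        path = []
        while self.parent[i] != i:
            path.append(i)
            i = self.parent[i]
        # path compression with offset accumulation
        total = np.zeros(3, int)
        for node in reversed(path):
            total = total + self.offset[node]
            self.parent[node] = i
            self.offset[node] = total.copy()
        return i, None

    def root_offset(self, i: int) -> np.ndarray:
        off = np.zeros(3, int)
        while self.parent[i] != i:
            off += self.offset[i]
            i = self.parent[i]
        return off

    def union(self, a: int, b: int, delta: np.ndarray) -> None:
        """Join labels with constraint pos(a) - pos(b) = delta (image units)."""
        ra, _ = self.find(a)
        rb, _ = self.find(b)
        off_a = self.root_offset(a)
        off_b = self.root_offset(b)
        if ra == rb:
            mismatch = off_a - off_b - delta
            self.percolates |= mismatch != 0
            return
        # attach rb under ra satisfying the constraint
        self.parent[rb] = ra
        self.offset[rb] = off_a - delta - off_b
        # invariant: off(b->rb) + off(rb->ra) = off_a - delta


def percolating_clusters(mask: np.ndarray) -> np.ndarray:
    """Dimensions (as a boolean triple) along which the open-node mask
    percolates under periodic 6-connectivity."""
    if not mask.any():
        return np.zeros(3, bool)
    labels, n_labels = ndimage.label(mask)  # 6-connectivity, non-periodic
    if n_labels == 0:
        return np.zeros(3, bool)
    uf = _UnionFindOffsets(n_labels + 1)
    for axis in range(3):
        lo = np.take(labels, 0, axis=axis)
        hi = np.take(labels, labels.shape[axis] - 1, axis=axis)
        both = (lo > 0) & (hi > 0)
        if not both.any():
            continue
        delta = np.zeros(3, int)
        delta[axis] = 1  # the low face sits one image above the high face
        for a, b in zip(lo[both].ravel(), hi[both].ravel()):
            uf.union(int(a), int(b), delta)
    return uf.percolates.copy()


def _percolates(mask: np.ndarray, require_all: bool = False) -> bool:
    dims = percolating_clusters(mask)
    return bool(dims.all()) if require_all else bool(dims.any())


def pore_limiting_diameter(grid: DistanceGrid, tolerance: float = 0.05,
                           require_all_dims: bool = False) -> float:
    """Largest probe diameter that still percolates across the periodic box.

    Because the percolation indicator changes only at node clearance
    values, the supremum is found by bisection over the sorted unique
    positive clearances — exact to the grid discretization (and therefore
    well within any ``tolerance`` >= 0).
    """
    vals = np.unique(grid.values[grid.values > 0])
    if len(vals) == 0:
        return 0.0
    if not _percolates(grid.values >= vals[0], require_all_dims):
        return 0.0
    lo, hi = 0, len(vals) - 1  # invariant: vals[lo] percolates
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _percolates(grid.values >= vals[mid], require_all_dims):
            lo = mid
        else:
            hi = mid - 1
    return 2.0 * float(vals[lo])


def pld_exhaustive(grid: DistanceGrid, require_all_dims: bool = False) -> float:
    """Brute-force threshold sweep over every unique clearance (test oracle)."""
    best = 0.0
    for v in np.unique(grid.values[grid.values > 0]):
        if _percolates(grid.values >= v, require_all_dims):
            best = 2.0 * float(v)
    return best


# ---------------------------------------------------------------------------
# aggregation over trajectory frames
# ---------------------------------------------------------------------------

def sample_frame_indices(times: np.ndarray, n_frames: int, window: tuple[float, float]) -> np.ndarray:
    """Uniformly sample ``n_frames`` frame indices (first/last inclusive)
    from frames whose times fall inside ``window``."""
    times = np.asarray(times, float)
    in_win = np.flatnonzero((times >= window[0]) & (times <= window[1]))
    if len(in_win) < n_frames:
        raise InsufficientFramesError(
            f"window holds {len(in_win)} frames, need {n_frames}")
    pick = np.round(np.linspace(0, len(in_win) - 1, n_frames)).astype(int)
    return in_win[pick]


def aggregate_pore_metrics(traj, n_frames: int = 20,
                           window: tuple[float, float] | None = None,
                           spacing: float = 0.4, radii=None,
                           group: str = "polymer",
                           dims: MoleculeDims = IBU_DIMS) -> PoreMetrics:
    """Per-frame PLD/MPD over uniformly sampled frames, with mean ± SD.

    Defaults mirror the study: 20 frames from the final 10 ns window.
    ``traj`` is a :class:`gelmesh.trajectory.Trajectory`; the distance grid
    is built from the ``group`` atoms (the polymer network).
    """
    if n_frames < 2:
        raise InsufficientFramesError("need at least 2 frames")
    times = traj.times
    if window is None:
        window = (times[-1] - 10_000.0, times[-1])  # final 10 ns in ps
    idx = sample_frame_indices(times, n_frames, window)
    sel = traj.groups[group]
    per_frame = []
    for k in idx:
        pos = traj.coordinates[k][sel]
        r = traj.radii[sel] if radii is None else np.broadcast_to(np.asarray(radii, float), (len(sel),))
        g = distance_grid(pos, traj.boxes[k], spacing, r)
        pld = pore_limiting_diameter(g)
        mpd = max_pore_diameter(g)
        per_frame.append((float(times[k]), pld, mpd))
    plds = np.array([p[1] for p in per_frame])
    mpds = np.array([p[2] for p in per_frame])
    state = classify_steric_state(float(plds.mean()), float(mpds.mean()), dims)
    return PoreMetrics(
        per_frame=per_frame,
        mean_pld=float(plds.mean()), sd_pld=float(plds.std(ddof=1)),
        mean_mpd=float(mpds.mean()), sd_mpd=float(mpds.std(ddof=1)),
        steric_state=state,
    )


def classify_steric_state(pld: float, mpd: float, dims: MoleculeDims = IBU_DIMS) -> str:
    """Steric-sieving category of a pore network for a drug of given dims.

    Rule order (resolving the overlap between the descriptive scenarios):
    if MPD > Z the largest pockets admit the drug in any orientation —
    ``free`` when the bottleneck also admits it (PLD >= Y), otherwise
    ``bottleneck_with_free_pockets`` (confined bottlenecks but releasable
    local pockets).  If only MPD > Y, passage is orientation-sensitive:
    ``transition`` when PLD >= Y, else ``bottleneck_limited``.  Otherwise
    ``bottleneck_limited``.
    """
    if pld > mpd:
        raise ValueError(f"PLD {pld} exceeds MPD {mpd}")
    if mpd > dims.Z:
        return "bottleneck_with_free_pockets" if pld < dims.Y else "free"
    if mpd > dims.Y:
        return "transition" if pld >= dims.Y else "bottleneck_limited"
    return "bottleneck_limited"


def molecule_dimensions(positions: np.ndarray, radii) -> MoleculeDims:
    """Molecular extents along principal axes of the position covariance.

    Extents are max − min of surface projections (center ± radius along
    each axis), sorted ascending.  This is a hard-sphere surface
    approximation of an electron-density surface measurement.
    """
    pos = np.asarray(positions, float).reshape(-1, 3)
    if len(pos) < 2:
        r = float(np.asarray(radii).ravel()[0])
        return MoleculeDims(2 * r, 2 * r, 2 * r)
    radii = np.broadcast_to(np.asarray(radii, float), (len(pos),))
    centered = pos - pos.mean(axis=0)
    cov = centered.T @ centered
    if np.allclose(cov, 0):
        import warnings

        warnings.warn("degenerate (coincident) coordinates: zero extent")
        r = float(radii[0])
        return MoleculeDims(2 * r, 2 * r, 2 * r)
    _, axes = np.linalg.eigh(cov)
    extents = []
    for k in range(3):
        proj = centered @ axes[:, k]
        extents.append(float((proj + radii).max() - (proj - radii).min()))
    x, y, z = sorted(extents)
    return MoleculeDims(x, y, z)
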