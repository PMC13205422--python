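"""Synthetic-data generators with known ground truth.

Every input class the pipeline consumes can be generated here with the
answer attached, so each analysis stage is testable without external data:

* Brownian drug trajectories with a prescribed diffusion coefficient
  (exercises the MSD/Einstein estimator),
* dissociation scenarios with an exact number of detached molecules
  (exercises the 5 Å average-minimum-distance classifier),
* release curves drawn from the four kinetic models with replicate noise
  (exercises the fitting stage),
* pore phantoms with analytically known PLD/MPD,
* donor–H–acceptor triplets at controlled geometry.

Default scales mirror the study conditions: 50 drug molecules, a 10 ns
analysis window at 1 ps sampling, triplicate release measurements.
All generators are deterministic in their seed.
"""

from __future__ import annotations

import warnings

import numpy as np

from .release import ReleaseProfile, _model_fn
from .trajectory import Trajectory
from .units import D_1E7_CM2_S_TO_A2_PER_PS


def _unit_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def gen_brownian(D: float, n_mol: int = 50, dt: float = 1.0, n_steps: int = 10_000,
                 box: float = 500.0, seed: int = 0) -> Trajectory:
    """Independent 3-D Brownian walkers at diffusion coefficient ``D``
    (10^-7 cm^2 s^-1), with a static decoy polymer group.

    Increments are Gaussian with per-step, per-dimension variance
    2·D·dt (unit-converted to Å^2); coordinates are kept unwrapped.
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)
    d_a2ps = D * D_1E7_CM2_S_TO_A2_PER_PS
    sigma = np.sqrt(2.0 * d_a2ps * dt)
    n_frames = n_steps + 1
    start = rng.uniform(0.25 * box, 0.75 * box, size=(n_mol, 3))
    steps = rng.normal(0.0, sigma, size=(n_steps, n_mol, 3)) if sigma > 0 else np.zeros((n_steps, n_mol, 3))
    walks = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)], axis=0)
    # decoy static polymer: a compact cluster at the box center
    poly = box / 2 + 2.0 * _unit_sphere(rng, 8)
    coords = np.concatenate([walks, np.repeat(poly[None], n_frames, axis=0)], axis=1)
    return Trajectory(
        times=np.arange(n_frames) * dt,
        coordinates=coords,
        boxes=np.full((n_frames, 3), box),
        groups={"drug": np.arange(n_mol), "polymer": np.arange(n_mol, n_mol + 8)},
        mol_ids=np.concatenate([np.arange(n_mol), np.full(8, n_mol)]),
        unwrapped=True,
        ground_truth={"D": D, "dt": dt, "sigma_step": float(sigma)},
    )


def gen_dissociation_scenario(n_total: int = 50, n_free: int = 11, cutoff: float = 5.0,
                              margin: float = 1.0, window: float = 10_000.0,
                              n_frames: int = 21, seed: int = 0,
                              box: float = 100.0) -> Trajectory:
    """Static-polymer trajectory in which exactly ``n_free`` of ``n_total``
    drug molecules have a time-averaged minimum distance of
    ``cutoff + margin`` and the rest ``cutoff − margin``.

    Per-frame radial jitter is mean-centered so the window averages hit
    the intended distances exactly; ground-truth labels are attached.
    With ``margin == 0`` every average sits exactly at the cutoff, which
    the classifier must keep as associated (the criterion is strict
    exceedance).
    """
    if not 0 <= n_free <= n_total:
        raise ValueError("need 0 <= n_free <= n_total")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    rng = np.random.default_rng(seed)
    center = np.full(3, box / 2)
    targets = np.where(np.arange(n_total) < n_free, cutoff + margin, cutoff - margin)
    order = rng.permutation(n_total)
    targets = targets[order]
    labels = order < n_free  # permuted free/bound assignment
    dirs = _unit_sphere(rng, n_total)
    jitter_scale = min(margin, 0.5) * 0.5
    jitter = rng.normal(0.0, jitter_scale, size=(n_frames, n_total)) if jitter_scale > 0 else np.zeros((n_frames, n_total))
    jitter -= jitter.mean(axis=0, keepdims=True)
    radii_t = targets[None, :] + jitter  # (n_frames, n_total)
    coords = center[None, None, :] + radii_t[:, :, None] * dirs[None, :, :]
    coords = np.concatenate([coords, np.repeat(center[None, None, :], n_frames, axis=0)], axis=1)
    times = np.linspace(0.0, window, n_frames)
    return Trajectory(
        times=times,
        coordinates=coords,
        boxes=np.full((n_frames, 3), box),
        groups={"drug": np.arange(n_total), "polymer": np.array([n_total])},
        mol_ids=np.concatenate([np.arange(n_total), [n_total]]),
        unwrapped=False,
        ground_truth={"labels": labels, "fraction_pct": 100.0 * n_free / n_total},
    )


DEFAULT_RELEASE_TIMES_H = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0)


def gen_release_curve(model: str, params: dict, times_h=DEFAULT_RELEASE_TIMES_H,
                      noise_sd: float = 0.0, n_rep: int = 3, seed: int = 0,
                      system_id: str = "synthetic") -> ReleaseProfile:
    """Release profile sampled from one kinetic model with replicate noise.

    ``params`` uses the model's parameter names (k0 | k1 | kH | kKP, n).
    Replicates add Gaussian noise of ``noise_sd`` percentage points; the
    mean curve is truncated to [0, 100]% with a warning if the parameters
    drive it beyond.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times_h, float)
    fn = _model_fn(model)
    clean = fn(t, *params.values()) * 100.0
    if np.any(clean > 100.0):
        warnings.warn("model parameters drive release beyond 100%; truncating")
    reps = np.repeat(clean[None, :], n_rep, axis=0)
    if noise_sd > 0:
        reps = reps + rng.normal(0.0, noise_sd, size=(n_rep, len(t)))
    reps = np.clip(reps, 0.0, 100.0)
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if n_rep > 1 else np.zeros(len(t))
    prof = ReleaseProfile(system_id=system_id, times_h=t, cumulative_pct=mean,
                          sd_pct=sd, n_replicates=n_rep,
                          metadata={"model": model, "params": dict(params),
                                    "noise_sd": noise_sd})
    return prof


def gen_pore_phantom(kind: str, box: float = 24.0, r: float = 3.0,
                     lattice_a: float = 1.0, atom_radius: float = 1.2,
                     seed: int = 0):
    """Atom arrangement with analytically known pore descriptors.

    kinds
    -----
    ``channel`` : straight z-axis cylindrical void of clearance radius
        ``r`` through an otherwise blocked box → PLD = MPD = 2r.
    ``cavity``  : sealed spherical void of clearance radius ``r`` at the
        box center → PLD = 0, MPD = 2r.
    ``lattice`` : simple-cubic sphere packing (spacing ``lattice_a``·k) —
        ground truth from the closed-form face-window and body-center gaps.
    ``vacuum``  : empty box → PLD = MPD = probe cap (box edge).

    Returns ``(positions, radii, box_vec, truth)``.
    """
    box_vec = np.full(3, float(box))
    n = int(round(box / lattice_a))
    a = box / n  # commensurate lattice spacing
    grid = np.arange(n) * a
    pts = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1).reshape(-1, 3)
    center = box_vec / 2
    if kind == "channel":
        dist_axis = np.linalg.norm(pts[:, :2] - center[:2], axis=1)
        keep = dist_axis >= r + atom_radius
        truth = {"pld": 2.0 * r, "mpd": 2.0 * r}
    elif kind == "cavity":
        dist = np.linalg.norm(pts - center, axis=1)
        keep = dist >= r + atom_radius
        truth = {"pld": 0.0, "mpd": 2.0 * r}
    elif kind == "lattice":
        # sparse simple-cubic packing: spheres every `step` lattice sites
        step = max(int(round((4.0 * atom_radius) / a)), 3)
        while n % step:  # keep the packing commensurate with the box
            step += 1
        idx = np.stack(np.meshgrid(*[np.arange(0, n, step)] * 3, indexing="ij"), axis=-1).reshape(-1, 3)
        pts = idx * a
        keep = np.ones(len(pts), bool)
        spacing = step * a
        truth = {
            "pld": 2.0 * (spacing / np.sqrt(2.0) - atom_radius),
            "mpd": 2.0 * (spacing * np.sqrt(3.0) / 2.0 - atom_radius),
        }
    elif kind == "vacuum":
        pts = np.empty((0, 3))
        keep = np.ones(0, bool)
        truth = {"pld": float(box), "mpd": float(box)}
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    positions = pts[keep]
    radii = np.full(len(positions), atom_radius)
    return positions, radii, box_vec, truth


def gen_hbond_triplet(dDA: float = 2.9, angle_deg: float = 10.0,
                      dDH: float = 1.0, box: float = 30.0):
    """Donor, hydrogen and acceptor at an exact requested geometry.

    The H–D···A angle (at the donor) equals ``angle_deg`` exactly and the
    donor–acceptor distance equals ``dDA``.  Returns ``(positions, box_vec,
    topology)`` where topology feeds the hydrogen-bond counter directly.
    """
    if dDA <= 0:
        raise ValueError("dDA must be positive")
    if not 0 <= angle_deg <= 180:
        raise ValueError("angle must lie in [0, 180] degrees")
    box_vec = np.full(3, float(box))
    center = box_vec / 2
    d_pos = center
    a_pos = center + np.array([dDA, 0.0, 0.0])
    theta = np.radians(angle_deg)
    h_pos = center + dDH * np.array([np.cos(theta), np.sin(theta), 0.0])
    positions = np.stack([d_pos, h_pos, a_pos])
    topology = {"donors": np.array([0]), "hydrogens": np.array([1]),
                "donor_of_hydrogen": {1: 0}, "acceptors": np.array([2])}
    return positions, box_vec, topology
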