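"""Periodic-boundary geometry helpers (orthorhombic boxes, minimum image)."""

from __future__ import annotations

import numpy as np


def min_image_vectors(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Parameters
    ----------
    d : array (..., 3)
        Raw displacement vectors.
    box : array (3,)
        Orthorhombic box edge lengths (Å).
    """
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image distances between points ``a`` and ``b`` (broadcasting)."""
    d = min_image_vectors(np.asarray(a, float) - np.asarray(b, float), box)
    return np.linalg.norm(d, axis=-1)


def brute_force_min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Distance between two points minimized over all 27 periodic images.

    Reference implementation used as an oracle in tests; O(27) per pair.
    """
    box = np.asarray(box, float)
    best = np.inf
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            for iz in (-1, 0, 1):
                shift = box * np.array([ix, iy, iz], float)
                best = min(best, float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float) + shift)))
    return best


def wrap_positions(x: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary cell [0, box)."""
    box = np.asarray(box, float)
    return np.mod(x, box)
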