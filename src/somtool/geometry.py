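"""Minimum-image geometry for orthorhombic periodic boxes."""

from __future__ import annotations

import numpy as np

__all__ = ["min_image_vectors", "min_image_distance_matrix", "wrap"]


def min_image_vectors(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors b - a, broadcast to (len(a), len(b), 3)."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    box = np.asarray(box, dtype=float)
    d = b[None, :, :] - a[:, None, :]
    d -= box * np.round(d / box)
    return d


def min_image_distance_matrix(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.linalg.norm(min_image_vectors(a, b, box), axis=-1)


def wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary box [0, L) per dimension."""
    return np.mod(coords, np.asarray(box, dtype=float))
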