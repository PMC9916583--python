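"""Small rigid-transform helpers used by the kinematics and dynamics cores."""

from __future__ import annotations

import numpy as np


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix: skew(v) @ w == np.cross(v, w)."""
    return np.array(
        [
            [0.0, -v[2], v[1]],
            [v[2], 0.0, -v[0]],
            [-v[1], v[0], 0.0],
        ]
    )


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    c = np.cos(angle)
    s = np.sin(angle)
    k = skew(axis)
    return np.eye(3) * c + s * k + (1.0 - c) * np.outer(axis, axis)


def normalized(v, name: str = "axis") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"{name} has zero length")
    return v / n


def is_spd(mat: np.ndarray, tol: float = 1e-9) -> bool:
    """Symmetric positive semidefinite check (used for inertia tensors)."""
    if not np.allclose(mat, mat.T, atol=1e-9):
        return False
    eig = np.linalg.eigvalsh(0.5 * (mat + mat.T))
    return bool(eig.min() >= -tol * max(1.0, abs(eig.max())))
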