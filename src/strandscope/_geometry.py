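"""Low-level vector geometry: angle wrapping, torsion measurement, NeRF placement.

All angles are in degrees, all lengths in Angstrom.  Arrays are vectorised
over a leading "frames" axis wherever it makes sense, so building or
re-measuring a 50,000-model ensemble never loops in Python over frames.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_angle", "dihedral", "bond_angle", "nerf_place"]


def wrap_angle(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) in degrees into the half-open interval (-180, +180].

    -180 itself maps to +180, so the interval is genuinely half-open on the
    left; this is the convention used for every dihedral in the package.
    """
    wrapped = -((-np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0)
    return wrapped


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Signed torsion angle a-b-c-d in degrees, IUPAC sign convention.

    Inputs are ``(..., 3)`` coordinate arrays; broadcasting over leading
    axes is supported.  The result lies in (-180, +180].
    """
    b1 = np.asarray(b) - np.asarray(a)
    b2 = np.asarray(c) - np.asarray(b)
    b3 = np.asarray(d) - np.asarray(c)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, _normalize(b2))
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Angle a-b-c at vertex b, degrees in [0, 180]."""
    u = _normalize(np.asarray(a) - np.asarray(b))
    v = _normalize(np.asarray(c) - np.asarray(b))
    cosang = np.clip(np.einsum("...i,...i->...", u, v), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def nerf_place(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: np.ndarray | float,
) -> np.ndarray:
    """Place atom D from internal coordinates (natural-extension reference frame).

    D is bonded to ``c`` with the given bond length, forms bond angle b-c-D
    and torsion a-b-c-D.  ``torsion`` may be a scalar or a per-frame array;
    ``a``, ``b``, ``c`` are ``(..., 3)`` arrays sharing leading axes.

    The placement is exact: ``dihedral(a, b, c, nerf_place(...)) == torsion``
    up to floating-point rounding.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    theta = np.radians(angle)
    tau = np.radians(np.asarray(torsion, dtype=float))

    u_bc = _normalize(c - b)
    n = _normalize(np.cross(b - a, u_bc))
    m = np.cross(n, u_bc)

    d_local = bond * (
        -np.cos(theta) * u_bc
        + np.sin(theta) * (np.cos(tau)[..., None] * m - np.sin(tau)[..., None] * n)
    )
    return c + d_local
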