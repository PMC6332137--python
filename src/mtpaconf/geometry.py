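"""Exact 3-D vector geometry for torsion analysis of crystal structures.

Torsion angles follow the IUPAC (Klyne–Prelog) sign convention: looking from
the second axis atom toward the third, a clockwise rotation of the far bond
relative to the near bond is positive.  Angles live on the half-open interval
(−180°, +180]; a value of exactly −180° is reported as +180°.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "InvalidCellError",
    "UnitCell",
    "torsion_angle",
    "fractional_to_cartesian",
    "invert_through_origin",
    "wrap_angle",
]


class DegenerateGeometryError(ValueError):
    """Raised when a torsion is undefined (collinear or coincident atoms)."""


class InvalidCellError(ValueError):
    """Raised for unit cells with non-positive lengths, angles or volume."""


def wrap_angle(value: float) -> float:
    """Map an angle in degrees onto (−180, +180], sending −180 to +180."""
    v = float(value) % 360.0
    if v > 180.0:
        v -= 360.0
    if v <= -180.0:  # numerical guard; % keeps v in [0, 360)
        v += 360.0
    return 180.0 if v == -180.0 else v


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise InvalidCellError(f"cell lengths must be positive: {self}")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not (0.0 < ang < 180.0):
                raise InvalidCellError(f"cell angle {name}={ang} outside (0, 180)")
        if self.volume <= 0 or not np.isfinite(self.volume):
            raise InvalidCellError(f"degenerate cell (volume {self.volume}): {self}")

    @property
    def volume(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return float(self.a * self.b * self.c * np.sqrt(arg))

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """Matrix M with cart = M @ frac (standard a-along-x convention)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v = self.volume / (a * b * c)  # unit-cell volume of the normalized cell
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, c * v / sg],
            ]
        )


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return v


def torsion_angle(p1, p2, p3, p4, labels: tuple[str, ...] | None = None) -> float:
    """Signed dihedral angle p1–p2–p3–p4 in degrees, in (−180, +180].

    Positive when, viewed from ``p2`` toward ``p3``, the bond p3→p4 is rotated
    clockwise from the bond p2→p1 (IUPAC convention).  Antisymmetric under
    inversion of all four points.

    Raises
    ------
    DegenerateGeometryError
        If p2 == p3 or either bonded triple is collinear.
    """
    p1, p2, p3, p4 = (_as_vec(p) for p in (p1, p2, p3, p4))
    what = labels or ("p1", "p2", "p3", "p4")
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise DegenerateGeometryError(f"coincident axis atoms {what[1]} and {what[2]}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    scale = max(np.linalg.norm(b1), 1.0) * nb2
    if np.linalg.norm(n1) < 1e-10 * scale:
        raise DegenerateGeometryError(f"collinear atoms {what[0]}–{what[1]}–{what[2]}")
    if np.linalg.norm(n2) < 1e-10 * max(np.linalg.norm(b3), 1.0) * nb2:
        raise DegenerateGeometryError(f"collinear atoms {what[1]}–{what[2]}–{what[3]}")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def fractional_to_cartesian(cell: UnitCell, frac) -> np.ndarray:
    """Transform fractional coordinates to Cartesian Å for ``cell``.

    Accepts a single 3-vector or an (n, 3) array.
    """
    frac = np.asarray(frac, dtype=float)
    return frac @ cell.orthogonalization_matrix.T


def cartesian_to_fractional(cell: UnitCell, cart) -> np.ndarray:
    cart = np.asarray(cart, dtype=float)
    inv = np.linalg.inv(cell.orthogonalization_matrix)
    return cart @ inv.T


def invert_through_origin(points) -> np.ndarray:
    """Point inversion x → −x; an involution that mirrors every chirality."""
    return -np.asarray(points, dtype=float)
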