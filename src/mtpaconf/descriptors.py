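"""The seven torsion descriptors of the MTPA-amide survey.

Selection conventions follow the survey's figure captions: F3 is the CF3
fluorine antiperiplanar to the carbonyl carbon (the one maximizing
|C1–C2–C3–F|, hence |tau| >= 120° for a near-tetrahedral CF3), and C10 is
the phenyl ortho carbon minimizing |O2–C2–C5–C| (hence |theta2| <= 90°).
S-acid moieties are mirror-normalized into the R-acid frame by negating
every torsion.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import networkx as nx
import numpy as np

from .cif import CrystalStructure, TORSION_FIELDS
from .geometry import torsion_angle, wrap_angle
from .perception import (
    MtpaRoleMap,
    RoleMapError,
    chirality_at_c2,
    idealized_h_position,
)

log = logging.getLogger(__name__)

__all__ = [
    "TorsionSet",
    "ConformerClass",
    "select_f3",
    "select_c10",
    "compute_torsion_set",
    "normalize_to_R",
    "classify_conformer",
]


@dataclass(frozen=True)
class TorsionSet:
    """The seven descriptors (degrees) of one moiety, plus chirality.

    ``tau_ap`` is ``None`` when the ap substituent is H (no X1'' atom) and
    ``tau_h`` when C1' carries no single methine hydrogen.  ``normalized``
    records whether the values are already in the R-acid frame.
    """

    theta1: float
    tau_f3: float
    tau_sp: float
    tau_ap: Optional[float]
    tau_h: Optional[float]
    theta2: float
    tau_ome: float
    chirality: str
    normalized: bool = False
    tau_h_inferred: bool = False

    def __post_init__(self) -> None:
        if self.chirality not in ("R", "S"):
            raise ValueError(f"chirality must be R or S, got {self.chirality!r}")
        for name in TORSION_FIELDS:
            v = getattr(self, name)
            if v is not None and not (-180.0 < v <= 180.0):
                raise ValueError(f"{name}={v} outside (-180, 180]")

    @classmethod
    def from_values(cls, torsions: dict, chirality: str, **kw) -> "TorsionSet":
        return cls(chirality=chirality,
                   **{k: torsions.get(k) for k in TORSION_FIELDS}, **kw)

    def torsions(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in TORSION_FIELDS}


@dataclass(frozen=True)
class ConformerClass:
    """Categorical conformational assignment of one normalized moiety."""

    theta1_window: str          # sp_major | minor_anti | other
    cf3_staggered: bool
    amide_form: str             # Z | E | indeterminate
    mosher_type: bool
    carbonyl_methoxy: str       # syn | anti


def select_f3(structure: CrystalStructure, rolemap: MtpaRoleMap) -> int:
    """Index of F3, the CF3 fluorine ap to the carbonyl carbon C1."""
    if len(rolemap.f_all) != 3:
        raise RoleMapError(f"expected 3 fluorines on C3, got {len(rolemap.f_all)}")
    pos = structure.cartesian()
    torsions = {
        f: torsion_angle(pos[rolemap.c1], pos[rolemap.c2], pos[rolemap.c3], pos[f])
        for f in rolemap.f_all
    }
    best = sorted(torsions, key=lambda f: (-abs(torsions[f]),
                                           structure.atoms[f].label))
    if abs(abs(torsions[best[0]]) - abs(torsions[best[1]])) < 0.01:
        log.info("F3 tie within 0.01 deg; picking label order (%s)",
                 structure.atoms[best[0]].label)
    return best[0]


def select_c10(structure: CrystalStructure, rolemap: MtpaRoleMap) -> int:
    """Index of C10, the ortho carbon giving the smaller |O2–C2–C5–C|."""
    pos = structure.cartesian()
    torsions = {
        c: torsion_angle(pos[rolemap.o2], pos[rolemap.c2], pos[rolemap.c5], pos[c])
        for c in rolemap.ortho_pair
    }
    (a, ta), (b, tb) = torsions.items()
    if abs(abs(ta) - abs(tb)) < 1e-9:  # both at exactly 90: take the + one
        choice = a if ta > 0 else b
        log.info("ortho-carbon tie at ±90; picking positive torsion (%s)",
                 structure.atoms[choice].label)
        return choice
    return a if abs(ta) < abs(tb) else b


def compute_torsion_set(
    structure: CrystalStructure,
    rolemap: MtpaRoleMap,
    bonds: Optional[nx.Graph] = None,
    infer_missing_h: bool = True,
) -> TorsionSet:
    """Measure all seven descriptors of one lateralized moiety.

    ``tau_h`` is computed from the deposited methine H when present; when the
    structure omits riding hydrogens and ``bonds`` is given, an idealized H
    is placed and the result flagged ``tau_h_inferred``.
    """
    if not rolemap.lateralized:
        raise RoleMapError("role map not lateralized; run assign_sp_ap first")
    pos = structure.cartesian()
    r = rolemap

    def tors(*idx, what):
        return torsion_angle(*(pos[i] for i in idx),
                             labels=tuple(structure.atoms[i].label for i in idx))

    theta1 = tors(r.o1, r.c1, r.c2, r.c3, what="theta1")
    f3 = select_f3(structure, r)
    tau_f3 = tors(r.c1, r.c2, r.c3, f3, what="tau_f3")
    tau_sp = tors(r.c1p, r.n, r.c1, r.o1, what="tau_sp")
    tau_ap = None
    if r.x1pp is not None:
        tau_ap = tors(r.x1pp, r.n, r.c1, r.o1, what="tau_ap")
    tau_h = None
    inferred = False
    if r.h1p is not None:
        tau_h = tors(r.h1p, r.c1p, r.n, r.c1, what="tau_h")
    elif infer_missing_h and bonds is not None and r.c1p is not None \
            and structure.elements[r.c1p] == "C":
        heavy = [j for j in bonds.neighbors(r.c1p)
                 if structure.elements[j] != "H"]
        h_count = sum(1 for j in bonds.neighbors(r.c1p)
                      if structure.elements[j] == "H")
        if len(heavy) == 3 and h_count == 0:
            try:
                h_pos = idealized_h_position(structure, bonds, r.c1p)
            except RoleMapError:
                h_pos = None  # planar (e.g. aryl) alpha carbon: no methine H
            if h_pos is not None:
                tau_h = torsion_angle(h_pos, pos[r.c1p], pos[r.n], pos[r.c1])
                inferred = True
    c10 = select_c10(structure, r)
    theta2 = tors(r.o2, r.c2, r.c5, c10, what="theta2")
    tau_ome = tors(r.c1, r.c2, r.o2, r.c4, what="tau_ome")
    chirality = chirality_at_c2(structure, r)
    return TorsionSet(theta1=theta1, tau_f3=tau_f3, tau_sp=tau_sp,
                      tau_ap=tau_ap, tau_h=tau_h, theta2=theta2,
                      tau_ome=tau_ome, chirality=chirality,
                      tau_h_inferred=inferred)


def _negate(v: Optional[float]) -> Optional[float]:
    # +180 is its own mirror image under the (−180, 180] convention
    return None if v is None else wrap_angle(-v)


def normalize_to_R(ts: TorsionSet) -> TorsionSet:
    """Express a torsion set in the R-acid frame (idempotent).

    S-acid moieties are replaced by their mirror images, i.e. every non-null
    torsion changes sign; R-acid input passes through unchanged.
    """
    if ts.normalized:
        return ts
    if ts.chirality == "R":
        return replace(ts, normalized=True)
    flipped = {k: _negate(v) for k, v in ts.torsions().items()}
    return replace(ts, **flipped, normalized=True)


def classify_conformer(
    ts: TorsionSet,
    rsp_class: str,
    rap_class: str,
    amide_arity: str,
) -> ConformerClass:
    """Categorical assignment of one R-normalized torsion set.

    The major conformer window for theta1 is (−30, 0]; moieties outside it
    whose methoxy torsion sits on the anti branch (|C1–C2–O2–C4| >= 120°)
    are the carbonyl/methoxy-anti minor conformer; the rest are irregular.
    The CF3 is staggered when |tau_f3| >= 150°.
    """
    from .perception import classify_amide_form  # local to avoid cycle

    if not ts.normalized:
        raise ValueError("classify_conformer requires an R-normalized TorsionSet")
    anti = ts.tau_ome is not None and abs(ts.tau_ome) >= 120.0
    if -30.0 < ts.theta1 <= 0.0:
        window = "sp_major"
    elif anti:
        window = "minor_anti"
    else:
        window = "other"
    return ConformerClass(
        theta1_window=window,
        cf3_staggered=abs(ts.tau_f3) >= 150.0,
        amide_form=classify_amide_form(rsp_class, rap_class),
        mosher_type=(amide_arity == "secondary"
                     and rsp_class == "secondary_alkyl"),
        carbonyl_methoxy="anti" if anti else "syn",
    )
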