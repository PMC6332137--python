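"""Locate MTPA-amide moieties in raw coordinates and assign atom roles.

The moiety searched for is the 3,3,3-trifluoro-2-methoxy-2-phenylpropanamide
core: a quaternary stereocenter C2 carrying the amide carbonyl C1(=O1)–N, a
CF3 carbon C3, a methoxy oxygen O2–C4, and a phenyl ipso carbon C5.  The two
N-substituents other than C1 are lateralized into the synperiplanar (sp) and
antiperiplanar (ap) side by the sign-free magnitude of their X–N–C1–O1
torsion, and classified by the branching of their alpha atom.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .cif import CrystalStructure
from .geometry import torsion_angle

log = logging.getLogger(__name__)

__all__ = [
    "COVALENT_RADII",
    "MtpaRoleMap",
    "GeometryError",
    "RoleMapError",
    "AmbiguousLateralizationError",
    "perceive_bonds",
    "find_mtpa_moieties",
    "assign_sp_ap",
    "chirality_at_c2",
    "substituent_class",
    "classify_amide_form",
    "idealized_h_position",
]

#: Cordero-style single-bond covalent radii, Å.
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "K": 2.03, "Ca": 1.76, "Fe": 1.32, "Co": 1.26, "Ni": 1.24,
    "Cu": 1.32, "Zn": 1.22, "Se": 1.20, "Br": 1.20, "Ru": 1.46, "I": 1.39,
}

BOND_TOLERANCE = 0.40  # Å added to the radius sum
MAX_H_BOND = 1.30  # Å cap for any bond involving hydrogen
MIN_CONTACT = 0.50  # Å below which two sites are treated as overlapping

#: Alkyl/H substituent classes ordered by alpha-carbon branching.
ALKYL_RANK = {"H": 0, "methyl": 1, "primary_alkyl": 2,
              "secondary_alkyl": 3, "tertiary_alkyl": 4}

#: Atomic number of the alpha atom for each substituent class (specials
#: compare by this when the alkyl ordering does not apply).
ALPHA_ATOMIC_NUMBER = {
    "H": 1, "methyl": 6, "primary_alkyl": 6, "secondary_alkyl": 6,
    "tertiary_alkyl": 6, "aryl": 6, "phosphoryl_alkyl": 6, "selenoxo": 6,
    "thiocarbamoyl": 6, "nitrogen": 7, "oxygen": 8, "phosphorus": 15,
    "sulfonyl": 16, "sulfur": 16, "selenium": 34,
}

_ELEMENT_Z = {"H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15,
              "S": 16, "Cl": 17, "Se": 34, "Br": 35, "Ru": 44, "I": 53}


class GeometryError(ValueError):
    pass


class RoleMapError(ValueError):
    pass


class AmbiguousLateralizationError(RoleMapError):
    pass


@dataclass
class MtpaRoleMap:
    """Atom indices of one MTPA-amide moiety, in the survey's numbering.

    ``c1p`` (the sp-side alpha atom, C1' of the table) and ``x1pp`` (the
    ap-side alpha atom, X1'') are ``None`` until :func:`assign_sp_ap` runs;
    ``x1pp`` stays ``None`` when the ap substituent is the N–H hydrogen.
    """

    c1: int
    o1: int
    n: int
    c2: int
    c3: int
    f_all: tuple[int, int, int]
    o2: int
    c4: int
    c5: int
    ortho_pair: tuple[int, int]
    c1p: Optional[int] = None
    h1p: Optional[int] = None
    x1pp: Optional[int] = None
    lateralized: bool = False


def perceive_bonds(structure: CrystalStructure) -> nx.Graph:
    """Distance-based bond perception over Cartesian coordinates.

    Atoms i, j bond iff d(i,j) <= r_cov(i) + r_cov(j) + 0.40 Å, with bonds to
    hydrogen additionally capped at 1.3 Å.  Raises :class:`GeometryError` for
    overlapping sites (d < 0.5 Å).
    """
    pos = structure.cartesian()
    elements = structure.elements
    radii = np.array([COVALENT_RADII[e] for e in elements])
    n = len(elements)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    if n < 2:
        return graph
    dmat = squareform(pdist(pos))
    cutoff = radii[:, None] + radii[None, :] + BOND_TOLERANCE
    is_h = np.array([e == "H" for e in elements])
    cutoff = np.where(is_h[:, None] | is_h[None, :],
                      np.minimum(cutoff, MAX_H_BOND), cutoff)
    ii, jj = np.triu_indices(n, k=1)
    close = dmat[ii, jj] < MIN_CONTACT
    if close.any():
        k = int(np.argmax(close))
        a, b = structure.atoms[ii[k]].label, structure.atoms[jj[k]].label
        raise GeometryError(
            f"overlapping atoms {a} and {b} (d = {dmat[ii[k], jj[k]]:.2f} Å)")
    bonded = dmat[ii, jj] <= cutoff[ii, jj]
    graph.add_edges_from(zip(ii[bonded].tolist(), jj[bonded].tolist()))
    return graph


def _neighbors(bonds: nx.Graph, elements, idx: int, element: str) -> list[int]:
    return [j for j in bonds.neighbors(idx) if elements[j] == element]


def _find_six_carbon_ring(bonds: nx.Graph, elements, start: int) -> Optional[list[int]]:
    """Return a 6-membered all-carbon simple cycle through ``start``."""

    def dfs(path: list[int]) -> Optional[list[int]]:
        last = path[-1]
        for nxt in bonds.neighbors(last):
            if elements[nxt] != "C":
                continue
            if len(path) == 6:
                if nxt == start:
                    return path
                continue
            if nxt not in path:
                found = dfs(path + [nxt])
                if found:
                    return found
        return None

    return dfs([start])


def find_mtpa_moieties(structure: CrystalStructure,
                       bonds: nx.Graph) -> list[MtpaRoleMap]:
    """Every subgraph matching the MTPA-amide core, one role map each.

    Multi-arm molecules (bis-/tetrakis-amides) yield one map per arm.  The
    sp/ap lateralization of the N-substituents is left to
    :func:`assign_sp_ap`.
    """
    elements = structure.elements
    maps = []
    for c2 in range(len(elements)):
        if elements[c2] != "C" or bonds.degree(c2) != 4:
            continue
        nbrs = list(bonds.neighbors(c2))
        # CF3 carbon: a carbon neighbor bearing exactly three fluorines
        c3_candidates = [
            j for j in nbrs
            if elements[j] == "C"
            and len(_neighbors(bonds, elements, j, "F")) == 3
            and bonds.degree(j) == 4
        ]
        # methoxy oxygen: two-coordinate O whose other neighbor is a carbon
        o2_candidates = [
            j for j in nbrs
            if elements[j] == "O" and bonds.degree(j) == 2
        ]
        if len(c3_candidates) != 1 or len(o2_candidates) != 1:
            continue
        c3 = c3_candidates[0]
        o2 = o2_candidates[0]
        c4_list = [j for j in bonds.neighbors(o2) if j != c2]
        if len(c4_list) != 1 or elements[c4_list[0]] != "C":
            continue
        c4 = c4_list[0]
        rest = [j for j in nbrs if j not in (c3, o2) and elements[j] == "C"]
        if len(rest) != 2:
            continue
        c1 = c5 = o1 = n_idx = None
        ring = None
        for j in rest:
            o_term = [k for k in _neighbors(bonds, elements, j, "O")
                      if bonds.degree(k) == 1]
            n_amide = _neighbors(bonds, elements, j, "N")
            if len(o_term) == 1 and len(n_amide) == 1 and bonds.degree(j) == 3:
                c1, o1, n_idx = j, o_term[0], n_amide[0]
            else:
                r = _find_six_carbon_ring(bonds, elements, j)
                if r is not None:
                    c5, ring = j, r
        if c1 is None or c5 is None:
            continue
        ortho = tuple(sorted(j for j in bonds.neighbors(c5)
                             if j in ring and j != c5))
        if len(ortho) != 2:
            continue
        maps.append(
            MtpaRoleMap(
                c1=c1, o1=o1, n=n_idx, c2=c2, c3=c3,
                f_all=tuple(sorted(_neighbors(bonds, elements, c3, "F"))),
                o2=o2, c4=c4, c5=c5, ortho_pair=ortho,
            )
        )
    return maps


def assign_sp_ap(structure: CrystalStructure, bonds: nx.Graph,
                 rolemap: MtpaRoleMap) -> MtpaRoleMap:
    """Lateralize the two N-substituents into sp (C1') and ap (X1'') sides.

    The substituent whose X–N–C1–O1 torsion magnitude is <= 90° is the sp
    side; an ap-side hydrogen leaves ``x1pp`` as ``None``.  Near-boundary
    torsions (80–100°) are accepted with a logged warning; two substituents
    on the same side raise :class:`AmbiguousLateralizationError`.
    """
    pos = structure.cartesian()
    elements = structure.elements
    subs = [j for j in bonds.neighbors(rolemap.n) if j != rolemap.c1]
    if not 1 <= len(subs) <= 2:
        raise RoleMapError(
            f"amide N has {len(subs)} non-acyl substituents; expected 1 or 2")
    torsions = {
        j: torsion_angle(pos[j], pos[rolemap.n], pos[rolemap.c1],
                         pos[rolemap.o1])
        for j in subs
    }
    for j, t in torsions.items():
        if 80.0 <= abs(t) <= 100.0:
            log.warning(
                "near-boundary sp/ap torsion %.1f deg for atom %s",
                t, structure.atoms[j].label)
    sp = [j for j, t in torsions.items() if abs(t) <= 90.0]
    ap = [j for j, t in torsions.items() if abs(t) > 90.0]
    if len(subs) == 2 and (not sp or not ap):
        detail = ", ".join(
            f"{structure.atoms[j].label}: {t:+.1f} deg" for j, t in torsions.items())
        raise AmbiguousLateralizationError(
            f"both N-substituents on the same side of the amide plane ({detail})")
    if len(subs) == 1:
        # single heavy substituent with an implicit/absent N-H
        j = subs[0]
        sp, ap = ([j], []) if abs(torsions[j]) <= 90.0 else ([], [j])
    c1p = sp[0] if sp else None
    x1pp_atom = ap[0] if ap else None
    x1pp = None
    if x1pp_atom is not None and elements[x1pp_atom] != "H":
        x1pp = x1pp_atom
    h1p = None
    if c1p is not None and elements[c1p] != "H":
        h_on_c1p = _neighbors(bonds, elements, c1p, "H")
        if len(h_on_c1p) == 1:  # a methine hydrogen, the H1' of the survey
            h1p = h_on_c1p[0]
    return replace(rolemap, c1p=c1p, x1pp=x1pp, h1p=h1p, lateralized=True)


def n_hydrogen_count(structure: CrystalStructure, bonds: nx.Graph,
                     rolemap: MtpaRoleMap) -> int:
    elements = structure.elements
    return len(_neighbors(bonds, elements, rolemap.n, "H"))


def chirality_at_c2(structure: CrystalStructure, rolemap: MtpaRoleMap) -> str:
    """CIP descriptor (R or S) of the quaternary stereocenter C2.

    The priority order of the four substituents is fixed by the moiety
    itself: O2 > C3 (C(F,F,F)) > C1 (C(O,O,N)) > C5 (C(C,C,C)).  The
    descriptor follows from the sign of the scalar triple product of the
    bond vectors to the three highest priorities: negative determinant means
    the 1→2→3 sweep is clockwise viewed with C5 pointing away, i.e. R.
    """
    pos = structure.cartesian()
    for role in ("o2", "c3", "c1", "c5"):
        if getattr(rolemap, role) is None:
            raise RoleMapError(f"role {role} missing from role map")
    v1 = pos[rolemap.o2] - pos[rolemap.c2]
    v2 = pos[rolemap.c3] - pos[rolemap.c2]
    v3 = pos[rolemap.c1] - pos[rolemap.c2]
    det = float(np.dot(v1, np.cross(v2, v3)))
    if det == 0.0:
        raise RoleMapError("planar arrangement at C2; chirality undefined")
    return "R" if det < 0 else "S"


def substituent_class(structure: CrystalStructure, bonds: nx.Graph,
                      alpha_atom: Optional[int],
                      n_index: Optional[int] = None) -> str:
    """Classify an N-substituent by its alpha atom.

    ``None`` or a hydrogen index means the substituent is H.  Alpha carbons
    are ranked by heavy-neighbor count (excluding the amide N):
    0/1/2/3 → methyl/primary/secondary/tertiary alkyl, with carbons inside a
    six-membered carbocycle reported as ``aryl``.  Non-carbon alpha atoms map
    to an element-keyed special class.
    """
    elements = structure.elements
    if alpha_atom is None or elements[alpha_atom] == "H":
        return "H"
    el = elements[alpha_atom]
    if el != "C":
        return {"N": "nitrogen", "O": "oxygen", "P": "phosphorus",
                "S": "sulfonyl", "Se": "selenium"}.get(el, el.lower())
    if _find_six_carbon_ring(bonds, elements, alpha_atom) is not None:
        return "aryl"
    heavy = [j for j in bonds.neighbors(alpha_atom)
             if elements[j] != "H" and j != n_index]
    return {0: "methyl", 1: "primary_alkyl", 2: "secondary_alkyl"}.get(
        len(heavy), "tertiary_alkyl")


def classify_amide_form(rsp_class: str, rap_class: str) -> str:
    """Z / E / indeterminate from the two N-substituent classes.

    Z when the sp-side substituent outranks the ap side, E for the reverse.
    Within the alkyl series the rank is the branching order H < Me < primary
    < secondary < tertiary; classes outside that series compare by the
    atomic number of their alpha atom, and anything left unresolved (equal
    rank, or two carbon-alpha classes of which one is special) is
    ``indeterminate`` rather than guessed.
    """
    if rsp_class in ALKYL_RANK and rap_class in ALKYL_RANK:
        a, b = ALKYL_RANK[rsp_class], ALKYL_RANK[rap_class]
        return "Z" if a > b else ("E" if a < b else "indeterminate")
    za = ALPHA_ATOMIC_NUMBER.get(rsp_class)
    zb = ALPHA_ATOMIC_NUMBER.get(rap_class)
    if za is None or zb is None or za == zb:
        return "indeterminate"
    return "Z" if za > zb else "E"


def idealized_h_position(structure: CrystalStructure, bonds: nx.Graph,
                         c1p: int) -> np.ndarray:
    """Idealized methine H on a three-heavy-neighbor carbon, 1.09 Å.

    Used when the deposited structure omits riding hydrogens: the H is
    placed along the negative vector sum of the unit vectors to the three
    heavy neighbors.
    """
    pos = structure.cartesian()
    elements = structure.elements
    heavy = [j for j in bonds.neighbors(c1p) if elements[j] != "H"]
    if len(heavy) != 3:
        raise RoleMapError(
            f"cannot infer methine H: alpha carbon has {len(heavy)} heavy neighbors")
    vecs = [pos[j] - pos[c1p] for j in heavy]
    direction = -sum(v / np.linalg.norm(v) for v in vecs)
    norm = np.linalg.norm(direction)
    if norm < 1e-6:
        raise RoleMapError("degenerate (planar) alpha carbon; cannot place H")
    return pos[c1p] + 1.09 * direction / norm
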