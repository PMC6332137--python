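"""Build MTPA-amide 3-D structures from internal coordinates.

Atoms are placed sequentially by bond length, bond angle, and torsion from
three already-placed reference atoms, so every requested torsion target is
met exactly (closed-form, no optimization).  The builder constructs the
R-acid enantiomer; S is produced by mirroring the finished build, so an
S structure's raw torsions are the negatives of the targets.  Structures are
embedded as fractional coordinates in a 20 Å orthorhombic P1 box.

Five amine templates cover the substituent chemistry of the survey:

==================== =========================================== ===========
template             amine moiety                                 amide form
==================== =========================================== ===========
isopropylamine       primary amine, secondary alkyl (Mosher-type) Z
n_propylamine        primary amine, primary alkyl                 Z
pyrrolidine          cyclic secondary amine (2-methylpyrrolidine) Z
N_methyl_isopropyl   N-methyl secondary amine                     E
tetrakis_aryl        four aniline-type arms on a tetraphenyl-     Z (x4)
                     methane core
==================== =========================================== ===========
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .cif import AtomRecord, CrystalStructure
from .geometry import UnitCell, cartesian_to_fractional, wrap_angle

__all__ = ["TorsionSpec", "SpecError", "build_mtpa_amide", "perturb",
           "sample_survey", "TEMPLATES"]

TEMPLATES = ("isopropylamine", "n_propylamine", "pyrrolidine",
             "N_methyl_isopropyl", "tetrakis_aryl")

# bond lengths, Å
B_CC = 1.53
B_CO_DOUBLE = 1.23
B_CN_AMIDE = 1.34
B_CN_SINGLE = 1.47
B_CF = 1.34
B_CO_SINGLE = 1.42
B_CC_AROM = 1.39
B_CH = 1.09
B_NH = 1.01
B_C_AR = 1.51  # sp3 C to aromatic ipso

TET = 109.4712206  # tetrahedral angle
TRI = 120.0

# Torsion offsets of the methoxy O and phenyl ipso around the C1–C2 bond
# relative to the CF3 carbon; this pair of signs fixes the stereocenter as R
# (validated against the hand-built CIP reference tetrahedron).
_D_O2 = -120.0
_D_C5 = +120.0

_CONSENSUS = {"theta1": -13.0, "tau_f3": -174.0, "tau_sp": 2.0,
              "tau_ap": -174.0, "theta2": 21.0, "tau_ome": 54.0}

#: default methine torsion where the template has a single H on C1'
_TAU_H_DEFAULT = {"isopropylamine": -11.0, "pyrrolidine": -60.0}


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class TorsionSpec:
    """Torsion targets (degrees) for one synthetic MTPA amide.

    ``None`` fields fall back to the survey's consensus conformation.  A
    ``tau_h`` target on a template whose C1' has no single methine hydrogen
    is a :class:`SpecError`.
    """

    theta1: Optional[float] = None
    tau_f3: Optional[float] = None
    tau_sp: Optional[float] = None
    tau_ap: Optional[float] = None
    tau_h: Optional[float] = None
    theta2: Optional[float] = None
    tau_ome: Optional[float] = None
    chirality: str = "R"
    amine_template: str = "isopropylamine"
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chirality not in ("R", "S"):
            raise SpecError(f"chirality must be R or S, got {self.chirality!r}")
        if self.amine_template not in TEMPLATES:
            raise SpecError(f"unknown template {self.amine_template!r}")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be >= 0")
        for name in ("theta1", "tau_f3", "tau_sp", "tau_ap", "tau_h",
                     "theta2", "tau_ome"):
            v = getattr(self, name)
            if v is not None and not (-180.0 < v <= 180.0):
                raise SpecError(f"{name}={v} outside (-180, 180]")
        if self.tau_h is not None and self.amine_template not in _TAU_H_DEFAULT:
            raise SpecError(
                f"template {self.amine_template!r} has no single methine H; "
                "tau_h target is not applicable")

    def resolved(self) -> dict[str, Optional[float]]:
        out = {}
        for name, default in _CONSENSUS.items():
            v = getattr(self, name)
            out[name] = default if v is None else v
        th = self.tau_h
        if th is None:
            th = _TAU_H_DEFAULT.get(self.amine_template)
        out["tau_h"] = th
        return out


class _Mol:
    """Growing molecule; atoms addressed by label."""

    def __init__(self) -> None:
        self.labels: list[str] = []
        self.elements: list[str] = []
        self.pos: dict[str, np.ndarray] = {}

    def add(self, label: str, element: str, position) -> str:
        if label in self.pos:
            raise ValueError(f"duplicate label {label}")
        self.labels.append(label)
        self.elements.append(element)
        self.pos[label] = np.asarray(position, dtype=float)
        return label

    def place(self, label: str, element: str, a: str, b: str, c: str,
              r: float, angle: float, torsion: float) -> str:
        """NeRF placement: new atom bonded to ``c`` at distance ``r``, bond
        angle ``b–c–new`` = ``angle``, dihedral ``a–b–c–new`` = ``torsion``
        (IUPAC sign convention)."""
        pa, pb, pc = self.pos[a], self.pos[b], self.pos[c]
        th = np.radians(angle)
        ph = np.radians(torsion)
        bc = pc - pb
        bc = bc / np.linalg.norm(bc)
        ab = pb - pa
        n = np.cross(ab, bc)
        n = n / np.linalg.norm(n)
        m = np.cross(n, bc)
        d = r * (-np.cos(th) * bc
                 + np.sin(th) * np.cos(ph) * m
                 + np.sin(th) * np.sin(ph) * n)
        return self.add(label, element, pc + d)


def _decorate_c2(mol: _Mol, o1: str, c1: str, c2: str, t: dict,
                 p: str = "") -> None:
    """Place everything on the C2 side: CF3, methoxy, phenyl (+ ring H)."""
    c3 = mol.place(f"{p}C3", "C", o1, c1, c2, B_CC, TET, t["theta1"])
    mol.place(f"{p}O2", "O", o1, c1, c2, B_CO_SINGLE, TET,
              t["theta1"] + _D_O2)
    c5 = mol.place(f"{p}C5", "C", o1, c1, c2, B_C_AR, TET,
                   t["theta1"] + _D_C5)
    # CF3: the labelled F3 hits the tau_f3 target, the others trail at ±120
    mol.place(f"{p}F3", "F", c1, c2, c3, B_CF, TET, t["tau_f3"])
    mol.place(f"{p}F1", "F", c1, c2, c3, B_CF, TET, t["tau_f3"] + 120.0)
    mol.place(f"{p}F2", "F", c1, c2, c3, B_CF, TET, t["tau_f3"] - 120.0)
    mol.place(f"{p}C4", "C", c1, c2, f"{p}O2", B_CO_SINGLE, 111.0,
              t["tau_ome"])
    for i, tau in (("A", 60.0), ("B", 180.0), ("C", -60.0)):
        mol.place(f"{p}H4{i}", "H", c2, f"{p}O2", f"{p}C4", B_CH, TET, tau)
    # phenyl: C10 is the ortho carbon meeting the theta2 target
    c10 = mol.place(f"{p}C10", "C", f"{p}O2", c2, c5, B_CC_AROM, TRI,
                    t["theta2"])
    c6 = mol.place(f"{p}C6", "C", f"{p}O2", c2, c5, B_CC_AROM, TRI,
                   t["theta2"] + 180.0)
    c7 = mol.place(f"{p}C7", "C", c2, c5, c6, B_CC_AROM, TRI, 180.0)
    c8 = mol.place(f"{p}C8", "C", c5, c6, c7, B_CC_AROM, TRI, 0.0)
    c9 = mol.place(f"{p}C9", "C", c6, c7, c8, B_CC_AROM, TRI, 0.0)
    ring = [c5, c6, c7, c8, c9, c10]
    for i, atom in enumerate(ring):
        if atom == c5:
            continue
        prev_, next_ = ring[i - 1], ring[(i + 1) % 6]
        u = mol.pos[prev_] - mol.pos[atom]
        v = mol.pos[next_] - mol.pos[atom]
        d = -(u / np.linalg.norm(u) + v / np.linalg.norm(v))
        mol.add(f"{p}H{atom[len(p):]}", "H",
                mol.pos[atom] + B_CH * d / np.linalg.norm(d))


def _methyl(mol: _Mol, prefix: str, a: str, b: str, c: str) -> None:
    for i, tau in ((1, 60.0), (2, 180.0), (3, -60.0)):
        mol.place(f"{prefix}{i}", "H", a, b, c, B_CH, TET, tau)


def _build_amine(mol: _Mol, template: str, t: dict) -> None:
    """Place the N-substituents of a core-first build (N already exists)."""
    o1, c1, n = "O1", "C1", "N1"
    if template in ("isopropylamine", "n_propylamine"):
        c1p = mol.place("C11", "C", o1, c1, n, B_CN_SINGLE, 121.0, t["tau_sp"])
        mol.place("H1N", "H", o1, c1, n, B_NH, 119.0, t["tau_ap"])
        if template == "isopropylamine":
            tau_h = t["tau_h"]
            mol.place("H11", "H", c1, n, c1p, B_CH, TET, tau_h)
            cm1 = mol.place("C12", "C", c1, n, c1p, B_CC, TET, tau_h + 120.0)
            cm2 = mol.place("C13", "C", c1, n, c1p, B_CC, TET, tau_h - 120.0)
            _methyl(mol, "H12", n, c1p, cm1)
            _methyl(mol, "H13", n, c1p, cm2)
        else:
            c2p = mol.place("C12", "C", c1, n, c1p, B_CC, TET, 180.0)
            mol.place("H11", "H", c1, n, c1p, B_CH, TET, 60.0)
            mol.place("H12", "H", c1, n, c1p, B_CH, TET, -60.0)
            c3p = mol.place("C13", "C", n, c1p, c2p, B_CC, TET, 180.0)
            mol.place("H21", "H", n, c1p, c2p, B_CH, TET, 60.0)
            mol.place("H22", "H", n, c1p, c2p, B_CH, TET, -60.0)
            _methyl(mol, "H3", c1p, c2p, c3p)
    elif template == "pyrrolidine":
        # 2-methylpyrrolidine: the sp-side ring carbon carries the methyl
        ca = mol.place("C11", "C", o1, c1, n, B_CN_SINGLE, 121.0, t["tau_sp"])
        cd = mol.place("C14", "C", o1, c1, n, B_CN_SINGLE, 121.0, t["tau_ap"])
        cb = mol.place("C12", "C", c1, n, ca, B_CC, 104.0, 180.0)
        cc = mol.place("C13", "C", c1, n, cd, B_CC, 104.0, 180.0)
        tau_h = t["tau_h"] if t["tau_h"] is not None else -60.0
        # the third and fourth slots around Ca (ring Cb sits near 180)
        me_tau = tau_h + 120.0 if wrap_angle(tau_h + 120.0) * tau_h < 0 \
            else tau_h - 120.0
        mol.place("H11", "H", c1, n, ca, B_CH, 110.0, tau_h)
        cme = mol.place("C15", "C", c1, n, ca, B_CC, 110.0, me_tau)
        _methyl(mol, "H5", n, ca, cme)
        mol.place("H41", "H", c1, n, cd, B_CH, 110.0, 65.0)
        mol.place("H42", "H", c1, n, cd, B_CH, 110.0, -65.0)
        for cx, ref in ((cb, ca), (cc, cd)):
            u = mol.pos[n] - mol.pos[ref]
            for i, tau in ((1, 115.0), (2, -115.0)):
                mol.place(f"H{cx[1:]}{i}", "H", n, ref, cx, B_CH, 110.0, tau)
    elif template == "N_methyl_isopropyl":
        cme = mol.place("C11", "C", o1, c1, n, B_CN_SINGLE, 121.0, t["tau_sp"])
        cip = mol.place("C12", "C", o1, c1, n, B_CN_SINGLE, 121.0, t["tau_ap"])
        _methyl(mol, "H1", c1, n, cme)
        # methine H eclipses the acyl side; methyls point away from the core
        mol.place("H21", "H", c1, n, cip, B_CH, TET, 0.0)
        cm1 = mol.place("C13", "C", c1, n, cip, B_CC, TET, 120.0)
        cm2 = mol.place("C14", "C", c1, n, cip, B_CC, TET, -120.0)
        _methyl(mol, "H3", n, cip, cm1)
        _methyl(mol, "H4", n, cip, cm2)
    else:  # pragma: no cover - guarded by TorsionSpec
        raise SpecError(f"unknown template {template!r}")


def _build_core_first(template: str, t: dict) -> _Mol:
    mol = _Mol()
    c2 = mol.add("C2", "C", (0.0, 0.0, 0.0))
    c1 = mol.add("C1", "C", (B_CC, 0.0, 0.0))
    ang = np.radians(121.0)
    o1 = mol.add("O1", "O",
                 (B_CC - B_CO_DOUBLE * np.cos(ang),
                  -B_CO_DOUBLE * np.sin(ang), 0.0))
    mol.place("N1", "N", o1, c2, c1, B_CN_AMIDE, 117.0, 180.0)
    _build_amine(mol, template, t)
    _decorate_c2(mol, o1, c1, c2, t)
    return mol


_TETRAHEDRAL_DIRS = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3.0)


def _build_tetrakis(t: dict) -> _Mol:
    mol = _Mol()
    mol.add("C0", "C", (0.0, 0.0, 0.0))
    ipso = [mol.add(f"A{k}_Ci", "C", B_C_AR * _TETRAHEDRAL_DIRS[k])
            for k in range(4)]
    for k in range(4):
        p = f"A{k}_"
        ci = ipso[k]
        ref = ipso[(k + 1) % 4]  # any other arm fixes the ring plane
        co1 = mol.place(f"{p}Co1", "C", ref, "C0", ci, B_CC_AROM, TRI, 0.0)
        co2 = mol.place(f"{p}Co2", "C", ref, "C0", ci, B_CC_AROM, TRI, 180.0)
        cm1 = mol.place(f"{p}Cm1", "C", "C0", ci, co1, B_CC_AROM, TRI, 180.0)
        cm2 = mol.place(f"{p}Cm2", "C", "C0", ci, co2, B_CC_AROM, TRI, 180.0)
        cp = mol.place(f"{p}Cp", "C", ci, co1, cm1, B_CC_AROM, TRI, 0.0)
        for ring_c, u, v in ((co1, ci, cm1), (co2, ci, cm2),
                             (cm1, co1, cp), (cm2, co2, cp)):
            du = mol.pos[u] - mol.pos[ring_c]
            dv = mol.pos[v] - mol.pos[ring_c]
            d = -(du / np.linalg.norm(du) + dv / np.linalg.norm(dv))
            mol.add(f"H{ring_c}", "H",
                    mol.pos[ring_c] + B_CH * d / np.linalg.norm(d))
        n = mol.place(f"{p}N1", "N", co1, cm1, cp, 1.40, TRI, 180.0)
        c1 = mol.place(f"{p}C1", "C", cm1, cp, n, B_CN_AMIDE, 125.0, 150.0)
        o1 = mol.place(f"{p}O1", "O", cp, n, c1, B_CO_DOUBLE, 121.0,
                       t["tau_sp"])
        mol.place(f"{p}H1N", "H", o1, c1, n, B_NH, 118.0, t["tau_ap"])
        c2 = mol.place(f"{p}C2", "C", cp, n, c1, B_CC, 117.0,
                       t["tau_sp"] + 180.0)
        _decorate_c2(mol, o1, c1, c2, t, p=p)
    return mol


def build_mtpa_amide(spec: TorsionSpec) -> CrystalStructure:
    """Build one (or, for the tetrakis template, a four-arm) MTPA amide.

    Every resolved torsion target is met exactly before noise; S chirality
    mirrors the finished R build through the origin, so the raw torsions of
    an S structure are the negatives of the targets.
    """
    t = spec.resolved()
    if spec.amine_template == "tetrakis_aryl":
        mol = _build_tetrakis(t)
    else:
        mol = _build_core_first(spec.amine_template, t)
    coords = np.array([mol.pos[lab] for lab in mol.labels])
    if spec.chirality == "S":
        coords = -coords
    cell = UnitCell(20.0, 20.0, 20.0)
    coords = coords - coords.mean(axis=0) + 10.0
    frac = cartesian_to_fractional(cell, coords)
    atoms = [AtomRecord(lab, el, frac[i])
             for i, (lab, el) in enumerate(zip(mol.labels, mol.elements))]
    ident = f"synth_{spec.amine_template}_{spec.chirality}"
    structure = CrystalStructure(ident, cell, atoms)
    if spec.noise_sigma > 0:
        structure = perturb(structure, spec.noise_sigma, spec.seed)
    return structure


def perturb(structure: CrystalStructure, noise_sigma: float,
            seed: int) -> CrystalStructure:
    """Isotropic Gaussian displacement per atom; deterministic per seed.

    ``noise_sigma`` is the root-mean-square magnitude (Å) of each atom's
    displacement vector, so every Cartesian component is drawn with standard
    deviation ``noise_sigma / sqrt(3)``.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return structure
    rng = np.random.default_rng(seed)
    cart = structure.cartesian() + rng.normal(
        0.0, noise_sigma / np.sqrt(3.0), (len(structure.atoms), 3))
    frac = cartesian_to_fractional(structure.cell, cart)
    atoms = [replace(a, position=frac[i])
             for i, a in enumerate(structure.atoms)]
    return CrystalStructure(structure.identifier, structure.cell, atoms)


#: sampling defaults: consensus means with survey-like spreads (degrees)
SURVEY_DISTRIBUTION = {
    "theta1": (-13.0, 8.0),
    "tau_f3": (-174.0, 6.0),
    "tau_sp": (2.0, 5.0),
    "tau_ap": (-174.0, 6.0),
    "tau_h": (-11.0, 20.0),
    "theta2": (21.0, 10.0),
    "tau_ome": (54.0, 8.0),
}


def sample_survey(
    n: int,
    distribution: Optional[dict[str, tuple[float, float]]] = None,
    seed: int = 0,
    template: str = "isopropylamine",
    chirality_p_s: float = 0.5,
    noise_sigma: float = 0.0,
) -> list[CrystalStructure]:
    """Draw ``n`` synthetic moieties with wrapped-normal torsion targets.

    Each descriptor target is drawn from a normal distribution (mean, sd per
    ``distribution``, defaulting to the survey consensus) and wrapped onto
    (−180, 180]; chirality is Bernoulli(``chirality_p_s``) for S.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dist = {**SURVEY_DISTRIBUTION, **(distribution or {})}
    rng = np.random.default_rng(seed)
    structures = []
    for i in range(n):
        targets = {name: wrap_angle(rng.normal(mu, sd))
                   for name, (mu, sd) in dist.items()}
        if template not in _TAU_H_DEFAULT:
            targets.pop("tau_h", None)
        chirality = "S" if rng.random() < chirality_p_s else "R"
        spec = TorsionSpec(**targets, chirality=chirality,
                           amine_template=template,
                           noise_sigma=noise_sigma,
                           seed=int(rng.integers(0, 2**31 - 1)))
        structure = build_mtpa_amide(spec)
        structure.identifier = f"{structure.identifier}_{i}"
        structures.append(structure)
    return structures
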