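"""Core-CIF structure I/O (via gemmi) and the packaged torsion-survey table.

The survey table ships with the package as a TSV, one row per MTPA-amide
moiety (58 rows): multiple conformers in one lattice and multiple MTPA arms
on one molecule are separate rows.  Null entries are marked with an en dash,
and printed standard uncertainties like ``-13.1(2)`` are split into value and
su on load.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import IO, Iterable, Optional

import gemmi
import numpy as np

from .geometry import UnitCell, fractional_to_cartesian, wrap_angle

log = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "CrystalStructure",
    "Table1Row",
    "CifParseError",
    "FixtureIntegrityError",
    "read_cif",
    "write_cif",
    "load_table1",
    "packaged_table1_path",
    "TORSION_FIELDS",
]

#: The seven torsion descriptors, keyed by code name, with their atom paths.
TORSION_FIELDS = {
    "theta1": "O1-C1-C2-C3",
    "tau_f3": "C1-C2-C3-F3",
    "tau_sp": "C1'-N-C1-O1",
    "tau_ap": "X1''-N-C1-O1",
    "tau_h": "H1'-C1'-N-C1",
    "theta2": "O2-C2-C5-C10",
    "tau_ome": "C1-C2-O2-C4",
}

_ELEMENTS = {
    "H", "B", "C", "N", "O", "F", "Na", "Mg", "Al", "Si", "P", "S", "Cl",
    "K", "Ca", "Fe", "Co", "Ni", "Cu", "Zn", "Se", "Br", "Ru", "I",
}


class CifParseError(ValueError):
    pass


class FixtureIntegrityError(ValueError):
    pass


@dataclass
class AtomRecord:
    """One atom site: fractional coordinates when the structure has a cell."""

    label: str
    element: str
    position: np.ndarray
    su: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("atom label must be non-empty")
        if self.element not in _ELEMENTS:
            raise ValueError(f"unrecognized element symbol {self.element!r}")
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class CrystalStructure:
    identifier: str
    cell: Optional[UnitCell]
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"structure {self.identifier!r} has no atoms")
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate atom labels in {self.identifier!r}")

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def cartesian(self) -> np.ndarray:
        """Atom positions in Å, orthogonalized if a cell is present."""
        pos = np.array([a.position for a in self.atoms])
        if self.cell is None:
            return pos
        return fractional_to_cartesian(self.cell, pos)


_NUM_SU = re.compile(r"([-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)(?:\((\d+)\))?")


def parse_numeric_su(token: str) -> tuple[float, Optional[float]]:
    """Parse a CIF numeric like ``0.1234(5)`` into (value, su).

    The su applies to the last printed decimal place: ``0.1234(5)`` → su
    0.0005, ``169(4)`` → su 4.
    """
    m = _NUM_SU.fullmatch(token.strip())
    if not m:
        raise CifParseError(f"malformed numeric value {token!r}")
    value = float(m.group(1))
    su = None
    if m.group(2) is not None:
        mantissa = m.group(1)
        decimals = len(mantissa.split(".")[1]) if "." in mantissa else 0
        su = int(m.group(2)) * 10.0 ** (-decimals)
    return value, su


def _read_text(source) -> str:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        return Path(source).read_text(encoding="utf-8")
    if hasattr(source, "read"):
        return source.read()
    return str(source)


def read_cif(source: str | Path | IO[str]) -> list[CrystalStructure]:
    """Read core-CIF text (path, string, or stream) into structures.

    Each data block with an atom-site loop becomes one structure.  Cell
    parameters and ``_atom_site_fract_*`` coordinates are captured; standard
    uncertainties are split off into :attr:`AtomRecord.su`.
    """
    text = _read_text(source)
    doc = gemmi.cif.read_string(text)
    structures = []
    for block in doc:
        cell = None
        cell_vals = {}
        for tag in ("a", "b", "c"):
            v = block.find_value(f"_cell_length_{tag}")
            if v is not None:
                cell_vals[tag] = parse_numeric_su(v)[0]
        for tag in ("alpha", "beta", "gamma"):
            v = block.find_value(f"_cell_angle_{tag}")
            if v is not None:
                cell_vals[tag] = parse_numeric_su(v)[0]
        if {"a", "b", "c"} <= set(cell_vals):
            cell = UnitCell(**{**{"alpha": 90.0, "beta": 90.0, "gamma": 90.0}, **cell_vals})

        table = block.find(
            "_atom_site_",
            ["label", "type_symbol", "fract_x", "fract_y", "fract_z"],
        )
        if len(table) == 0:
            raise CifParseError(
                f"data block {block.name!r} has no _atom_site_ loop with "
                "fractional coordinates"
            )
        if cell is None:
            raise CifParseError(
                f"data block {block.name!r} has fractional coordinates but no cell"
            )
        atoms = []
        for row in table:
            label = gemmi.cif.as_string(row[0])
            element = gemmi.cif.as_string(row[1])
            vals, sus = [], []
            for i in (2, 3, 4):
                try:
                    v, s = parse_numeric_su(row[i])
                except CifParseError as err:
                    raise CifParseError(f"atom {label!r}: {err}") from None
                vals.append(v)
                sus.append(s)
            su = None
            if any(s is not None for s in sus):
                su = np.array([s if s is not None else 0.0 for s in sus])
            atoms.append(AtomRecord(label, element, np.array(vals), su))
        structures.append(CrystalStructure(block.name, cell, atoms))
    if not structures:
        raise CifParseError("no data blocks found")
    return structures


def write_cif(structure: CrystalStructure) -> str:
    """Emit one structure as a core-CIF data block (fractional coordinates)."""
    out = StringIO()
    name = re.sub(r"\s+", "_", structure.identifier) or "structure"
    out.write(f"data_{name}\n")
    if structure.cell is not None:
        c = structure.cell
        out.write(f"_cell_length_a    {c.a:.6f}\n")
        out.write(f"_cell_length_b    {c.b:.6f}\n")
        out.write(f"_cell_length_c    {c.c:.6f}\n")
        out.write(f"_cell_angle_alpha {c.alpha:.6f}\n")
        out.write(f"_cell_angle_beta  {c.beta:.6f}\n")
        out.write(f"_cell_angle_gamma {c.gamma:.6f}\n")
    out.write("loop_\n")
    for tag in ("label", "type_symbol", "fract_x", "fract_y", "fract_z"):
        out.write(f"_atom_site_{tag}\n")
    for atom in structure.atoms:
        x, y, z = atom.position
        out.write(f"{atom.label} {atom.element} {x:.6f} {y:.6f} {z:.6f}\n")
    return out.getvalue()


# --- survey fixture -------------------------------------------------------

AMINE_CLASSES = {
    "Primary amine": "primary_amine",
    "Secondary amine": "secondary_amine",
    "Aniline derivative": "aniline_derivative",
    "Benzotriazole": "benzotriazole",
    "Diethyl 1-aminoalkylphosphonate derivative": "phosphonate_derivative",
    "Oxazolidine-2-selone derivative": "selone_derivative",
    "Thiocarbamide derivative": "thiocarbamide_derivative",
    "p-Toluenesulfonamide derivative": "sulfonamide_derivative",
}

SUBSTITUENT_CLASSES = {
    "H": "H",
    "Me": "methyl",
    "Primary alkyl group": "primary_alkyl",
    "Secondary alkyl group": "secondary_alkyl",
    "Tertiary alkyl group": "tertiary_alkyl",
    "ortho-Substituted phenyl group": "aryl",
    "N": "nitrogen",
    "1-(Diethoxyphosphoryl)alkyl group": "phosphoryl_alkyl",
    "Selenoxo group": "selenoxo",
    "N-Substituted thiocarbamoyl group": "thiocarbamoyl",
    "p-Toluenesulfonyl group": "sulfonyl",
}

_NULL_MARKERS = {"–", "-", "—", ""}
_FLAG_LETTERS = set("defghij")


@dataclass(frozen=True)
class Table1Row:
    """One moiety of the packaged survey table.

    Torsions are the printed (as-deposited) values in degrees, i.e. not yet
    mirror-normalized: S-acid rows keep their original signs.
    """

    row_no: int
    ccdc: str
    chirality: str  # R | S as printed
    amine_class: str
    rsp_class: str
    rap_class: str
    theta1: Optional[float]
    tau_f3: Optional[float]
    tau_sp: Optional[float]
    tau_ap: Optional[float]
    tau_h: Optional[float]
    theta2: Optional[float]
    tau_ome: Optional[float]
    su: dict = field(default_factory=dict)
    footnote_flags: frozenset = frozenset()

    def torsions(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in TORSION_FIELDS}

    @property
    def amide_arity(self) -> str:
        """'secondary' when the ap substituent is the N–H hydrogen."""
        return "secondary" if self.rap_class == "H" else "tertiary"


def _clean_cell(raw: str) -> str:
    # unify the unicode minus variants that PDF extraction produces
    return raw.strip().replace("−", "-").replace("‐", "-")


def _parse_torsion(raw: str, where: str) -> tuple[Optional[float], Optional[float]]:
    cell = _clean_cell(raw)
    if cell in _NULL_MARKERS:
        return None, None
    value, su = parse_numeric_su(cell)
    if not (-180.0 < value <= 180.0):
        raise FixtureIntegrityError(f"{where}: torsion {value} outside (-180, 180]")
    return value, su


def packaged_table1_path() -> Path:
    return Path(resources.files("mtpaconf") / "data" / "table1.tsv")


def load_table1(source: str | Path | IO[str] | None = None) -> list[Table1Row]:
    """Load the packaged 58-row survey table (or a user-supplied copy).

    Raises :class:`FixtureIntegrityError` if the row count is not 58, a
    torsion falls outside (−180, 180], or a footnote flag contradicts the
    row's printed classification.
    """
    if source is None:
        source = packaged_table1_path()
    text = _read_text(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    expected = ["no", "ccdc", "chirality", "amine_class", "rsp", "rap",
                *TORSION_FIELDS, "flags"]
    if header != expected:
        raise FixtureIntegrityError(f"unexpected fixture header {header}")
    rows = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) == len(expected) - 1:
            parts.append("")  # trailing flags column may be empty
        rec = dict(zip(expected, parts))
        row_no = int(rec["no"])
        where = f"fixture row {row_no}"
        torsions, sus = {}, {}
        for name in TORSION_FIELDS:
            torsions[name], sus[name] = _parse_torsion(rec[name], f"{where} {name}")
        flags = frozenset(f for f in _clean_cell(rec["flags"]).split(",") if f)
        if not flags <= _FLAG_LETTERS:
            raise FixtureIntegrityError(f"{where}: unknown flags {flags}")
        chirality = rec["chirality"].strip()
        if chirality not in ("R", "S"):
            raise FixtureIntegrityError(f"{where}: chirality {chirality!r}")
        try:
            amine_class = AMINE_CLASSES[rec["amine_class"].strip()]
            rsp_class = SUBSTITUENT_CLASSES[_clean_cell(rec["rsp"])]
            rap_class = SUBSTITUENT_CLASSES[_clean_cell(rec["rap"])]
        except KeyError as err:
            raise FixtureIntegrityError(f"{where}: unknown class {err}") from None
        if "d" in flags and amine_class != "primary_amine":
            raise FixtureIntegrityError(f"{where}: flag d on non-primary-amine row")
        if "h" in flags and rsp_class != "methyl":
            raise FixtureIntegrityError(f"{where}: flag h on non-methyl row")
        rows.append(
            Table1Row(
                row_no=row_no,
                ccdc=rec["ccdc"].strip(),
                chirality=chirality,
                amine_class=amine_class,
                rsp_class=rsp_class,
                rap_class=rap_class,
                su={k: v for k, v in sus.items() if v is not None},
                footnote_flags=flags,
                **torsions,
            )
        )
    if len(rows) != 58:
        raise FixtureIntegrityError(f"expected 58 rows, found {len(rows)}")
    if [r.row_no for r in rows] != list(range(1, 59)):
        raise FixtureIntegrityError("row numbers are not 1..58 in order")
    return rows
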