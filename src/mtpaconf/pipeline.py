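"""End-to-end driver: crystal structure(s) → classified moiety records.

Each MTPA-amide moiety found in a structure becomes one record (bis- and
tetrakis-amides and multiple conformers per lattice expand to several), with
its raw and R-normalized descriptors and its conformer classification.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Optional

from .cif import CrystalStructure, read_cif
from .descriptors import (
    ConformerClass,
    TorsionSet,
    classify_conformer,
    compute_torsion_set,
    normalize_to_R,
)
from .perception import (
    MtpaRoleMap,
    assign_sp_ap,
    find_mtpa_moieties,
    n_hydrogen_count,
    perceive_bonds,
    substituent_class,
)

__all__ = ["MoietyRecord", "analyze_structure", "analyze_cif"]


@dataclass
class MoietyRecord:
    structure_id: str
    moiety_index: int
    rolemap: MtpaRoleMap
    raw: TorsionSet
    normalized: TorsionSet
    rsp_class: str
    rap_class: str
    amide_arity: str
    conformer: ConformerClass

    @property
    def chirality(self) -> str:
        """Measured (as-crystallized) descriptor of the acid stereocenter."""
        return self.raw.chirality

    def to_dict(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "moiety_index": self.moiety_index,
            "chirality": self.chirality,
            "rsp_class": self.rsp_class,
            "rap_class": self.rap_class,
            "amide_arity": self.amide_arity,
            "raw": self.raw.torsions(),
            "normalized": self.normalized.torsions(),
            "tau_h_inferred": self.raw.tau_h_inferred,
            "conformer": {
                "theta1_window": self.conformer.theta1_window,
                "cf3_staggered": self.conformer.cf3_staggered,
                "amide_form": self.conformer.amide_form,
                "mosher_type": self.conformer.mosher_type,
                "carbonyl_methoxy": self.conformer.carbonyl_methoxy,
            },
        }


def analyze_structure(structure: CrystalStructure,
                      infer_missing_h: bool = True) -> list[MoietyRecord]:
    """Perceive, lateralize, measure and classify every moiety in one structure."""
    bonds = perceive_bonds(structure)
    records = []
    for i, rolemap in enumerate(find_mtpa_moieties(structure, bonds)):
        rolemap = assign_sp_ap(structure, bonds, rolemap)
        raw = compute_torsion_set(structure, rolemap, bonds=bonds,
                                  infer_missing_h=infer_missing_h)
        normalized = normalize_to_R(raw)
        rsp = substituent_class(structure, bonds, rolemap.c1p, rolemap.n)
        rap = substituent_class(structure, bonds, rolemap.x1pp, rolemap.n)
        arity = "secondary" if n_hydrogen_count(structure, bonds, rolemap) >= 1 \
            else "tertiary"
        conformer = classify_conformer(normalized, rsp, rap, arity)
        records.append(MoietyRecord(
            structure_id=structure.identifier, moiety_index=i,
            rolemap=rolemap, raw=raw, normalized=normalized,
            rsp_class=rsp, rap_class=rap, amide_arity=arity,
            conformer=conformer))
    return records


def analyze_cif(source: str | Path | IO[str]) -> list[MoietyRecord]:
    """Analyze every data block of a CIF file/stream."""
    records = []
    for structure in read_cif(source):
        records.extend(analyze_structure(structure))
    return records
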