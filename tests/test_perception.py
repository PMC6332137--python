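import logging

import numpy as np
import pytest

from mtpaconf.cif import AtomRecord, CrystalStructure
from mtpaconf.perception import (
    AmbiguousLateralizationError,
    GeometryError,
    MtpaRoleMap,
    assign_sp_ap,
    chirality_at_c2,
    classify_amide_form,
    find_mtpa_moieties,
    n_hydrogen_count,
    perceive_bonds,
    substituent_class,
)
from mtpaconf.pipeline import analyze_structure
from mtpaconf.synth import TorsionSpec, build_mtpa_amide


def _cartesian_structure(atoms):
    return CrystalStructure("test", None,
                            [AtomRecord(lab, el, pos) for lab, el, pos in atoms])


class TestPerceiveBonds:
    def test_carbon_pair_distance_rule(self):
        bonded = _cartesian_structure(
            [("C1", "C", (0, 0, 0)), ("C2", "C", (1.54, 0, 0))])
        apart = _cartesian_structure(
            [("C1", "C", (0, 0, 0)), ("C2", "C", (2.50, 0, 0))])
        assert perceive_bonds(bonded).has_edge(0, 1)
        assert not perceive_bonds(apart).has_edge(0, 1)

    def test_h_bond_capped(self):
        # r_cov sum + 0.40 would allow 1.47 Å, but H bonds cap at 1.3 Å
        s = _cartesian_structure(
            [("C1", "C", (0, 0, 0)), ("H1", "H", (1.4, 0, 0))])
        assert not perceive_bonds(s).has_edge(0, 1)

    def test_no_self_bonds_and_overlap_error(self):
        s = _cartesian_structure(
            [("C1", "C", (0, 0, 0)), ("C2", "C", (1.5, 0, 0))])
        g = perceive_bonds(s)
        assert not any(a == b for a, b in g.edges)
        clash = _cartesian_structure(
            [("C1", "C", (0, 0, 0)), ("C2", "C", (0.3, 0, 0))])
        with pytest.raises(GeometryError, match="overlap"):
            perceive_bonds(clash)

    def test_generator_structure_degrees(self, mosher_structure):
        bonds = perceive_bonds(mosher_structure)
        (rolemap,) = find_mtpa_moieties(mosher_structure, bonds)
        assert bonds.degree(rolemap.c2) == 4
        assert bonds.degree(rolemap.c3) == 4  # C2 + three F


class TestFindMoieties:
    def test_mono_amide_yields_one_map(self, mosher_structure):
        bonds = perceive_bonds(mosher_structure)
        maps = find_mtpa_moieties(mosher_structure, bonds)
        assert len(maps) == 1

    def test_tetrakis_template_yields_four_maps(self):
        s = build_mtpa_amide(TorsionSpec(amine_template="tetrakis_aryl"))
        maps = find_mtpa_moieties(s, perceive_bonds(s))
        assert len(maps) == 4

    def test_benzene_yields_nothing(self):
        ring = []
        for i in range(6):
            ang = np.radians(60 * i)
            ring.append((f"C{i+1}", "C",
                         (1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0)))
        s = _cartesian_structure(ring)
        assert find_mtpa_moieties(s, perceive_bonds(s)) == []

    def test_role_map_invariants_hold_on_generator_output(self):
        for template in ("isopropylamine", "pyrrolidine", "N_methyl_isopropyl"):
            s = build_mtpa_amide(TorsionSpec(amine_template=template))
            bonds = perceive_bonds(s)
            (m,) = find_mtpa_moieties(s, bonds)
            els = s.elements
            assert set(bonds.neighbors(m.c2)) == {m.c1, m.c3, m.o2, m.c5}
            assert sorted(m.f_all) == sorted(
                j for j in bonds.neighbors(m.c3) if els[j] == "F")
            assert set(bonds.neighbors(m.o2)) == {m.c2, m.c4}
            assert {m.o1, m.n, m.c2} <= set(bonds.neighbors(m.c1))


class TestLateralization:
    def test_sp_is_the_small_torsion_side(self, mosher_record):
        m = mosher_record.rolemap
        assert m.lateralized
        assert m.c1p is not None and m.x1pp is None  # ap side is the N-H

    def test_tertiary_amide_gets_both_sides(self):
        s = build_mtpa_amide(TorsionSpec(amine_template="pyrrolidine",
                                         tau_sp=3.0, tau_ap=-176.0))
        (rec,) = analyze_structure(s)
        assert rec.rolemap.x1pp is not None
        assert rec.raw.tau_ap == pytest.approx(-176.0, abs=0.5)

    def test_near_boundary_assignment_warns(self, caplog):
        s = build_mtpa_amide(TorsionSpec(amine_template="pyrrolidine",
                                         tau_sp=89.0, tau_ap=-91.0))
        bonds = perceive_bonds(s)
        (m,) = find_mtpa_moieties(s, bonds)
        with caplog.at_level(logging.WARNING, logger="mtpaconf.perception"):
            m = assign_sp_ap(s, bonds, m)
        assert m.lateralized
        assert "near-boundary" in caplog.text

    def test_same_side_substituents_are_ambiguous(self):
        # hand-built strongly pyramidal N: both substituents within |90°|
        import networkx as nx
        from mtpaconf.synth import _Mol
        m = _Mol()
        m.add("C1", "C", (0, 0, 0))
        m.add("O1", "O", (-0.6, 1.07, 0))
        m.add("N1", "N", (1.34, 0, 0))
        m.place("CA", "C", "O1", "C1", "N1", 1.47, 115.0, 30.0)
        m.place("CB", "C", "O1", "C1", "N1", 1.47, 115.0, 60.0)
        s = _cartesian_structure(
            [(lab, el, m.pos[lab]) for lab, el in zip(m.labels, m.elements)])
        bonds = nx.Graph([(0, 1), (0, 2), (2, 3), (2, 4)])
        rolemap = MtpaRoleMap(c1=0, o1=1, n=2, c2=0, c3=0, f_all=(0, 0, 0),
                              o2=0, c4=0, c5=0, ortho_pair=(0, 0))
        with pytest.raises(AmbiguousLateralizationError, match="deg"):
            assign_sp_ap(s, bonds, rolemap)


def _tetrahedron(o2, c3, c1, c5):
    s = _cartesian_structure([
        ("C2", "C", (0, 0, 0)), ("O2", "O", o2), ("C3", "C", c3),
        ("C1", "C", c1), ("C5", "C", c5),
    ])
    # atom order: 0 C2, 1 O2, 2 C3, 3 C1, 4 C5; unused roles point at C2
    rolemap = MtpaRoleMap(c1=3, o1=0, n=0, c2=0, c3=2, f_all=(0, 0, 0),
                          o2=1, c4=0, c5=4, ortho_pair=(0, 0))
    return s, rolemap


class TestChirality:
    def test_hand_built_clockwise_reference_is_R(self):
        # priorities O2 > C3 > C1 swept clockwise viewed with C5 pointing away
        s, m = _tetrahedron(o2=(1, 0, 0.33),
                            c3=(-0.5, -0.866, 0.33),
                            c1=(-0.5, 0.866, 0.33),
                            c5=(0, 0, -1))
        assert chirality_at_c2(s, m) == "R"

    def test_manual_cip_walk_axes_case(self):
        # O2 on +x, C3 on +y, C1 on +z, C5 toward (-1,-1,-1): the 1→2→3 sweep
        # is counterclockwise viewed from the side opposite C5, hence S
        s, m = _tetrahedron(o2=(1, 0, 0), c3=(0, 1, 0), c1=(0, 0, 1),
                            c5=(-0.58, -0.58, -0.58))
        assert chirality_at_c2(s, m) == "S"

    def test_inversion_swaps_descriptor(self, mosher_structure):
        (rec,) = analyze_structure(mosher_structure)
        inv = CrystalStructure(
            "inv", None,
            [AtomRecord(a.label, a.element, -p) for a, p in
             zip(mosher_structure.atoms, mosher_structure.cartesian())])
        (rec_inv,) = analyze_structure(inv)
        assert {rec.chirality, rec_inv.chirality} == {"R", "S"}

    @pytest.mark.parametrize("chirality", ["R", "S"])
    def test_generator_ground_truth(self, chirality):
        s = build_mtpa_amide(TorsionSpec(chirality=chirality))
        (rec,) = analyze_structure(s)
        assert rec.chirality == chirality

    @pytest.mark.parametrize("chirality", ["R", "S"])
    def test_rdkit_cross_check(self, chirality):
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem
        from rdkit.Chem import rdDetermineBonds

        s = build_mtpa_amide(TorsionSpec(chirality=chirality))
        pos = s.cartesian()
        xyz = f"{len(s.atoms)}\n\n" + "\n".join(
            f"{a.element} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}"
            for a, p in zip(s.atoms, pos))
        mol = Chem.MolFromXYZBlock(xyz)
        rdDetermineBonds.DetermineBonds(mol, charge=0)
        Chem.AssignStereochemistryFrom3D(mol)
        centers = dict(Chem.FindMolChiralCenters(mol))
        (rec,) = analyze_structure(s)
        assert centers[0] == rec.chirality == chirality


class TestSubstituentClasses:
    def test_generator_alpha_classes(self):
        expectations = {
            "isopropylamine": ("secondary_alkyl", "H", "secondary"),
            "n_propylamine": ("primary_alkyl", "H", "secondary"),
            "pyrrolidine": ("secondary_alkyl", "primary_alkyl", "tertiary"),
            "N_methyl_isopropyl": ("methyl", "secondary_alkyl", "tertiary"),
            "tetrakis_aryl": ("aryl", "H", "secondary"),
        }
        for template, (rsp, rap, arity) in expectations.items():
            s = build_mtpa_amide(TorsionSpec(amine_template=template))
            rec = analyze_structure(s)[0]
            assert (rec.rsp_class, rec.rap_class, rec.amide_arity) == \
                (rsp, rap, arity), template

    def test_heteroatom_alpha_is_element_keyed(self):
        s = _cartesian_structure([("N1", "N", (0, 0, 0)),
                                  ("N2", "N", (1.4, 0, 0))])
        bonds = perceive_bonds(s)
        assert substituent_class(s, bonds, 1, n_index=0) == "nitrogen"


class TestAmideForm:
    @pytest.mark.parametrize("rsp,rap,expected", [
        ("secondary_alkyl", "primary_alkyl", "Z"),
        ("methyl", "secondary_alkyl", "E"),
        ("primary_alkyl", "primary_alkyl", "indeterminate"),
        ("secondary_alkyl", "H", "Z"),
        ("aryl", "H", "Z"),                      # alpha C beats H
        ("aryl", "nitrogen", "E"),               # alpha N beats alpha C
        ("sulfonyl", "primary_alkyl", "Z"),      # alpha S beats alpha C
        ("selenoxo", "secondary_alkyl", "indeterminate"),
        ("tertiary_alkyl", "primary_alkyl", "Z"),
    ])
    def test_priority_comparison(self, rsp, rap, expected):
        assert classify_amide_form(rsp, rap) == expected

    def test_fixture_tertiary_rows_tally(self, table1_rows):
        forms = [classify_amide_form(r.rsp_class, r.rap_class)
                 for r in table1_rows if 15 <= r.row_no <= 40]
        assert (forms.count("Z"), forms.count("E"),
                forms.count("indeterminate")) == (13, 4, 9)

    def test_all_primary_amine_rows_are_Z(self, table1_rows):
        for r in table1_rows:
            if r.amine_class == "primary_amine":
                assert classify_amide_form(r.rsp_class, r.rap_class) == "Z"
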