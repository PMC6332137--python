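import numpy as np
import pytest

from mtpaconf.cif import TORSION_FIELDS
from mtpaconf.descriptors import (
    TorsionSet,
    classify_conformer,
    normalize_to_R,
    select_c10,
    select_f3,
)
from mtpaconf.geometry import torsion_angle
from mtpaconf.perception import find_mtpa_moieties, perceive_bonds
from mtpaconf.pipeline import analyze_structure
from mtpaconf.synth import TorsionSpec, build_mtpa_amide
from .conftest import CONSENSUS


def _ts(chirality="R", normalized=False, **kw):
    base = dict(theta1=-13.0, tau_f3=-174.0, tau_sp=2.0, tau_ap=-174.0,
                tau_h=-11.0, theta2=21.0, tau_ome=54.0)
    base.update(kw)
    return TorsionSet(**base, chirality=chirality, normalized=normalized)


class TestSelectionRules:
    @pytest.mark.parametrize("tau_f3", [-174.0, -130.0, 180.0, 125.0])
    def test_f3_is_the_max_magnitude_fluorine(self, tau_f3):
        s = build_mtpa_amide(TorsionSpec(tau_f3=tau_f3))
        bonds = perceive_bonds(s)
        (m,) = find_mtpa_moieties(s, bonds)
        f3 = select_f3(s, m)
        pos = s.cartesian()
        got = torsion_angle(pos[m.c1], pos[m.c2], pos[m.c3], pos[f3])
        assert got == pytest.approx(tau_f3, abs=0.5)
        assert abs(got) >= 120.0

    def test_cf3_torsions_are_120_apart(self):
        s = build_mtpa_amide(TorsionSpec())
        bonds = perceive_bonds(s)
        (m,) = find_mtpa_moieties(s, bonds)
        pos = s.cartesian()
        taus = sorted(
            torsion_angle(pos[m.c1], pos[m.c2], pos[m.c3], pos[f])
            for f in m.f_all)
        gaps = [taus[1] - taus[0], taus[2] - taus[1]]
        assert all(abs(g - 120.0) <= 2.0 for g in gaps)

    @pytest.mark.parametrize("theta2", [21.0, -60.0, 89.0])
    def test_c10_minimizes_magnitude(self, theta2):
        s = build_mtpa_amide(TorsionSpec(theta2=theta2))
        bonds = perceive_bonds(s)
        (m,) = find_mtpa_moieties(s, bonds)
        c10 = select_c10(s, m)
        pos = s.cartesian()
        got = torsion_angle(pos[m.o2], pos[m.c2], pos[m.c5], pos[c10])
        assert got == pytest.approx(theta2, abs=0.5)
        assert abs(got) <= 90.0

    def test_ortho_torsions_differ_by_half_turn(self):
        s = build_mtpa_amide(TorsionSpec())
        bonds = perceive_bonds(s)
        (m,) = find_mtpa_moieties(s, bonds)
        pos = s.cartesian()
        ta, tb = (torsion_angle(pos[m.o2], pos[m.c2], pos[m.c5], pos[c])
                  for c in m.ortho_pair)
        diff = abs(ta - tb) % 360
        assert min(diff, 360 - diff) == pytest.approx(180.0, abs=3.0)

    def test_selection_invariants_over_random_rotations(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            spec = TorsionSpec(
                tau_f3=float(np.round(180 - rng.uniform(0, 60), 3)) *
                (1 if rng.random() < 0.5 else -1),
                theta2=float(np.round(rng.uniform(-89, 89), 3)))
            rec = analyze_structure(build_mtpa_amide(spec))[0]
            assert abs(rec.raw.tau_f3) >= 120.0
            assert abs(rec.raw.theta2) <= 90.0


class TestComputeTorsionSet:
    def test_consensus_roundtrip_within_half_degree(self, mosher_record):
        expected = dict(CONSENSUS, tau_h=-11.0)
        for name, target in expected.items():
            if name == "tau_ap":
                continue  # ap side is the N-H: null by contract
            assert getattr(mosher_record.raw, name) == pytest.approx(
                target, abs=0.5), name

    def test_secondary_amide_tau_ap_is_null(self, mosher_record):
        assert mosher_record.raw.tau_ap is None

    def test_mirror_negates_all_torsions(self, mosher_record):
        spec = TorsionSpec(**CONSENSUS, tau_h=-11.0, chirality="S")
        (rec_s,) = analyze_structure(build_mtpa_amide(spec))
        for name in TORSION_FIELDS:
            v_r = getattr(mosher_record.raw, name)
            v_s = getattr(rec_s.raw, name)
            if v_r is None:
                assert v_s is None
            else:
                assert v_s == pytest.approx(-v_r, abs=1e-6)


class TestNormalization:
    def test_s_rows_flip_sign(self):
        ts = normalize_to_R(_ts(chirality="S", theta1=35.0))
        assert ts.theta1 == -35.0 and ts.normalized
        ts50 = normalize_to_R(_ts(chirality="S", theta1=57.0))
        assert ts50.theta1 == -57.0

    def test_r_rows_unchanged_and_idempotent(self):
        ts = _ts(chirality="R")
        once = normalize_to_R(ts)
        assert once.torsions() == ts.torsions()
        assert normalize_to_R(once) is once

    def test_plus_180_is_a_fixed_point(self):
        ts = normalize_to_R(_ts(chirality="S", tau_f3=180.0))
        assert ts.tau_f3 == 180.0

    def test_fixture_normalization_matches_survey_quotes(self, table1_rows):
        row4 = table1_rows[3]
        ts = normalize_to_R(
            TorsionSet.from_values(row4.torsions(), row4.chirality))
        assert ts.theta1 == -35.0
        row50 = table1_rows[49]
        ts50 = normalize_to_R(
            TorsionSet.from_values(row50.torsions(), row50.chirality))
        assert ts50.theta1 == -57.0


class TestClassifyConformer:
    def _classified(self, row):
        ts = normalize_to_R(TorsionSet.from_values(row.torsions(), row.chirality))
        return classify_conformer(ts, row.rsp_class, row.rap_class,
                                  row.amide_arity)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            classify_conformer(_ts(), "H", "H", "secondary")

    def test_row1_is_the_canonical_mosher_conformer(self, table1_rows):
        c = self._classified(table1_rows[0])
        assert c.theta1_window == "sp_major"
        assert c.cf3_staggered
        assert c.amide_form == "Z"
        assert c.mosher_type
        assert c.carbonyl_methoxy == "syn"

    def test_row9_is_the_anti_minor_conformer(self, table1_rows):
        c = self._classified(table1_rows[8])
        assert c.theta1_window == "minor_anti"
        assert c.carbonyl_methoxy == "anti"

    def test_row26_is_E_form(self, table1_rows):
        assert self._classified(table1_rows[25]).amide_form == "E"

    def test_mosher_flag_matches_footnote_d(self, table1_rows):
        mosher = {r.row_no for r in table1_rows if self._classified(r).mosher_type}
        flagged = {r.row_no for r in table1_rows if "d" in r.footnote_flags}
        assert mosher == flagged

    def test_anti_flag_matches_footnote_f(self, table1_rows):
        anti = {r.row_no for r in table1_rows
                if self._classified(r).carbonyl_methoxy == "anti"}
        flagged = {r.row_no for r in table1_rows if "f" in r.footnote_flags}
        assert anti == flagged

    def test_irregular_theta1_rows_are_other_not_minor(self, table1_rows):
        # the ~−41/−36/−31/−35 outliers have syn methoxy: irregular, not anti
        for idx in (10, 12, 46, 3):  # rows 11, 13, 47, 4
            assert self._classified(table1_rows[idx]).theta1_window == "other"
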