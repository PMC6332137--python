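import numpy as np
import pytest

from mtpaconf import load_table1
from mtpaconf.pipeline import analyze_structure
from mtpaconf.synth import TorsionSpec, build_mtpa_amide

#: the survey's consensus conformation, used as a generator target throughout
CONSENSUS = dict(theta1=-13.0, tau_f3=-174.0, tau_sp=2.0, tau_ap=-174.0,
                 theta2=21.0, tau_ome=54.0)


def oracle_torsion(p1, p2, p3, p4):
    """Independent dihedral: project the end bonds onto the plane normal to
    the axis and take the signed angle between the projections."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    axis = p3 - p2
    axis = axis / np.linalg.norm(axis)
    u = (p1 - p2) - np.dot(p1 - p2, axis) * axis
    w = (p4 - p3) - np.dot(p4 - p3, axis) * axis
    return float(np.degrees(np.arctan2(np.dot(axis, np.cross(u, w)),
                                       np.dot(u, w))))


@pytest.fixture(scope="session")
def table1_rows():
    return load_table1()


@pytest.fixture(scope="session")
def mosher_structure():
    """Noise-free Mosher-type build at the consensus torsions."""
    return build_mtpa_amide(
        TorsionSpec(**CONSENSUS, tau_h=-11.0, amine_template="isopropylamine"))


@pytest.fixture(scope="session")
def mosher_record(mosher_structure):
    (rec,) = analyze_structure(mosher_structure)
    return rec
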