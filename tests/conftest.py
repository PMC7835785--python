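import numpy as np
import pytest

import elfiqa as ei
from elfiqa.basins import BasinPartition, BasinRecord


@pytest.fixture(scope="session")
def one_orbital_bond():
    return ei.make_toy_wavefunction("one_orbital_bond", alpha=1.0, distance=1.4)


@pytest.fixture(scope="session")
def two_orbital_model():
    return ei.make_toy_wavefunction("two_orbital_model", alpha=1.0, distance=3.0)


@pytest.fixture(scope="session")
def midplane_partition(one_orbital_bond):
    """one_orbital_bond density grid split by the z = 0 mirror plane."""
    fields = ei.fields_on_grid(one_orbital_bond, n_points=40, margin=5.0)
    rho = fields["rho"]
    z = rho.axes()[2]
    labels = np.zeros(rho.shape, dtype=np.int32)
    labels[:, :, z > 0] = 1
    part = BasinPartition(
        labels=rho.like(labels, "labels"),
        records=[BasinRecord(0, np.array([0.0, 0.0, -0.7]), 1.0),
                 BasinRecord(1, np.array([0.0, 0.0, +0.7]), 1.0)])
    return part, fields


MOLDEN_H2 = """[Molden Format]
[Atoms] AU
H     1    1     0.000000   0.000000  -0.700000
H     2    1     0.000000   0.000000   0.700000
[GTO]
  1 0
 s    3 1.00
      3.42525091         0.15432897
      0.62391373         0.53532814
      0.16885540         0.44463454

  2 0
 s    3 1.00
      3.42525091         0.15432897
      0.62391373         0.53532814
      0.16885540         0.44463454

[MO]
 Sym= a1
 Ene= -0.578
 Spin= Alpha
 Occup= 2.0
   1   {c:.8f}
   2   {c:.8f}
"""


@pytest.fixture(scope="session")
def molden_h2_text():
    # bonding coefficient for the STO-3G-like H2 at R = 1.4 bohr
    sh = ei.Shell(0, 0, np.array([3.42525091, 0.62391373, 0.16885540]),
                  np.array([0.15432897, 0.53532814, 0.44463454]))
    wf = ei.Wavefunction(
        [ei.Nucleus("H", 1.0, [0, 0, -0.7]), ei.Nucleus("H", 1.0, [0, 0, 0.7])],
        [sh, ei.Shell(1, 0, sh.exponents, sh.coefficients)],
        np.ones((2, 1)), np.array([2.0]))
    s = wf.overlap_matrix()[0, 1]
    return MOLDEN_H2.format(c=1.0 / np.sqrt(2 * (1 + s)))


@pytest.fixture(scope="session")
def fixture_store():
    return ei.FixtureStore()


def _cached_analysis(name, n_points=150):
    wf = ei.load_molecule(name)
    return ei.analyze_wavefunction(wf, name=name, n_points=n_points)


@pytest.fixture(scope="session")
def benzene_analysis():
    return _cached_analysis("benzene")


@pytest.fixture(scope="session")
def phenolate_analysis():
    return _cached_analysis("phenolate")


@pytest.fixture(scope="session")
def anilinium_analysis():
    return _cached_analysis("anilinium")


@pytest.fixture(scope="session")
def aniline_analysis():
    return _cached_analysis("aniline")


@pytest.fixture(scope="session")
def nitrobenzene_analysis():
    return _cached_analysis("nitrobenzene")


@pytest.fixture(scope="session")
def toluene_analysis():
    return _cached_analysis("toluene")
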