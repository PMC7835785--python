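import numpy as np
import pytest

import elfiqa as ei
from elfiqa.basins import BasinPartition, BasinRecord
from elfiqa.deloc import covariance_oracle, vicinal_di


class TestDIMatrix:
    def test_one_orbital_closed_form(self, midplane_partition, one_orbital_bond):
        """2-electron system split in two basins: delta = 4 s (1 - s)."""
        part, _ = midplane_partition
        obs = ei.integrate_basins(part, one_orbital_bond)
        dm = ei.di_matrix(obs)
        s = obs.overlap(0)[0, 0]
        assert dm.get(0, 1) == pytest.approx(4 * s * (1 - s), abs=1e-12)

    def test_half_overlap_gives_unity(self, one_orbital_bond):
        """A symmetric split has S^A_11 = 1/2, so delta = 1 exactly."""
        fields = ei.fields_on_grid(one_orbital_bond, n_points=40, margin=5.0)
        rho = fields["rho"]
        z = rho.axes()[2]
        labels = np.zeros(rho.shape, dtype=np.int32)
        labels[:, :, z > 0] = 1
        part = BasinPartition(labels=rho.like(labels, "labels"),
                              records=[BasinRecord(0, np.zeros(3), 1.0),
                                       BasinRecord(1, np.zeros(3), 1.0)])
        obs = ei.integrate_basins(part, one_orbital_bond)
        dm = ei.di_matrix(obs)
        assert obs.overlap(0)[0, 0] == pytest.approx(0.5, abs=2e-3)
        assert dm.get(0, 1) == pytest.approx(1.0, abs=1e-2)

    def test_whole_space_single_basin(self, two_orbital_model):
        fields = ei.fields_on_grid(two_orbital_model, n_points=50, margin=6.0)
        rho = fields["rho"]
        labels = np.zeros(rho.shape, dtype=np.int32)
        part = BasinPartition(labels=rho.like(labels, "labels"),
                              records=[BasinRecord(0, np.zeros(3), 1.0)])
        obs = ei.integrate_basins(part, two_orbital_model)
        dm = ei.di_matrix(obs)
        assert dm.lam[0] == pytest.approx(obs.populations[0], abs=0.02)
        assert np.all(dm.delta == 0)

    def test_sum_rule(self, midplane_partition, one_orbital_bond):
        part, _ = midplane_partition
        obs = ei.integrate_basins(part, one_orbital_bond)
        dm = ei.di_matrix(obs)
        assert np.abs(dm.sum_rule_residual(obs.populations)).max() < 1e-10

    def test_mo_rotation_invariance(self, two_orbital_model):
        rng = np.random.default_rng(19)
        th = rng.uniform(0, 2 * np.pi)
        U = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        wf2 = ei.Wavefunction(two_orbital_model.nuclei, two_orbital_model.shells,
                              two_orbital_model.mo_coefficients @ U,
                              two_orbital_model.mo_occupations)
        fields = ei.fields_on_grid(two_orbital_model, n_points=40, margin=5.0)
        rho = fields["rho"]
        z = rho.axes()[2]
        labels = np.zeros(rho.shape, dtype=np.int32)
        labels[:, :, z > 0] = 1
        part = BasinPartition(labels=rho.like(labels, "labels"),
                              records=[BasinRecord(0, np.zeros(3), 1.0),
                                       BasinRecord(1, np.zeros(3), 1.0)])
        d1 = ei.di_matrix(ei.integrate_basins(part, two_orbital_model)).get(0, 1)
        d2 = ei.di_matrix(ei.integrate_basins(part, wf2)).get(0, 1)
        assert d1 == pytest.approx(d2, abs=1e-10)


class TestCovarianceOracle:
    def test_matches_overlap_formula(self, midplane_partition, one_orbital_bond):
        part, _ = midplane_partition
        obs = ei.integrate_basins(part, one_orbital_bond)
        dm = ei.di_matrix(obs)
        cov = covariance_oracle(part, one_orbital_bond, 0, 1)
        assert cov == pytest.approx(dm.get(0, 1), abs=1e-6)

    def test_self_covariance_sum_rule(self, midplane_partition, one_orbital_bond):
        """-2 cov(n_A, n_A) = 2 (n_A - lambda... ) ties to the sum rule."""
        part, _ = midplane_partition
        obs = ei.integrate_basins(part, one_orbital_bond)
        dm = ei.di_matrix(obs)
        self_cov = covariance_oracle(part, one_orbital_bond, 0, 0)
        # var(n_A) = n_A - lambda(A), so -2 cov(nA,nA) = 2 lambda(A) - 2 n_A
        assert self_cov == pytest.approx(
            2 * dm.lam[0] - 2 * obs.population(0), abs=1e-6)

    def test_disjoint_fragments_vanish(self):
        wf = ei.make_toy_wavefunction("two_orbital_model", alpha=1.2, distance=9.0)
        fields = ei.fields_on_grid(wf, n_points=56, margin=4.0)
        rho = fields["rho"]
        z = rho.axes()[2]
        labels = np.zeros(rho.shape, dtype=np.int32)
        labels[:, :, z > 0] = 1
        part = BasinPartition(labels=rho.like(labels, "labels"),
                              records=[BasinRecord(0, np.zeros(3), 1.0),
                                       BasinRecord(1, np.zeros(3), 1.0)])
        obs = ei.integrate_basins(part, wf)
        dm = ei.di_matrix(obs)
        assert dm.get(0, 1) < 1e-6

    def test_large_system_refused(self, benzene_analysis):
        with pytest.raises(ValueError):
            covariance_oracle(benzene_analysis.partition, benzene_analysis.wf, 0, 1)


class TestVicinalDI:
    def test_benzene_d6h_degeneracy(self, benzene_analysis):
        di = vicinal_di(benzene_analysis.di, benzene_analysis.ring)
        vals = [di[a] for a in ("i", "o", "m", "p")]
        assert max(vals) - min(vals) < 0.01

    def test_branch_averaging(self, benzene_analysis):
        di = vicinal_di(benzene_analysis.di, benzene_analysis.ring)
        for a in ("o", "m"):
            assert di[a] == pytest.approx(float(np.mean(di["raw"][a])))
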