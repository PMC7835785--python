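import numpy as np
import pytest

import elfiqa as ei
from elfiqa.basins import (DegenerateFieldError, classify_synapticity,
                           find_basins)
from elfiqa.grids import FieldGrid


def _bump_field(centers, n=40, half=4.0):
    ax = np.linspace(-half, half, n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    f = sum(np.exp(-((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2))
            for c in centers)
    sp = np.full(3, ax[1] - ax[0])
    return FieldGrid(np.full(3, -half), sp, f, "field"), ax


class TestFindBasins:
    def test_single_bump_single_basin(self):
        grid, _ = _bump_field([(0, 0, 0)])
        part = find_basins(grid)
        assert part.n_basins == 1
        lab = part.labels.values
        # one basin covering every non-vacuum voxel
        assert set(np.unique(lab)) <= {-1, 0}
        assert lab[20, 20, 20] == 0

    def test_two_bumps_split_by_midplane(self):
        grid, ax = _bump_field([(-1.5, 0, 0), (1.5, 0, 0)])
        part = find_basins(grid)
        assert part.n_basins == 2
        lab = part.labels.values
        # brute-force nearest-maximum oracle (the bumps are symmetric)
        X = ax[:, None, None] * np.ones_like(lab, float)
        oracle = (X > 0).astype(int)
        lab_oracle_map = lab[30, 20, 20]  # label of the +x side
        agree = (lab == np.where(oracle == 1, lab_oracle_map, 1 - lab_oracle_map))
        labeled = lab >= 0
        assert agree[labeled].mean() > 0.999
        counts = np.bincount(lab.ravel()[lab.ravel() >= 0])
        assert abs(counts[0] - counts[1]) <= lab.shape[1] * lab.shape[2]

    def test_partition_exhaustive(self):
        grid, _ = _bump_field([(-1.5, 0, 0), (1.5, 0, 0)])
        part = find_basins(grid)
        lab = part.labels.values
        assert np.sum(lab >= 0) + np.sum(lab == -1) == lab.size
        # attractor of each basin lies inside its own region
        for r in part.records:
            idx = np.round((r.attractor_xyz - grid.origin) / grid.spacing).astype(int)
            assert lab[tuple(idx)] == r.basin_id

    def test_flat_field_degenerate(self):
        g = FieldGrid(np.zeros(3), np.ones(3), np.ones((8, 8, 8)), "field")
        with pytest.raises(DegenerateFieldError):
            find_basins(g)

    def test_attractor_merging(self):
        """Two maxima closer than the merge distance collapse to one basin."""
        grid, _ = _bump_field([(-0.05, 0, 0), (0.05, 0, 0)], n=48)
        part = find_basins(grid)
        assert part.n_basins == 1


class TestSynapticity:
    def test_toy_bond_disynaptic(self, one_orbital_bond):
        fields = ei.fields_on_grid(one_orbital_bond, n_points=48, margin=4.0)
        part = find_basins(fields["elf"], rho_grid=fields["rho"])
        classify_synapticity(part, one_orbital_bond)
        real = part.real_records()
        assert len(real) == 1
        # both 'X' centers have Z=1 and are picked up by the proximity rule
        assert real[0].kind == "disynaptic"
        assert real[0].nuclei == (0, 1)

    def test_atomlike_shell_structure(self):
        """Tight + diffuse s shells give a core attractor and a valence shell."""
        wf = ei.make_toy_wavefunction("atomlike")
        fields = ei.fields_on_grid(wf, n_points=64, margin=4.0)
        part = find_basins(fields["elf"], rho_grid=fields["rho"])
        classify_synapticity(part, wf)
        kinds = [r.kind for r in part.real_records()]
        assert "core" in kinds            # attractor at the Z=4 nucleus
        assert len(part.real_records()) >= 2  # plus an outer shell region


class TestBenzeneTopology:
    def test_census_18_basins(self, benzene_analysis):
        """Benzene: 6 cores + 6 V(C,C) + 6 V(C,H)."""
        census = benzene_analysis.census()
        assert census.get("core") == 6
        names = [r.name for r in benzene_analysis.partition.real_records()]
        vcc = [n for n in names if n.count("C") == 2 and "H" not in n and n.startswith("V")]
        vch = [n for n in names if "H" in n and n.startswith("V")]
        assert len(vcc) == 6
        assert len(vch) == 6
        assert len(benzene_analysis.partition.real_records()) == 18

    def test_ring_labeling_circular(self, benzene_analysis):
        ring = benzene_analysis.ring
        assert len(set(ring.bond_basin_map.values())) == 6
        # b61 links C6 and C1
        rec = benzene_analysis.partition.records[ring.bond_basin_map["b61"]]
        assert set(rec.nuclei) == {ring.ring_atoms[5], ring.ring_atoms[0]}

    def test_toluene_ipso_labeling(self, toluene_analysis):
        """b12 and b61 are the bonds adjacent to the methyl-bearing carbon."""
        ring = toluene_analysis.ring
        part = toluene_analysis.partition
        ipso = ring.ring_atoms[0]
        for key in ("b12", "b61"):
            rec = part.records[ring.bond_basin_map[key]]
            assert ipso in rec.nuclei


class TestTwoRingDetection:
    def test_attachment_selects_ring(self):
        """With two fused 6-rings (biphenyl-like connectivity), labeling picks
        the ring containing the carbon bonded to the marked attachment."""
        from dataclasses import dataclass
        import elfiqa as ei
        from elfiqa.basins import BasinPartition, BasinRecord, label_ring_basins

        # two hexagons of carbons (0-5 and 6-11) linked 0-6; no real grid needed
        rcc = 2.64  # bohr
        coords = []
        for ring0, xoff in ((0, 0.0), (6, 2 * rcc + 2.64)):
            for k in range(6):
                th = np.pi + k * np.pi / 3 if ring0 == 0 else k * np.pi / 3
                coords.append([xoff + rcc * np.cos(th), rcc * np.sin(th), 0.0])
        coords = np.array(coords)

        @dataclass
        class FakeWf:
            nuclei: list
            @property
            def coords(self):
                return np.array([n.xyz for n in self.nuclei])

        wf = FakeWf([ei.Nucleus("C", 6.0, c) for c in coords])
        labels = ei.FieldGrid(np.zeros(3), np.ones(3),
                              np.zeros((2, 2, 2), dtype=np.int32), "labels")
        records = []
        bid = 0
        edges = [(i, (i + 1) % 6) for i in range(6)]
        edges += [(6 + i, 6 + (i + 1) % 6) for i in range(6)]
        edges += [(0, 6)]
        for a, b in edges:
            mid = 0.5 * (coords[a] + coords[b])
            r = BasinRecord(bid, mid, 0.9, kind="disynaptic", nuclei=(a, b),
                            name=f"V(C{a+1},C{b+1})", population_estimate=2.8)
            records.append(r)
            bid += 1
        part = BasinPartition(labels=labels, records=records)
        # attachment = carbon 6 (the other ring's ipso): ring must be 6..11
        ring = label_ring_basins(part, wf, substituent_attachment=0)
        assert set(ring.ring_atoms) == set(range(6, 12))
        assert ring.ring_atoms[0] == 6
        # and symmetrically
        ring2 = label_ring_basins(part, wf, substituent_attachment=6)
        assert set(ring2.ring_atoms) == set(range(6))
        assert ring2.ring_atoms[0] == 0
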