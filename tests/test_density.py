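"""Map I/O, Fourier synthesis, footprint masks, and density transcription."""

import gemmi
import numpy as np
import pytest

from mcligand.density import (DensityGrid, atom_density, build_mask,
                              extract_masked, fourier_synthesize,
                              half_sphere_hkl, read_map,
                              synthesize_from_coefficients, transcribe_density)
from mcligand.errors import MapError
from mcligand.sampling import ConformerSet

from conftest import make_ligand, write_ccp4_raw
from mcligand.ligand import assign_bond_orders


def cubic_grid(n=20, a=10.0, resolution=1.5, fill=0.0):
    return DensityGrid(values=np.full((n, n, n), fill),
                       unit_cell=gemmi.UnitCell(a, a, a, 90, 90, 90),
                       resolution=resolution)


class TestReadMap:
    def test_round_trips_cell_and_values(self, tmp_path):
        rng = np.random.default_rng(0)
        values = rng.random((40, 40, 40))
        grid = DensityGrid(values=values,
                           unit_cell=gemmi.UnitCell(20, 20, 20, 90, 90, 90))
        path = tmp_path / "m.ccp4"
        grid.write_ccp4(path)
        back = read_map(path)
        assert back.shape == (40, 40, 40)
        assert back.unit_cell.a == pytest.approx(20.0)
        assert back.spacing[0] == pytest.approx(0.5)
        np.testing.assert_allclose(back.values, values, atol=1e-6)

    def test_permuted_axis_order_is_canonicalized(self, tmp_path):
        rng = np.random.default_rng(1)
        values = rng.random((6, 8, 10)).astype(np.float32)
        p1 = tmp_path / "canon.ccp4"
        p2 = tmp_path / "permuted.ccp4"
        write_ccp4_raw(p1, values, (6.0, 8.0, 10.0), axis_order=(1, 2, 3))
        write_ccp4_raw(p2, values, (6.0, 8.0, 10.0), axis_order=(2, 3, 1))
        a = read_map(p1)
        b = read_map(p2)
        np.testing.assert_allclose(a.values, b.values, atol=1e-7)
        np.testing.assert_allclose(a.values, values, atol=1e-7)

    def test_truncated_file_raises(self, tmp_path):
        path = tmp_path / "broken.ccp4"
        path.write_bytes(b"\x00" * 100)
        with pytest.raises(MapError):
            read_map(path)


class TestFourierSynthesis:
    def _write_mtz(self, path, cell, rows):
        mtz = gemmi.Mtz(with_base=True)
        mtz.spacegroup = gemmi.SpaceGroup("P1")
        mtz.set_cell_for_all(cell)
        mtz.add_dataset("d")
        mtz.add_column("FWT", "F")
        mtz.add_column("PHWT", "P")
        mtz.set_data(np.asarray(rows, dtype=np.float32))
        mtz.write_to_file(str(path))

    def test_dc_term_gives_constant_map(self, tmp_path):
        cell = gemmi.UnitCell(10, 10, 10, 90, 90, 90)
        c = 0.25
        path = tmp_path / "dc.mtz"
        self._write_mtz(path, cell, [[0, 0, 0, c * cell.volume, 0.0],
                                     [1, 0, 0, 0.0, 0.0]])
        grid = fourier_synthesize(path, "FWT,PHWT")
        np.testing.assert_allclose(grid.values, c, atol=1e-6)

    def test_single_reflection_matches_direct_summation(self, tmp_path):
        cell = gemmi.UnitCell(12, 12, 12, 90, 90, 90)
        amp, res = 3.0, 2.0
        path = tmp_path / "one.mtz"
        self._write_mtz(path, cell, [[1, 0, 0, amp, 0.0],
                                     [0, 0, 6, 0.0, 0.0]])
        grid = fourier_synthesize(path, "FWT,PHWT")
        nx = grid.shape[0]
        x = np.arange(nx) / nx
        # direct summation over F(1,0,0) and its Friedel mate
        expected = (2 * amp / cell.volume) * np.cos(2 * np.pi * x)
        np.testing.assert_allclose(grid.values[:, 0, 0], expected, atol=1e-6)

    def test_missing_column_raises(self, tmp_path):
        cell = gemmi.UnitCell(10, 10, 10, 90, 90, 90)
        path = tmp_path / "cols.mtz"
        self._write_mtz(path, cell, [[1, 0, 0, 1.0, 0.0]])
        with pytest.raises(MapError, match="column"):
            fourier_synthesize(path, "NOPE,PHWT")

    def test_many_reflection_synthesis_matches_brute_force(self):
        rng = np.random.default_rng(3)
        cell = gemmi.UnitCell(9, 11, 13, 90, 90, 90)
        hkl = half_sphere_hkl(cell, 4.0)
        sel = rng.choice(len(hkl), size=min(40, len(hkl)), replace=False)
        hkl = hkl[sel]
        f = rng.random(len(hkl)) * np.exp(2j * np.pi * rng.random(len(hkl)))
        grid = synthesize_from_coefficients(hkl, f, cell, 4.0)
        nu, nv, nw = grid.shape
        u, v, w = np.meshgrid(np.arange(nu) / nu, np.arange(nv) / nv,
                              np.arange(nw) / nw, indexing="ij")
        brute = np.zeros(grid.shape)
        for (h, k, l), fc in zip(hkl, f):
            phase = np.exp(-2j * np.pi * (h * u + k * v + l * w))
            brute += (2.0 / cell.volume) * np.real(fc * phase)
        assert np.max(np.abs(grid.values - brute)) < 1e-6 * max(1.0, np.abs(brute).max())

    def test_fft_round_trip_of_point_atom_map(self):
        # forward SF summation -> synthesis -> numpy inverse agrees
        lig = make_ligand("CC", seed=2)
        from mcligand.benchmark import structure_factors
        from mcligand.multiconformer import MulticonformerModel
        cell = gemmi.UnitCell(14, 14, 14, 90, 90, 90)
        model = MulticonformerModel(ligand=lig, conformers=lig.coords[None] + 5.0,
                                    occupancies=np.array([1.0]), altlocs=[""])
        hkl, F = structure_factors(model, cell, 1.5, bulk_solvent=False)
        grid = synthesize_from_coefficients(hkl, F, cell, 1.5)
        # inverse: recover F by direct sum over the synthesized map
        nu, nv, nw = grid.shape
        u, v, w = np.meshgrid(np.arange(nu) / nu, np.arange(nv) / nv,
                              np.arange(nw) / nw, indexing="ij")
        for idx in (0, len(hkl) // 2, len(hkl) - 1):
            h, k, l = hkl[idx]
            integrand = grid.values * np.exp(2j * np.pi * (h * u + k * v + l * w))
            f_back = integrand.sum() * cell.volume / (nu * nv * nw)
            assert abs(f_back - F[idx]) < 1e-4 * max(1.0, abs(F[idx]))


class TestMask:
    def test_single_atom_tiny_radius_hits_one_voxel(self, toy_bonded):
        grid = cubic_grid(n=10, a=10.0)
        coords = np.full((1, toy_bonded.ligand.n_heavy, 3), 5.0)
        conf = ConformerSet(topology=toy_bonded, coords=coords,
                            sources=["s"])
        mask = build_mask(grid, conf, radius=0.45)
        assert len(mask) == 1
        np.testing.assert_array_equal(mask.voxel_indices[0], [5, 5, 5])

    def test_union_of_disjoint_conformers(self, toy_bonded):
        grid = cubic_grid(n=20, a=20.0)
        n = toy_bonded.ligand.n_heavy
        c1 = np.full((1, n, 3), 5.0)
        c2 = np.full((1, n, 3), 15.0)
        m1 = build_mask(grid, ConformerSet(topology=toy_bonded, coords=c1,
                                           sources=["a"]), radius=0.9)
        m2 = build_mask(grid, ConformerSet(topology=toy_bonded, coords=c2,
                                           sources=["b"]), radius=0.9)
        both = build_mask(grid, ConformerSet(
            topology=toy_bonded, coords=np.concatenate([c1, c2]),
            sources=["a", "b"]), radius=0.9)
        s1 = {tuple(i) for i in m1.voxel_indices}
        s2 = {tuple(i) for i in m2.voxel_indices}
        assert {tuple(i) for i in both.voxel_indices} == s1 | s2

    def test_mask_wraps_across_periodic_boundary(self, toy_bonded):
        grid = cubic_grid(n=10, a=10.0)
        coords = np.zeros((1, toy_bonded.ligand.n_heavy, 3))   # at the corner
        mask = build_mask(grid, ConformerSet(topology=toy_bonded, coords=coords,
                                             sources=["s"]), radius=1.2)
        got = {tuple(i) for i in mask.voxel_indices}
        # brute force with periodic images
        brute = set()
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    d = np.array([min(i, 10 - i), min(j, 10 - j), min(k, 10 - k)])
                    if np.linalg.norm(d * 1.0) <= 1.2:
                        brute.add((i, j, k))
        assert got == brute


class TestTranscription:
    def _one_atom_set(self):
        lig = make_ligand("CC", seed=2)
        bonded = assign_bond_orders(lig, "CC")
        return bonded

    def test_single_gaussian_atom_peak_decreases_from_center(self):
        r = np.linspace(0.0, 2.0, 40)
        rho = atom_density("C", r, b_iso=0.0, resolution=1.0)
        assert np.all(np.diff(rho) < 0)

    def test_doubling_b_lowers_peak_but_conserves_integral(self):
        r = np.linspace(0.0, 6.0, 2000)
        rho1 = atom_density("C", r, b_iso=10.0, resolution=1.0)
        rho2 = atom_density("C", r, b_iso=20.0, resolution=1.0)
        assert rho2[0] < rho1[0]
        integral = lambda rho: np.trapezoid(4 * np.pi * r**2 * rho, r)
        assert integral(rho1) == pytest.approx(integral(rho2), rel=0.01)
        # both integrate to ~the carbon electron count
        assert integral(rho1) == pytest.approx(6.0, rel=0.02)

    def test_rows_are_linear_in_conformers(self, toy_bonded):
        grid = cubic_grid(n=24, a=12.0, resolution=1.5)
        n = toy_bonded.ligand.n_heavy
        rng = np.random.default_rng(8)
        c1 = rng.uniform(3, 9, (1, n, 3))
        c2 = rng.uniform(3, 9, (1, n, 3))
        both = ConformerSet(topology=toy_bonded,
                            coords=np.concatenate([c1, c2]), sources=["a", "b"])
        mask = build_mask(grid, both, radius=1.5)
        rows = transcribe_density(both, mask, grid, method="gaussian").values
        r1 = transcribe_density(ConformerSet(topology=toy_bonded, coords=c1,
                                             sources=["a"]), mask, grid,
                                method="gaussian").values
        r2 = transcribe_density(ConformerSet(topology=toy_bonded, coords=c2,
                                             sources=["b"]), mask, grid,
                                method="gaussian").values
        np.testing.assert_allclose(rows, np.concatenate([r1, r2]), atol=1e-12)
        assert np.all(rows >= 0)

    def test_gaussian_and_reciprocal_rows_correlate(self, torsional_case):
        grid = torsional_case["grid"]
        bonded = torsional_case["bonded_input"]
        conf = ConformerSet(topology=bonded, coords=bonded.ligand.coords[None],
                            sources=["in"])
        mask = build_mask(grid, conf)
        g = transcribe_density(conf, mask, grid, method="gaussian").values[0]
        r = transcribe_density(conf, mask, grid, method="reciprocal").values[0]
        # the two models share the gross shape but differ in radial profile
        assert np.corrcoef(g, r)[0, 1] > 0.8

    def test_masked_extraction_identical_from_ccp4_and_coefficients(
            self, tmp_path, torsional_case):
        grid = torsional_case["grid"]
        bonded = torsional_case["bonded_input"]
        path = tmp_path / "case.ccp4"
        grid.write_ccp4(path)
        back = read_map(path, resolution=grid.resolution)
        conf = ConformerSet(topology=bonded, coords=bonded.ligand.coords[None],
                            sources=["in"])
        mask = build_mask(grid, conf)
        np.testing.assert_allclose(extract_masked(back, mask),
                                   extract_masked(grid, mask), atol=1e-5)

    def test_unknown_element_raises(self):
        with pytest.raises(MapError):
            atom_density("Xx", np.array([0.0]), 10.0, 1.0)
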