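import numpy as np
import pytest

from cortexdiff.io_core import ImageVolume
from cortexdiff.cortical_grid import (
    LABEL_INTERIOR,
    LABEL_PIAL,
    LABEL_WM,
    TopologyError,
    build_grid,
    resample_line,
    sample_metric,
    solve_laplace,
    trace_gridlines,
    CorticalGrid,
    GridLine,
)

from conftest import annulus_mask, slab_mask


class TestLaplace:
    def test_slab_is_linear_in_depth(self):
        vol = slab_mask(n_depth=10)
        f = solve_laplace(vol)
        H = vol.data.shape[0]
        expect = np.linspace(0.0, 1.0, H)[:, None]
        assert np.nanmax(np.abs(f.psi - expect)) < 1e-9
        mid = f.psi[H // 2]  # even H: midline between rows; check both
        assert np.nanmin(f.psi[1:-1]) > 0.0
        assert np.nanmax(f.psi[1:-1]) < 1.0

    def test_annulus_matches_analytic_log_solution(self):
        vol, r = annulus_mask(10.0, 20.0)
        f = solve_laplace(vol)
        inside = vol.data == LABEL_INTERIOR
        analytic = np.log(np.maximum(r, 1e-9) / 10.0) / np.log(2.0)
        rms = np.sqrt(np.mean((f.psi[inside] - analytic[inside]) ** 2))
        assert rms < 0.02

    def test_harmonicity_residual(self):
        vol, _ = annulus_mask(10.0, 20.0)
        f = solve_laplace(vol)
        psi = f.psi
        res = 4 * psi[1:-1, 1:-1] - (
            psi[:-2, 1:-1] + psi[2:, 1:-1] + psi[1:-1, :-2] + psi[1:-1, 2:]
        )
        interior = (vol.data == LABEL_INTERIOR)[1:-1, 1:-1]
        # only stencils fully inside the ribbon are exactly harmonic
        full = np.isfinite(res) & interior
        assert np.abs(res[full]).max() < 1e-8

    def test_disconnected_ribbon_rejected(self):
        lab = np.zeros((8, 20), int)
        lab[0] = LABEL_PIAL
        lab[-1] = LABEL_WM
        lab[1:-1] = LABEL_INTERIOR
        lab[:, 10] = 0  # split in two
        lab[0, :10] = LABEL_PIAL
        lab[-1, 10:] = 0
        lab[1:-1, 10:] = 0  # right half has no WM and no interior link
        lab[1:-1, 11:] = LABEL_INTERIOR
        with pytest.raises(TopologyError):
            solve_laplace(ImageVolume(lab, (0.175, 0.175, 1.0)))

    def test_missing_boundary_rejected(self):
        lab = np.zeros((8, 20), int)
        lab[0] = LABEL_PIAL
        lab[1:] = LABEL_INTERIOR
        with pytest.raises(ValueError):
            solve_laplace(ImageVolume(lab, (0.175, 0.175, 1.0)))


class TestTracing:
    def test_slab_lines_straight_and_complete(self):
        vol = slab_mask(n_depth=10)
        f = solve_laplace(vol)
        raw = trace_gridlines(f)
        assert len(raw) == 50
        assert all(s is not None for s in raw)
        thickness = 11 * 0.175  # pial row center to WM row center
        for s in raw:
            length = np.sum(np.linalg.norm(np.diff(s, axis=0), axis=1))
            assert length == pytest.approx(thickness, abs=2 * 0.088)
            # straight down: x (row direction) varies, y constant
            assert np.ptp(s[:, 1]) < 1e-6

    def test_single_line_starts_at_arc_midpoint(self):
        vol = slab_mask(n_depth=10, n_len=41)
        f = solve_laplace(vol)
        raw = trace_gridlines(f, n_lines=1)
        assert len(raw) == 1
        y0 = raw[0][0, 1]
        assert y0 == pytest.approx(20 * 0.175, abs=0.175)

    def test_annulus_lines_radial(self):
        vol, _ = annulus_mask(10.0, 20.0)
        f = solve_laplace(vol)
        grid = build_grid(f)
        devs = []
        for ln in grid.lines:
            for v, t in zip(ln.vertices, ln.tangents):
                radial = v / np.linalg.norm(v)
                devs.append(
                    np.degrees(np.arccos(min(abs(t @ radial), 1.0)))
                )
        assert np.mean(devs) < 2.0

    def test_psi_monotone_along_lines(self):
        vol, _ = annulus_mask(10.0, 20.0)
        f = solve_laplace(vol)
        grid = build_grid(f)
        psi_map = ImageVolume(f.psi, vol.voxel_size, vol.affine)
        sheet = sample_metric(psi_map, grid)
        checked = 0
        for row in sheet.values:
            fin = row[np.isfinite(row)]
            # psi strictly increases with depth along every grid-line
            assert (np.diff(fin) > 0).all()
            checked += len(fin) - 1
        assert checked > 300

    @pytest.mark.parametrize("thickness_mm", [1.0, 2.0, 3.0, 4.0])
    def test_thickness_invariance(self, thickness_mm):
        n_depth = int(round(thickness_mm / 0.175))
        vol = slab_mask(n_depth=n_depth)
        grid = build_grid(solve_laplace(vol))
        assert grid.n_lines == 50
        for ln in grid.lines:
            assert ln.vertices.shape == (10, 2)
            sp = np.linalg.norm(np.diff(ln.vertices, axis=0), axis=1)
            assert np.allclose(sp, ln.arc_length / 9, rtol=0.01)
            # depth index d sits at relative depth d/9
            depth = ln.vertices[:, 0] - ln.vertices[0, 0]
            rel = depth / depth[-1]
            assert np.allclose(rel, np.arange(10) / 9, atol=0.02)

    def test_reparameterization_stability(self):
        vol, _ = annulus_mask(10.0, 20.0)
        f = solve_laplace(vol)
        g1 = build_grid(f, step_mm=0.088)
        g2 = build_grid(f, step_mm=0.044)
        assert g1.n_lines == g2.n_lines
        for a, b in zip(g1.lines, g2.lines):
            shift = np.linalg.norm(a.vertices - b.vertices, axis=1).max()
            assert shift < 0.5 * 0.088


class TestResample:
    def test_straight_segment(self):
        pts = np.array([[0.0, 0.0], [9.0, 0.0]])
        ln = resample_line(pts)
        assert np.allclose(ln.vertices[:, 0], np.arange(10.0))
        assert np.allclose(ln.vertices[:, 1], 0.0)

    def test_semicircle_equal_chords(self):
        t = np.linspace(0, np.pi, 500)
        r = 3.0
        pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
        ln = resample_line(pts)
        chords = np.linalg.norm(np.diff(ln.vertices, axis=0), axis=1)
        # equal arc-length steps on a circle give equal chords
        assert np.allclose(chords, chords[0], rtol=1e-3)
        angles = np.arctan2(ln.vertices[:, 1], ln.vertices[:, 0])
        assert np.allclose(np.abs(np.diff(angles)), np.pi / 9, rtol=1e-3)

    def test_two_point_input(self):
        ln = resample_line(np.array([[1.0, 1.0], [1.0, 10.0]]))
        assert np.allclose(np.diff(ln.vertices[:, 1]), 1.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            resample_line(np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestSampling:
    def _grid_on_slab(self):
        vol = slab_mask(n_depth=10)
        return vol, build_grid(solve_laplace(vol))

    def test_constant_map(self):
        vol, grid = self._grid_on_slab()
        cmap = ImageVolume(
            np.full(vol.data.shape, 3.25), vol.voxel_size, vol.affine
        )
        sheet = sample_metric(cmap, grid)
        assert np.allclose(sheet.values, 3.25)
        assert not sheet.missing.any()

    def test_exact_on_affine_field(self):
        vol, grid = self._grid_on_slab()
        H, W = vol.data.shape
        xmap = np.arange(W)[None, :] * 0.175 * np.ones((H, 1))
        sheet = sample_metric(
            ImageVolume(xmap, vol.voxel_size, vol.affine), grid
        )
        expect = grid.vertices()[:, :, 1]  # world y == column * pixel
        assert np.allclose(sheet.values, expect, atol=1e-6)

    def test_matches_brute_force_bilinear(self):
        rng = np.random.default_rng(3)
        vol, grid = self._grid_on_slab()
        arr = rng.normal(size=vol.data.shape)
        sheet = sample_metric(ImageVolume(arr, vol.voxel_size, vol.affine), grid)
        verts = grid.vertices().reshape(-1, 2)
        idx = rng.choice(len(verts), 20, replace=False)
        for k in idx:
            r, c = verts[k] / 0.175  # identity-scaled affine
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            r0 = min(max(r0, 0), arr.shape[0] - 2)
            c0 = min(max(c0, 0), arr.shape[1] - 2)
            fr, fc = r - r0, c - c0
            expect = (
                arr[r0, c0] * (1 - fr) * (1 - fc)
                + arr[r0 + 1, c0] * fr * (1 - fc)
                + arr[r0, c0 + 1] * (1 - fr) * fc
                + arr[r0 + 1, c0 + 1] * fr * fc
            )
            got = sheet.values.ravel()[k]
            assert got == pytest.approx(expect, abs=1e-9)

    def test_non_2d_map_rejected(self):
        vol, grid = self._grid_on_slab()
        with pytest.raises(ValueError):
            sample_metric(
                ImageVolume(np.zeros((4, 4, 4)), vol.voxel_size, vol.affine),
                grid,
            )

    def test_grid_table_roundtrip(self):
        _, grid = self._grid_on_slab()
        df = grid.to_table()
        back = CorticalGrid.from_table(df)
        assert np.allclose(back.vertices(), grid.vertices())
        assert np.allclose(back.tangents(), grid.tangents())
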