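"""Distance transforms, sources, skeletons and gradient fields."""

import numpy as np
import pytest
from scipy.sparse import csgraph, csr_matrix
from skimage.draw import disk

from useg3d import transforms as tr

from conftest import brute_edt


def _advect2d(start, field, steps=200, eta=1.0):
    """Tiny 2D advection helper for attractor-convergence checks."""
    pos = np.asarray(start, dtype=float)
    upper = np.asarray(field.components.shape[1:]) - 1.0
    for _ in range(steps):
        idx = np.clip(np.rint(pos), 0, upper).astype(int)
        g = field.components[:, idx[0], idx[1]]
        pos = np.clip(pos + eta * g, 0, upper)
    return pos


def _l_mask():
    m = np.zeros((30, 30), dtype=bool)
    m[5:25, 5:10] = True
    m[20:25, 5:25] = True
    return m


class TestEDT:
    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        assert tr.edt2d(m).values[2, 2] == 1.0

    def test_square_against_brute_force(self):
        m = np.zeros((9, 9), dtype=bool)
        m[2:7, 2:7] = True
        phi = tr.edt2d(m).values
        assert np.allclose(phi, brute_edt(m))
        assert phi[2, 2] == 1.0 and phi[4, 4] == 3.0

    def test_bar(self):
        m = np.zeros((3, 7), dtype=bool)
        m[1, 1:6] = True
        assert np.allclose(tr.edt2d(m).values[1, 1:6], 1.0)

    def test_border_counts_as_background(self):
        m = np.ones((5, 5), dtype=bool)
        phi = tr.edt2d(m).values
        assert phi[0, 0] == 1.0 and phi[2, 2] == 3.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            tr.edt2d(np.zeros((4, 4), dtype=bool))


class TestPoisson:
    def test_single_interior_pixel_quarter(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        assert np.isclose(tr.poisson_transform(m, "none").values[2, 2], 0.25)

    def test_disk_argmax_at_center(self, disk_mask):
        phi = tr.poisson_transform(disk_mask, "none").values
        peak = np.unravel_index(np.argmax(phi), phi.shape)
        assert np.linalg.norm(np.array(peak) - 20) <= 1.0

    @pytest.mark.parametrize("n", [3, 7, 15])
    def test_bar_matches_tridiagonal_oracle(self, n):
        m = np.zeros((3, n + 2), dtype=bool)
        m[1, 1 : n + 1] = True
        phi = tr.poisson_transform(m, "none").values[1, 1 : n + 1]
        A = (
            np.diag(np.full(n, 4.0))
            + np.diag(np.full(n - 1, -1.0), 1)
            + np.diag(np.full(n - 1, -1.0), -1)
        )
        oracle = np.linalg.solve(A, np.ones(n))
        assert np.abs(phi - oracle).max() < 1e-8

    def test_point_source_holds_maximum(self, disk_mask):
        dm = tr.poisson_transform(disk_mask, "point")
        src = np.argwhere(dm.source)[0]
        assert dm.values[tuple(src)] == dm.values.max()

    def test_power_transform_preserves_argmax(self, disk_mask):
        dm1 = tr.poisson_transform(disk_mask, "point", power=1.0)
        dm2 = tr.poisson_transform(disk_mask, "point", power=2.0)
        assert np.argmax(dm1.values) == np.argmax(dm2.values)
        assert (dm2.values >= 0).all()

    def test_source_outside_mask_rejected(self, disk_mask):
        with pytest.raises(ValueError):
            tr.poisson_transform(disk_mask, "point", src_coords=[(0, 0)])


class TestGeodesic:
    def test_disk_levels_concentric_and_inward(self, disk_mask):
        dm = tr.geodesic_transform(disk_mask, "point")
        gf = tr.gradient_field(dm, disk_mask)
        # boundary points advect radially inward toward the center
        for start in ((20, 7), (7, 20), (32, 20), (20, 32)):
            end = _advect2d(start, gf, steps=60)
            assert np.linalg.norm(end - 20) <= 2.0

    def test_l_mask_ordering_matches_dijkstra_oracle(self):
        m = _l_mask()
        src = (6, 6)
        dm = tr.geodesic_transform(m, "point", src_coords=[src])
        # oracle: Dijkstra on the 8-neighbor pixel graph with metric weights
        coords = np.argwhere(m)
        index = {tuple(c): k for k, c in enumerate(coords)}
        rows, cols, vals = [], [], []
        for k, c in enumerate(coords):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    q = (c[0] + dr, c[1] + dc)
                    if q in index:
                        rows.append(k)
                        cols.append(index[q])
                        vals.append(np.hypot(dr, dc))
        g = csr_matrix((vals, (rows, cols)), shape=(len(coords), len(coords)))
        oracle = csgraph.dijkstra(g, indices=index[src])
        travel = dm.values[m].max() - dm.values[m]
        assert np.abs(travel - oracle[[index[tuple(c)] for c in coords]]).max() < 0.45

    def test_source_gradient_zero(self, disk_mask):
        dm = tr.geodesic_transform(disk_mask, "skeleton")
        gf = tr.gradient_field(dm, disk_mask)
        assert np.allclose(gf.components[:, dm.source], 0.0)


class TestPointSource:
    def test_disk_center(self, disk_mask):
        assert np.allclose(tr.select_point_source(disk_mask), (20, 20))

    def test_crescent_source_stays_inside(self):
        m = np.zeros((40, 40), dtype=bool)
        rr, cc = disk((20, 20), 15)
        m[rr, cc] = True
        rr, cc = disk((20, 26), 12)
        m[rr, cc] = False
        src = tr.select_point_source(m)
        assert m[src]

    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=bool)
        m[3, 1] = True
        assert tr.select_point_source(m) == (3, 1)


class TestSkeleton:
    def test_rectangle_spans_long_axis(self):
        m = np.zeros((9, 54), dtype=bool)
        m[2:7, 2:52] = True
        sk = tr.medial_skeleton2d(m)
        assert sk.any() and (sk & m).sum() == sk.sum()
        cols = np.unique(np.argwhere(sk)[:, 1])
        assert cols.max() - cols.min() > 25  # a path along the long axis

    def test_disk_skeleton_is_small(self, disk_mask):
        sk = tr.medial_skeleton2d(disk_mask)
        assert 0 < sk.sum() <= 20

    def test_smoothing_reduces_branching(self):
        rng = np.random.default_rng(0)
        m = np.zeros((20, 60), dtype=bool)
        m[7:13, 3:57] = True
        noise = rng.random((20, 60)) < 0.12
        noisy = m | (np.roll(m, 1, axis=0) & noise) | (np.roll(m, -1, axis=0) & noise)
        from skimage.morphology import skeletonize

        raw_branches = _branch_count(skeletonize(noisy))
        smooth_branches = _branch_count(tr.medial_skeleton2d(noisy))
        assert smooth_branches <= raw_branches


def _branch_count(sk):
    from scipy import ndimage as ndi

    nbrs = ndi.convolve(sk.astype(int), np.ones((3, 3)), mode="constant") - 1
    return int(np.count_nonzero(sk & (nbrs >= 3)))


class TestGradientField:
    @pytest.mark.parametrize(
        "kind",
        ["edt", "poisson", "poisson_point", "poisson_skeleton", "geodesic_point", "geodesic_skeleton"],
    )
    def test_unit_magnitude_and_support(self, kind, disk_mask):
        phi = tr.cell_transform(disk_mask, kind)
        gf = tr.gradient_field(phi, disk_mask)
        mags = np.sqrt((gf.components**2).sum(axis=0))
        assert np.allclose(mags[~disk_mask], 0.0)
        inside = mags[disk_mask]
        assert np.all((inside < 1e-6) | (np.abs(inside - 1) < 1e-6))

    @pytest.mark.parametrize("kind", ["poisson_point", "geodesic_point", "geodesic_skeleton"])
    def test_explicit_sources_attract_all_pixels(self, kind):
        shapes = {
            "disk": None,
            "bar": None,
            "L": _l_mask(),
        }
        m = np.zeros((41, 41), dtype=bool)
        rr, cc = disk((20, 20), 14)
        m[rr, cc] = True
        shapes["disk"] = m
        bar = np.zeros((9, 41), dtype=bool)
        bar[3:6, 3:38] = True
        shapes["bar"] = bar
        for mask in shapes.values():
            phi = tr.cell_transform(mask, kind)
            gf = tr.gradient_field(phi, mask)
            src = np.argwhere(phi.source)
            for start in np.argwhere(mask)[::7]:
                end = _advect2d(start, gf, steps=250)
                d = np.sqrt(np.min(np.sum((src - end) ** 2, axis=1)))
                assert d <= 2.0

    def test_flat_region_zero_vector(self):
        phi = tr.DistanceMap(np.ones((5, 5)), "edt")
        gf = tr.gradient_field(phi, np.ones((5, 5), dtype=bool))
        assert np.allclose(gf.components, 0.0)

    def test_disk_edt_field_points_inward(self, disk_mask):
        gf = tr.gradient_field(tr.edt2d(disk_mask), disk_mask)
        pts = np.argwhere(disk_mask)
        off_center = pts[np.linalg.norm(pts - 20, axis=1) > 5]
        vecs = gf.components[:, off_center[:, 0], off_center[:, 1]].T
        to_center = (20 - off_center) / np.linalg.norm(20 - off_center, axis=1, keepdims=True)
        cos = np.sum(vecs * to_center, axis=1)
        assert np.mean(cos > 0.5) > 0.95


class TestLabelsToGradients:
    def test_two_separated_disks_independent(self):
        sl = np.zeros((40, 80), dtype=np.int32)
        rr, cc = disk((20, 20), 10)
        sl[rr, cc] = 1
        field1, _ = tr.labels_to_gradients(sl, "edt")
        rr2, cc2 = disk((20, 60), 10)
        sl2 = sl.copy()
        sl2[rr2, cc2] = 2
        field2, _ = tr.labels_to_gradients(sl2, "edt")
        assert np.allclose(field1[:, rr, cc], field2[:, rr, cc])

    def test_touching_labels_fields_point_apart(self):
        sl = np.zeros((21, 41), dtype=np.int32)
        sl[5:16, 5:20] = 1
        sl[5:16, 20:35] = 2
        field, _ = tr.labels_to_gradients(sl, "edt")
        # column component on either side of the contact line x=20
        left = field[1, 10, 18]
        right = field[1, 10, 21]
        assert left < 0 and right > 0  # each points into its own cell

    def test_empty_slice(self):
        field, proxy = tr.labels_to_gradients(np.zeros((10, 10), dtype=np.int32), "edt")
        assert not field.any() and not proxy.any()

    def test_proxy_in_unit_range(self, disk_mask):
        sl = disk_mask.astype(np.int32)
        _, proxy = tr.labels_to_gradients(sl, "edt")
        assert proxy.max() == 1.0 and proxy.min() == 0.0
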