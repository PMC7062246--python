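import numpy as np
import pytest
from scipy import stats

from habrisk import background as bg
from habrisk.occurrences import OccurrenceRecord, OccurrenceSet
from habrisk.raster import RasterGrid


def grid(n=80, cell=1.0, x0=-20.0, y0=-20.0):
    return RasterGrid(np.zeros((n, n)), x0=x0, y0=y0, cell_size=cell)


class TestBufferedMcp:
    def test_buffer_one_third_of_max_range_square(self):
        ext = bg.buffered_mcp([(0, 0), (3, 0), (0, 3)])
        assert ext.buffer_distance == pytest.approx(1.0)

    def test_buffer_uses_larger_axis(self):
        ext = bg.buffered_mcp([(0, 0), (6, 0), (0, 3)])
        assert ext.buffer_distance == pytest.approx(2.0)

    def test_two_points_degenerate(self):
        with pytest.raises(bg.DegenerateGeometryError):
            bg.buffered_mcp([(0, 0), (1, 1)])

    def test_collinear_degenerate(self):
        with pytest.raises(bg.DegenerateGeometryError):
            bg.buffered_mcp([(0, 0), (1, 1), (2, 2)])

    def test_contains_presences_with_margin(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 10, size=(25, 2))
        ext = bg.buffered_mcp(pts)
        assert ext.contains_points(pts[:, 0], pts[:, 1]).all()
        # hull vertices keep a margin >= buffer_distance to the boundary
        from shapely.geometry import MultiPoint

        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        for vx, vy in hull.exterior.coords:
            d = ext.polygon.exterior.distance(
                __import__("shapely.geometry", fromlist=["Point"]).Point(vx, vy)
            )
            # round-joint buffers are polygonal approximations; allow
            # the segmentation undershoot (<0.5%)
            assert d >= ext.buffer_distance * 0.995

    def test_per_axis_mode(self):
        ext = bg.buffered_mcp([(0, 0), (6, 0), (0, 3)], buffer_mode="per_axis")
        # right of the hull, within the 2-unit x-buffer
        assert ext.contains_points([7.9], [0.0])[0]


class TestFitKde:
    def test_density_maximal_at_cluster_centroid(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 0.5, size=(200, 2))
        k = bg.fit_kde(pts)
        center = k.pdf(0.0, 0.0)[0]
        assert center > k.pdf(4.0, 4.0)[0]
        assert center > k.pdf(-4.0, 2.0)[0]

    def test_symmetry_about_midline_of_two_clusters(self):
        pts = np.array([[-2.0, 0.0], [2.0, 0.0]])
        k = bg.fit_kde(pts, bandwidth=0.5)
        assert k.pdf(-1.0, 0.3)[0] == pytest.approx(k.pdf(1.0, 0.3)[0])

    def test_integrates_to_one(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1.0, size=(50, 2))
        k = bg.fit_kde(pts)
        g = grid(n=200, cell=0.2)
        dens = k.evaluate_on_grid(g)
        mass = np.nansum(dens.values) * g.cell_area
        assert mass == pytest.approx(1.0, abs=1e-2)

    def test_identical_points_error(self):
        with pytest.raises(bg.DegenerateGeometryError):
            bg.fit_kde([(1.0, 1.0), (1.0, 1.0)])

    def test_scalar_bandwidth_broadcast(self):
        k = bg.fit_kde([(0, 0), (1, 1)], bandwidth=2.0)
        np.testing.assert_allclose(k.bandwidth, [2.0, 2.0])


@pytest.fixture(scope="module")
def kde():
    rng = np.random.default_rng(3)
    pts = rng.normal(0, 2.0, size=(150, 2))
    return bg.fit_kde(pts)


class TestIsopleth:
    def test_contains_centroid(self, kde):
        ext = bg.kde_isopleth(kde, 0.99, grid())
        assert ext.contains_points([0.0], [0.0])[0]

    def test_nesting(self, kde):
        g = grid()
        small = bg.kde_isopleth(kde, 0.50, g)
        big = bg.kde_isopleth(kde, 0.99, g)
        assert np.all(big.mask[small.mask])

    def test_enclosed_mass(self, kde):
        g = grid(n=120, cell=0.5, x0=-30, y0=-30)
        ext = bg.kde_isopleth(kde, 0.99, g)
        dens = kde.evaluate_on_grid(g).values
        frac = dens[ext.mask].sum() / dens.sum()
        assert frac >= 0.99


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(4)
    cluster = rng.normal(0, 1.5, size=(120, 2))
    isolated = np.array([[12.0, 12.0]])
    pts = np.vstack([cluster, isolated])
    kde = bg.fit_kde(pts)
    extent = bg.buffered_mcp(pts)
    return kde, extent


class TestSampleKdeBackground:
    def test_determinism(self, setup):
        kde, extent = setup
        a = bg.sample_kde_background(kde, extent, 200, seed=9, template=grid())
        b = bg.sample_kde_background(kde, extent, 200, seed=9, template=grid())
        np.testing.assert_array_equal(a.points, b.points)

    def test_all_points_inside_extent(self, setup):
        kde, extent = setup
        s = bg.sample_kde_background(kde, extent, 500, seed=10, template=grid())
        assert extent.contains_points(s.points[:, 0], s.points[:, 1]).all()

    def test_sample_density_tracks_kde(self, setup):
        kde, extent = setup
        g = grid(n=30, cell=2.0, x0=-15, y0=-15)
        s = bg.sample_kde_background(kde, extent, 10000, seed=11, template=g)
        counts = np.zeros(g.shape)
        rows, cols = g.cell_of(s.points[:, 0], s.points[:, 1])
        np.add.at(counts, (rows, cols), 1)
        dens = kde.evaluate_on_grid(g).values
        X, Y = g.cell_centers()
        inside = extent.contains_points(X.ravel(), Y.ravel()).reshape(g.shape)
        rho = stats.spearmanr(counts[inside], dens[inside]).statistic
        assert rho > 0.8
        near_cluster = counts[g.cell_of(0.0, 0.0)]
        near_isolated = counts[g.cell_of(12.0, 12.0)]
        assert near_cluster > near_isolated

    def test_chi_square_decreases_with_n(self, setup):
        kde, extent = setup
        g = grid(n=30, cell=2.0, x0=-15, y0=-15)
        dens = kde.evaluate_on_grid(g).values
        X, Y = g.cell_centers()
        inside = extent.contains_points(X.ravel(), Y.ravel()).reshape(g.shape)
        p = np.where(inside, dens, 0.0).ravel()
        p = p / p.sum()
        keep = p > 1e-6
        chis = []
        for n in (1000, 10000):
            s = bg.sample_kde_background(kde, extent, n, seed=12, template=g)
            counts = np.zeros(g.shape)
            rows, cols = g.cell_of(s.points[:, 0], s.points[:, 1])
            np.add.at(counts, (rows, cols), 1)
            observed = counts.ravel()[keep]
            expected = n * p[keep]
            chis.append(float(((observed - expected) ** 2 / expected).sum()) / n)
        assert chis[1] < chis[0]

    def test_disjoint_extent_error(self, setup):
        kde, _ = setup
        far = bg.buffered_mcp([(500, 500), (510, 500), (500, 510)])
        with pytest.raises(bg.SamplingError):
            bg.sample_kde_background(kde, far, 10, seed=1, template=grid())


def _target_set(lifeforms, coords):
    recs = [
        OccurrenceRecord(
            species_name="t", x=float(x), y=float(y), lifeform=lf,
            record_type="observation",
        )
        for (x, y), lf in zip(coords, lifeforms)
    ]
    return OccurrenceSet(recs)


class TestTargetBackground:
    @pytest.fixture
    def region(self):
        return bg.buffered_mcp([(0, 0), (10, 0), (0, 10)])

    def test_lifeform_filter(self, region):
        s = _target_set(
            ["grass"] * 5 + ["forb"] * 5,
            [(i, i % 3) for i in range(10)],
        )
        out = bg.sample_target_background(s, "grass", region, n=100, seed=1)
        assert out.n <= 5
        assert out.method == "target"

    def test_all_outside_region_error(self, region):
        s = _target_set(["grass"] * 3, [(99, 99), (98, 98), (97, 99)])
        with pytest.raises(bg.EmptyTargetError):
            bg.sample_target_background(s, "grass", region, n=10, seed=1)

    def test_no_matching_lifeform_error(self, region):
        s = _target_set(["forb"] * 3, [(1, 1), (2, 2), (3, 1)])
        with pytest.raises(bg.EmptyTargetError):
            bg.sample_target_background(s, "grass", region, n=10, seed=1)

    def test_seeded_subsample_deterministic(self, region):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 8, size=(50, 2))
        s = _target_set(["grass"] * 50, coords)
        a = bg.sample_target_background(s, "grass", region, n=10, seed=2)
        b = bg.sample_target_background(s, "grass", region, n=10, seed=2)
        np.testing.assert_array_equal(a.points, b.points)
        assert a.n == 10
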