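"""Domain segmentation, coverage histograms, shape descriptors, scale calls."""

import networkx as nx
import numpy as np
import pytest

from memdomain.domains import (CoverageHistogram, classify_domain_scale,
                               combined_coverage_histogram, coverage_histogram,
                               detect_vesicle_geometry, find_mesh_domains,
                               histogram_overlap, histogram_pearson,
                               map_surface_signal, planar_shape_descriptors,
                               segment_surface_domains, select_w,
                               shape_descriptors, Domain, DomainSet)
from memdomain.synthetic import (GUVImageSpec, fibonacci_sphere,
                                 gen_guv_stack)
from memdomain.vesicle_mc import MCParams, build_vesicle


# --------------------------------------------------------------------------
# mesh-side components
# --------------------------------------------------------------------------

class TestMeshDomains:
    def test_components_match_networkx_oracle(self, rng):
        v = build_vesicle(MCParams(n_vertices=362, rho=0.3, seed=21))
        ds = find_mesh_domains(v)
        g = nx.Graph()
        dom = np.nonzero(v.vertex_type == 1)[0]
        g.add_nodes_from(dom.tolist())
        for a, b in v.ev:
            if v.vertex_type[a] == 1 and v.vertex_type[b] == 1:
                g.add_edge(int(a), int(b))
        oracle = {frozenset(c) for c in nx.connected_components(g)}
        ours = {frozenset(int(m) for m in d.members) for d in ds.domains}
        assert ours == oracle

    def test_empty_when_no_domain_vertices(self):
        v = build_vesicle(MCParams(n_vertices=162, rho=0.0))
        assert find_mesh_domains(v).domains == []

    def test_isolated_vertex_area_is_third_of_incident_triangles(self):
        v = build_vesicle(MCParams(n_vertices=162, rho=0.0))
        v.vertex_type[10] = 1
        ds = find_mesh_domains(v)
        assert len(ds.domains) == 1
        tris = v.triangles
        incident = tris[(tris == 10).any(axis=1)]
        p = v.pos
        areas = 0.5 * np.linalg.norm(np.cross(
            p[incident[:, 1]] - p[incident[:, 0]],
            p[incident[:, 2]] - p[incident[:, 0]]), axis=1)
        assert ds.domains[0].area == pytest.approx(areas.sum() / 3.0, rel=1e-9)

    def test_areas_bounded_by_surface(self):
        v = build_vesicle(MCParams(n_vertices=362, rho=0.5, seed=2))
        ds = find_mesh_domains(v)
        assert ds.areas().sum() <= ds.total_surface_area


# --------------------------------------------------------------------------
# histograms and w selection
# --------------------------------------------------------------------------

class TestCoverageHistograms:
    def _single_domain_set(self, frac):
        total = 400.0
        return DomainSet(domains=[Domain(members=np.array([0]),
                                         area=frac * total)],
                         source="image", total_surface_area=total)

    def test_single_domain_mass_in_right_bin(self):
        h = coverage_histogram(self._single_domain_set(0.5),
                               bin_edges=np.arange(0, 101, 10.0))
        assert h.counts[5] == 1.0 and h.counts.sum() == 1.0

    def test_two_equal_domains(self):
        total = 400.0
        ds = DomainSet(domains=[Domain(members=np.array([0]), area=0.1 * total),
                                Domain(members=np.array([1]), area=0.1 * total)],
                       source="image", total_surface_area=total)
        h = coverage_histogram(ds)
        assert h.counts[10] == 1.0

    def test_pooled_histogram_matches_per_snapshot_enumeration(self):
        sets = []
        for seed in (1, 2, 3):
            v = build_vesicle(MCParams(n_vertices=362, rho=0.2, seed=seed))
            sets.append(find_mesh_domains(v))
        edges = np.arange(0, 21, 1.0)
        pooled = combined_coverage_histogram(sets, edges)
        cov = np.concatenate([100 * ds.areas() / ds.total_surface_area
                              for ds in sets])
        oracle, _ = np.histogram(np.clip(cov, 0, 20 - 1e-12), bins=edges)
        assert np.allclose(pooled.counts, oracle / oracle.sum())

    def test_overlap_bounds_and_bin_mismatch(self):
        e = np.arange(0, 11, 1.0)
        h1 = CoverageHistogram(e, np.r_[1.0, np.zeros(9)])
        h2 = CoverageHistogram(e, np.r_[np.zeros(9), 1.0])
        assert histogram_overlap(h1, h1) == 1.0
        assert histogram_overlap(h1, h2) == 0.0
        with pytest.raises(ValueError):
            histogram_overlap(h1, CoverageHistogram(e[:-1], h1.counts[:-1]))

    def test_select_w_ties_break_toward_smaller_w(self):
        e = np.arange(0, 11, 1.0)
        h = CoverageHistogram(e, np.full(10, 0.1))
        assert select_w(h, {1.4: h, 1.2: h, 1.3: h}) == 1.2

    def test_pearson_is_symmetric(self):
        e = np.arange(0, 11, 1.0)
        rng = np.random.default_rng(0)
        a = rng.random(10); a /= a.sum()
        b = rng.random(10); b /= b.sum()
        h1, h2 = CoverageHistogram(e, a), CoverageHistogram(e, b)
        assert histogram_pearson(h1, h2) == pytest.approx(
            histogram_pearson(h2, h1))


# --------------------------------------------------------------------------
# planar shape harnesses (closed forms)
# --------------------------------------------------------------------------

class TestPlanarDescriptors:
    def test_rectangle_circularity_closed_form(self):
        s = planar_shape_descriptors([(0, 0), (10, 0), (10, 1), (0, 1)])
        assert s.circularity == pytest.approx(4 * np.pi * 10 / 22**2, abs=1e-6)

    def test_two_to_one_ellipse_roundness(self):
        t = np.linspace(0, 2 * np.pi, 3000, endpoint=False)
        s = planar_shape_descriptors(np.column_stack([2 * np.cos(t),
                                                      np.sin(t)]))
        assert s.roundness == pytest.approx(0.5, abs=1e-3)
        assert s.major_axis == pytest.approx(4.0, abs=2e-3)
        assert s.minor_axis == pytest.approx(2.0, abs=2e-3)

    def test_circle_is_round_and_circular(self):
        t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        s = planar_shape_descriptors(np.column_stack([np.cos(t), np.sin(t)]))
        assert s.circularity == pytest.approx(1.0, abs=1e-3)
        assert s.roundness == pytest.approx(1.0, abs=1e-3)


# --------------------------------------------------------------------------
# surface maps and segmentation
# --------------------------------------------------------------------------

def _analytic_map(n_points, radius, absent_mask_fn, seed=0):
    """SurfaceSignalMap built directly from an analytic absent-region mask."""
    from memdomain.domains import _knn_graph, SurfaceSignalMap
    pts = fibonacci_sphere(n_points)
    absent = absent_mask_fn(pts)
    return SurfaceSignalMap(points=pts, present=~absent,
                            valid=np.ones(n_points, bool),
                            neighbor_graph=_knn_graph(pts), radius=radius)


class TestSegmentation:
    def test_single_absent_point_area(self):
        smap = _analytic_map(4000, 5.0, lambda p: np.arange(len(p)) == 17)
        ds = segment_surface_domains(smap)
        assert len(ds.domains) == 1
        assert ds.domains[0].area == pytest.approx(4 * np.pi * 25 / 4000)

    def test_two_separated_caps_give_two_domains(self):
        def mask(p):
            return (p[:, 2] > np.cos(0.4)) | (p[:, 2] < -np.cos(0.4))
        ds = segment_surface_domains(_analytic_map(4000, 5.0, mask))
        assert len(ds.domains) == 2

    def test_components_match_networkx_oracle(self):
        rng = np.random.default_rng(5)
        def mask(p):
            return rng.random(len(p)) < 0.1
        smap = _analytic_map(1500, 3.0, mask)
        ds = segment_surface_domains(smap)
        g = nx.from_scipy_sparse_array(smap.neighbor_graph)
        absent = set(np.nonzero(~smap.present)[0].tolist())
        sub = g.subgraph(absent)
        oracle = {frozenset(c) for c in nx.connected_components(sub)}
        ours = {frozenset(int(m) for m in d.members) for d in ds.domains}
        assert ours == oracle

    def test_all_absent_yields_single_covering_domain(self):
        smap = _analytic_map(2000, 4.0, lambda p: np.ones(len(p), bool))
        ds = segment_surface_domains(smap)
        assert len(ds.domains) == 1
        assert ds.domains[0].area == pytest.approx(4 * np.pi * 16)


class TestSphericalDescriptors:
    def test_geodesic_cap_is_circular(self):
        smap = _analytic_map(12000, 5.0,
                             lambda p: p[:, 2] > np.cos(np.deg2rad(50)))
        ds = segment_surface_domains(smap)
        sh = shape_descriptors(ds.domains[0], smap)
        assert sh.circularity >= 0.95
        assert sh.roundness >= 0.9
        assert not sh.low_confidence

    def test_stripe_scores_lower_circularity_than_equal_area_cap(self):
        theta = np.deg2rad(60)
        width = 2 * np.arcsin((1 - np.cos(theta)) / 2)
        cap = _analytic_map(12000, 5.0, lambda p: p[:, 2] > np.cos(theta))
        stripe = _analytic_map(12000, 5.0,
                               lambda p: np.abs(p[:, 2]) < np.sin(width / 2))
        sh_cap = shape_descriptors(
            segment_surface_domains(cap).domains[0], cap)
        sh_str = shape_descriptors(
            segment_surface_domains(stripe).domains[0], stripe)
        assert sh_str.circularity < sh_cap.circularity

    def test_descriptor_stability_under_density_doubling(self):
        vals = []
        for n in (8000, 16000):
            smap = _analytic_map(n, 5.0,
                                 lambda p: p[:, 2] > np.cos(np.deg2rad(45)))
            ds = segment_surface_domains(smap)
            vals.append(shape_descriptors(ds.domains[0], smap).circularity)
        assert abs(vals[1] - vals[0]) / vals[0] < 0.05

    def test_tiny_domains_have_undefined_descriptors(self):
        smap = _analytic_map(2000, 4.0, lambda p: np.arange(len(p)) < 2)
        ds = segment_surface_domains(smap)
        assert shape_descriptors(ds.domains[0], smap) is None

    def test_circularity_within_isoperimetric_bound(self):
        smap = _analytic_map(10000, 5.0,
                             lambda p: p[:, 2] > np.cos(np.deg2rad(30)))
        ds = segment_surface_domains(smap)
        sh = shape_descriptors(ds.domains[0], smap)
        assert sh.circularity <= 1.02


# --------------------------------------------------------------------------
# image geometry
# --------------------------------------------------------------------------

class TestImageGeometry:
    def test_center_and_radius_recovery_noiseless(self):
        spec = GUVImageSpec(radius=5.0, voxel_size=(0.2, 0.2, 0.2),
                            shell_sigma=0.25, photon_scale=200,
                            poisson_noise=False, seed=0)
        stack, _ = gen_guv_stack(spec)
        geom = detect_vesicle_geometry(stack)
        assert np.allclose(geom.center, 7.0, atol=0.1)   # half a voxel
        assert geom.radius == pytest.approx(5.0, rel=0.01)

    def test_translation_equivariance(self):
        a = gen_guv_stack(GUVImageSpec(radius=4.0, center=(6.0, 6.0, 6.0),
                                       pad=4.0, poisson_noise=False))[0]
        b = gen_guv_stack(GUVImageSpec(radius=4.0, center=(7.0, 7.0, 7.0),
                                       pad=4.0, poisson_noise=False))[0]
        ga, gb = detect_vesicle_geometry(a), detect_vesicle_geometry(b)
        assert np.allclose(gb.center - ga.center, 1.0, atol=0.05)

    def test_radius_robust_to_poisson_noise(self):
        radii = []
        for seed in range(5):
            spec = GUVImageSpec(radius=5.0, shell_sigma=0.25, photon_scale=50,
                                seed=seed)
            stack, _ = gen_guv_stack(spec)
            radii.append(detect_vesicle_geometry(stack).radius)
        assert np.all(np.abs(np.array(radii) - 5.0) / 5.0 < 0.02)

    def test_homogeneous_shell_all_present(self):
        spec = GUVImageSpec(radius=4.0, photon_scale=300, poisson_noise=False)
        stack, _ = gen_guv_stack(spec)
        geom = detect_vesicle_geometry(stack)
        smap = map_surface_signal(stack, geom, n_points=3000)
        assert smap.present[smap.valid].all()

    def test_planted_cap_solid_angle(self):
        spec = GUVImageSpec(radius=5.0, shell_sigma=0.25, photon_scale=200,
                            domain_plan=[("cap", np.deg2rad(60), (0, 0, 1.0))],
                            seed=3)
        stack, truth = gen_guv_stack(spec)
        geom = detect_vesicle_geometry(stack)
        smap = map_surface_signal(stack, geom, n_points=8000)
        ds = segment_surface_domains(smap)
        biggest = max(ds.domains, key=lambda d: d.area)
        assert biggest.area == pytest.approx(truth.domains[0].area, rel=0.05)

    def test_threshold_above_shell_yields_covering_domain(self):
        spec = GUVImageSpec(radius=4.0, photon_scale=100, poisson_noise=False)
        stack, _ = gen_guv_stack(spec)
        geom = detect_vesicle_geometry(stack)
        smap = map_surface_signal(stack, geom, n_points=3000,
                                  threshold=1e9)
        ds = segment_surface_domains(smap)
        assert len(ds.domains) == 1
        assert ds.domains[0].area == pytest.approx(4 * np.pi * 16, rel=0.01)


class TestScaleClassification:
    @pytest.mark.parametrize("extent_um, expected", [
        (0.160, "nanodomain"),
        (0.670, "microdomain"),
        (0.275, "intermediate"),
    ])
    def test_extent_thresholds(self, extent_um, expected):
        assert classify_domain_scale(extent_um) == expected

    def test_mesh_domain_shapes_use_same_projection(self):
        v = build_vesicle(MCParams(n_vertices=642, rho=0.15, seed=9))
        ds = find_mesh_domains(v)
        big = max(ds.domains, key=lambda d: d.size)
        if big.size >= 3:
            sh = shape_descriptors(big, v)
            assert sh is None or (0 < sh.circularity <= 1.05)
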