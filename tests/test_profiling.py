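"""Guiding-line extraction, path ordering, node detection and profiling."""
import numpy as np
import pytest

from spectromap import beta, masking, profiling, segmentation, synth
from spectromap.errors import ConfigError, SpectromapError
from spectromap.model import BetaConfig
from tests.conftest import annulus


def circle_skeleton(r, shape=(90, 90)):
    c = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    return segmentation.skeletonize_mask(annulus(shape, c, r - 1.5, r + 1.5)), c


def angle_sort_arc_length(skel, center):
    """Independent arc-length oracle for circular loops: order the pixels by
    polar angle and sum consecutive (and closing) Euclidean steps."""
    pix = np.argwhere(skel).astype(float)
    ang = np.arctan2(pix[:, 0] - center[0], pix[:, 1] - center[1])
    pix = pix[np.argsort(ang)]
    diffs = np.diff(np.vstack([pix, pix[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


class TestExtractGuideline:
    def test_annulus_guideline_is_closed_degree2_loop(self):
        from spectromap._pixelgraph import degree_image

        sk = profiling.extract_guideline(annulus((64, 64)))
        assert (degree_image(sk)[sk] == 2).all()

    def test_straight_band_gives_center_line(self):
        band = np.zeros((16, 32), dtype=bool)
        band[7:10, 4:28] = True
        sk = profiling.extract_guideline(band)
        ys = np.nonzero(sk)[0]
        # centre row, allowing the 1-px end hooks thinning leaves behind
        assert (ys == 8).mean() >= 0.9

    def test_discontinuous_band_warns_with_count(self):
        band = np.zeros((32, 32), dtype=bool)
        band[5:8, 2:12] = True
        band[20:23, 2:12] = True
        with pytest.warns(UserWarning, match="2"):
            profiling.extract_guideline(band)

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning):
            sk = profiling.extract_guideline(np.zeros((8, 8), bool))
        assert not sk.any()


class TestOrderPath:
    def test_horizontal_line_left_to_right(self):
        pix = [(5, 4), (5, 2), (5, 3)]
        path = profiling.order_path(pix)
        np.testing.assert_array_equal(path.coords, [[5, 2], [5, 3], [5, 4]])
        assert not path.closed
        np.testing.assert_allclose(path.step_lengths, [1.0, 1.0])

    @pytest.mark.parametrize("r", range(5, 31, 5))
    def test_circle_visits_every_pixel_once_with_exact_length(self, r):
        skel, center = circle_skeleton(r)
        path = profiling.order_path(np.argwhere(skel))
        assert path.closed
        assert len(path) == skel.sum()
        assert len(set(map(tuple, path.coords))) == len(path)
        allowed = {1.0, round(float(np.sqrt(2)), 12)}
        assert {round(float(s), 12) for s in path.step_lengths} <= allowed
        assert path.total_length_px == pytest.approx(
            angle_sort_arc_length(skel, center), abs=1e-9
        )

    def test_loop_starts_topmost_leftmost_and_goes_clockwise(self):
        skel, _ = circle_skeleton(10)
        path = profiling.order_path(np.argwhere(skel))
        start = tuple(path.coords[0])
        assert start == min(map(tuple, np.argwhere(skel)))
        assert path.coords[1][1] >= start[1]  # heads rightward (clockwise, y down)

    def test_single_pixel_path(self):
        path = profiling.order_path([(3, 3)])
        assert len(path) == 1 and path.total_length_px == 0.0

    def test_branching_input_rejected(self):
        plus = [(5, 5), (4, 5), (6, 5), (5, 4), (5, 6)]
        with pytest.raises(ConfigError):
            profiling.order_path(plus)


class TestNodesAndSegments:
    def test_single_ring(self):
        skel, _ = circle_skeleton(12)
        g = profiling.detect_nodes_and_segments(skel)
        assert (g.n_nodes, g.n_segments) == (0, 1)
        assert g.segments[0].closed

    def test_plus_sign(self):
        plus = np.zeros((21, 21), dtype=bool)
        plus[10, 2:19] = True
        plus[2:19, 10] = True
        g = profiling.detect_nodes_and_segments(plus)
        assert (g.n_nodes, g.n_segments) == (1, 4)

    def test_crossing_rings_match_pixel_graph_oracle(self):
        import networkx as nx

        a = segmentation.skeletonize_mask(annulus((64, 96), (32, 36), 11, 14))
        b = segmentation.skeletonize_mask(annulus((64, 96), (32, 60), 11, 14))
        skel = a | b
        g = profiling.detect_nodes_and_segments(skel)
        # oracle: build the pixel adjacency graph, delete degree>=3 pixels,
        # count the remaining connected components
        G = nx.Graph()
        pix = list(map(tuple, np.argwhere(skel)))
        G.add_nodes_from(pix)
        for y, x in pix:
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dy or dx) and (y + dy, x + dx) in G:
                        G.add_edge((y, x), (y + dy, x + dx))
        node_pix = [p for p in G if G.degree(p) >= 3]
        merged = nx.number_connected_components(G.subgraph(node_pix)) if node_pix else 0
        H = G.copy()
        H.remove_nodes_from(node_pix)
        assert g.n_nodes == merged
        assert g.n_segments == nx.number_connected_components(H)

    def test_segment_lengths_sum_to_skeleton_length(self):
        a = segmentation.skeletonize_mask(annulus((64, 96), (32, 36), 11, 14))
        b = segmentation.skeletonize_mask(annulus((64, 96), (32, 60), 11, 14))
        g = profiling.detect_nodes_and_segments(a | b)
        total_px = sum(len(s) for s in g.segments) + sum(len(n) for n in g.nodes)
        assert total_px == (a | b).sum()


class TestProfileAlong:
    def _ring_beta(self, fraction_a=0.5, noise=0.0, seed=0, radius=16):
        spec = synth.two_phase_ring_spec(
            fraction_a=fraction_a, noise_sigma=noise, seed=seed, radius=radius
        )
        stack, gt = synth.make_vesicle_scene(spec)
        params = __import__("spectromap").model.MaskingParams(
            snr_k=3.0, threshold_channels={"0": 1.0, "1": 1.0},
            compress_enabled=True, gamma=0.5,
        )
        ms = masking.build_masks(stack, params)
        bm = beta.compute_beta_map(stack, ms.membrane_mask, BetaConfig())
        sk = profiling.extract_guideline(ms.membrane_mask)
        path = profiling.order_path(np.argwhere(sk))
        return stack, gt, ms, bm, path

    def test_uniform_ring_constant_trajectory(self):
        values = np.full((64, 64), np.nan)
        ring = annulus((64, 64))
        values[ring] = 0.4
        sk = profiling.extract_guideline(ring)
        path = profiling.order_path(np.argwhere(sk))
        for element in (("square", 3), ("line", 5)):
            traj = profiling.profile_along(path, values, element, 1.0)
            np.testing.assert_allclose(traj.beta, 0.4)

    def test_delta_x_starts_at_zero_and_grows(self):
        _, _, _, bm, path = self._ring_beta()
        traj = profiling.profile_along(path, bm.values, ("square", 3), 0.1)
        assert traj.delta_x_um[0] == 0.0
        assert (np.diff(traj.delta_x_um) > 0).all()
        assert len(traj.delta_x_um) == len(path)

    def test_two_phase_plateaus_recovered_within_one_percent(self):
        _, gt, _, bm, path = self._ring_beta()
        traj = profiling.profile_along(path, bm.values, ("square", 3), 0.1)
        v = traj.beta
        hi, lo = np.median(v[v > 0.2]), np.median(v[v < -0.2])
        assert hi == pytest.approx(1 / 3, rel=0.01)
        assert lo == pytest.approx(-1 / 3, rel=0.01)

    def test_transition_zone_bounded_by_element_extent(self):
        _, _, _, bm, path = self._ring_beta()
        k = 3
        traj = profiling.profile_along(path, bm.values, ("square", k), 1.0)
        v = traj.beta
        in_transition = (np.abs(v - 1 / 3) > 0.01) & (np.abs(v + 1 / 3) > 0.01)
        assert in_transition.sum() <= 2 * (k + 2)  # two phase boundaries

    def test_larger_element_smooths_noisy_plateaus(self):
        stack, gt, _, bm, path = self._ring_beta(noise=8.0, seed=11, radius=20)
        cy = (stack.shape_yx[0] - 1) / 2.0
        ang = np.arctan2(path.coords[:, 0] - cy, path.coords[:, 1] - cy) % (2 * np.pi)
        margin = (7 / 2 + 3) / 20.0
        d_b = np.minimum(ang % np.pi, np.pi - (ang % np.pi))
        interior = d_b > margin
        stds = []
        for k in (3, 5, 7):
            traj = profiling.profile_along(path, bm.values, ("square", k), 1.0)
            va = traj.beta[interior & (ang < np.pi)]
            vb = traj.beta[interior & (ang >= np.pi)]
            stds.append((np.std(va), np.std(vb)))
        assert stds[0][0] >= stds[1][0] >= stds[2][0]
        assert stds[0][1] >= stds[1][1] >= stds[2][1]

    def test_element_fully_off_image_yields_nan(self):
        values = np.full((8, 8), np.nan)
        path = profiling.order_path([(0, 0), (0, 1), (0, 2)])
        traj = profiling.profile_along(path, values, ("square", 3), 1.0)
        assert np.isnan(traj.beta).all()


class TestRecenter:
    def test_zero_radius_is_identity(self):
        skel, _ = circle_skeleton(10)
        path = profiling.order_path(np.argwhere(skel))
        assert profiling.recenter_guideline(path, np.ones((90, 90)), 0) is path

    def test_recentring_never_moves_away_from_ridge(self):
        img = np.zeros((90, 90))
        c = (44.5, 44.5)
        ring = annulus((90, 90), c, r_in=9, r_out=11)
        img[ring] = 100.0
        skel, _ = circle_skeleton(10)
        path = profiling.order_path(np.argwhere(skel))
        out = profiling.recenter_guideline(path, img, 2)

        def ridge_err(coords):
            d = np.hypot(coords[:, 0] - c[0], coords[:, 1] - c[1])
            return np.abs(d - 10.0)

        # stays on the ridge to within re-rasterization jitter (< 1/2 px)
        assert ridge_err(out.coords).mean() <= ridge_err(path.coords).mean() + 0.1
        assert ridge_err(out.coords).mean() < 0.5

    def test_offset_path_recentres_onto_bright_ring(self):
        img = np.zeros((90, 90))
        c = (44.5, 44.5)
        ring = annulus((90, 90), c, 11.5, 14.5)
        img[ring] = 100.0
        inner, _ = circle_skeleton(10)  # guiding line 3 px inside the ridge
        path = profiling.order_path(np.argwhere(inner))
        out = profiling.recenter_guideline(path, img, 5)
        yy, xx = out.coords[:, 0], out.coords[:, 1]
        dist = np.hypot(yy - c[0], xx - c[1])
        moved_out = (dist > 10.5).mean()
        assert moved_out >= 0.8  # most pixels moved toward the ridge


class TestColocalizeAndSplit:
    def test_third_channel_copy_matches_beta(self):
        values = np.full((64, 64), np.nan)
        ring = annulus((64, 64))
        values[ring] = 0.25
        sk = profiling.extract_guideline(ring)
        path = profiling.order_path(np.argwhere(sk))
        traj = profiling.profile_along(path, values, ("square", 3), 1.0)
        traj = profiling.colocalize(traj, path, values, 1.0)
        np.testing.assert_allclose(traj.coloc, traj.beta)

    def test_constant_third_channel_zero_variance(self):
        skel, _ = circle_skeleton(10)
        path = profiling.order_path(np.argwhere(skel))
        traj = profiling.profile_along(path, np.ones((90, 90)), ("square", 3), 1.0)
        traj = profiling.colocalize(traj, path, np.full((90, 90), 7.0), 1.0)
        assert np.std(traj.coloc) == 0.0

    def test_enrichment_exclusion_anticorrelates(self):
        spec = synth.FixtureSpec(
            shape=(96, 96), n_channels=2, seed=5, noise_sigma=1.0,
            objects=[synth.RingSpec(center=(47.5, 47.5), radius=30, width=3,
                     phases=[synth.PhaseSpec(1.0, (120.0, 120.0))])],
        )
        stack, gt = synth.make_contact_scene(spec, arc_span_deg=90,
                                             enrichment=3.0, exclusion=3.0)
        params = __import__("spectromap").model.MaskingParams(
            snr_k=3.0, threshold_channels={"0": 1.0, "1": 1.0},
            compress_enabled=True, gamma=0.5,
        )
        ms = masking.build_masks(stack, params)
        sk = profiling.extract_guideline(ms.membrane_mask)
        path = profiling.order_path(np.argwhere(sk))
        ta = profiling.profile_along(path, stack.plane(0, 0, 0).astype(float), ("square", 3), 0.1)
        tb = profiling.profile_along(path, stack.plane(0, 0, 1).astype(float), ("square", 3), 0.1)
        assert np.corrcoef(ta.beta, tb.beta)[0, 1] < 0

    def test_split_half_and_half(self):
        vals = np.array([0.3] * 50 + [-0.3] * 50)
        out = profiling.split_by_threshold(vals)
        assert out["fraction_high"] == 0.5
        assert out["median_high"] == pytest.approx(0.3)
        assert out["median_low"] == pytest.approx(-0.3)

    def test_split_explicit_threshold_all_high(self):
        out = profiling.split_by_threshold(np.array([0.1, 0.2, 0.3]), threshold=0.0)
        assert out["fraction_high"] == 1.0

    def test_split_all_nan_raises(self):
        with pytest.raises(SpectromapError):
            profiling.split_by_threshold(np.full(5, np.nan))

    def test_seventy_thirty_ring_fraction(self):
        spec = synth.two_phase_ring_spec(fraction_a=0.7)
        stack, _ = synth.make_vesicle_scene(spec)
        params = __import__("spectromap").model.MaskingParams(
            snr_k=3.0, threshold_channels={"0": 1.0, "1": 1.0},
            compress_enabled=True, gamma=0.5,
        )
        ms = masking.build_masks(stack, params)
        bm = beta.compute_beta_map(stack, ms.membrane_mask, BetaConfig())
        sk = profiling.extract_guideline(ms.membrane_mask)
        path = profiling.order_path(np.argwhere(sk))
        traj = profiling.profile_along(path, bm.values, ("square", 3), 0.1)
        out = profiling.split_by_threshold(traj, threshold=0.0)
        assert out["fraction_high"] == pytest.approx(0.70, abs=0.02)
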