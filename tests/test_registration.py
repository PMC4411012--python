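"""Rigid transforms, stitching, blob matching, RANSAC and stack alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arraytomo.benchmark import stack_alignment_benchmark
from arraytomo.errors import (
    InsufficientPointsError,
    NoConsensusError,
    NoSignalError,
    StitchGraphError,
)
from arraytomo.registration import (
    RigidTransform2D,
    align_stack,
    detect_blobs,
    estimate_pairwise_offset,
    estimate_rigid_ransac,
    register_session,
    stitch_mosaic,
)
from arraytomo.simulate import (
    ChannelModel,
    SceneSpec,
    apply_session_transform,
    generate_scene,
    tile_mosaic,
)

finite = st.floats(-50, 50, allow_nan=False)
angles = st.floats(-180, 180, allow_nan=False)


class TestRigidTransform:
    @given(t=angles, dx=finite, dy=finite)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_compose_inverse_roundtrip(self, t, dx, dy):
        T = RigidTransform2D(t, dx, dy)
        r = T.compose(T.inverse())
        assert abs(r.theta) < 1e-9 and abs(r.dx) < 1e-9 and abs(r.dy) < 1e-9

    @given(t1=angles, t2=angles, d=st.tuples(finite, finite, finite, finite))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_composition_matches_sequential_application(self, t1, t2, d):
        A = RigidTransform2D(t1, d[0], d[1])
        B = RigidTransform2D(t2, d[2], d[3])
        pts = np.array([[0.0, 0.0], [10.0, -5.0], [3.3, 7.7]])
        center = (4.0, 4.0)
        np.testing.assert_allclose(
            A.compose(B).apply(pts, center), B.apply(A.apply(pts, center), center),
            atol=1e-8,
        )

    def test_warp_moves_content_by_translation(self):
        img = np.zeros((40, 40))
        img[10, 12] = 100.0
        out = RigidTransform2D(0, 5, -3).warp(img)
        assert np.unravel_index(out.argmax(), out.shape) == (15, 9)


class TestPairwiseOffset:
    def test_exact_self_match(self):
        rng = np.random.default_rng(0)
        img = rng.random((200, 120)) * 100
        tile_a, tile_b = img[:120, :], img[40:160, :]
        dx, dy, conf = estimate_pairwise_offset(tile_a, tile_b, (40, 0), 10)
        assert (dx, dy) == (40, 0)
        assert conf > 0.99

    def test_offset_recovery_under_noise(self):
        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            base = np.kron(rng.random((40, 24)), np.ones((5, 5))) * 100  # structured
            a = base[:120, :] + rng.normal(0, 10, (120, 120))
            b = base[40:160, :] + rng.normal(0, 10, (120, 120))
            dx, dy, _ = estimate_pairwise_offset(a, b, (38, 1), 8)
            if abs(dx - 40) <= 1 and abs(dy - 0) <= 1:
                hits += 1
        assert hits == 8

    def test_pure_noise_has_low_confidence(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(100, 100)), rng.normal(size=(100, 100))
        _, _, conf = estimate_pairwise_offset(a, b, (0, 0), 5)
        assert conf < 0.2

    def test_constant_overlap_is_no_signal(self):
        with pytest.raises(NoSignalError):
            estimate_pairwise_offset(np.zeros((50, 50)), np.zeros((50, 50)), (0, 0), 3)


class TestStitchMosaic:
    def _tiles_and_offsets(self, img, tile_shape, overlap):
        tiles = tile_mosaic(img, tile_shape, overlap)
        origins = np.array([o for o, _ in tiles], dtype=float)
        offsets = []
        for i in range(len(tiles)):
            for j in range(i + 1, len(tiles)):
                if np.abs(origins[j] - origins[i]).max() <= tile_shape[0]:
                    offsets.append((i, j, tuple(origins[j] - origins[i])))
        return [t for _, t in tiles], origins, offsets

    def test_exact_offsets_recover_truth(self):
        rng = np.random.default_rng(1)
        img = rng.random((200, 200)) * 100
        tiles, truth, offsets = self._tiles_and_offsets(img, (120, 120), 0.3)
        layout, fused = stitch_mosaic(tiles, offsets)
        np.testing.assert_allclose(layout.origins, truth - truth[0], atol=1e-9)
        assert fused.shape == img.shape
        np.testing.assert_allclose(fused, img, atol=1e-9)

    def test_perturbed_offsets_average_out(self):
        rng = np.random.default_rng(2)
        img = rng.random((200, 200))
        tiles, truth, offsets = self._tiles_and_offsets(img, (120, 120), 0.3)
        noisy = [
            (i, j, (d[0] + rng.choice([-1, 1]), d[1] + rng.choice([-1, 1])))
            for i, j, d in offsets
        ]
        layout, _ = stitch_mosaic(tiles, noisy)
        err = layout.origins - (truth - truth[0])
        assert np.sqrt((err**2).mean()) <= 1.0

    def test_single_tile_identity(self):
        layout, fused = stitch_mosaic([np.ones((10, 10))], [])
        np.testing.assert_array_equal(layout.origins, [[0, 0]])

    def test_disconnected_graph_rejected(self):
        tiles = [np.ones((10, 10))] * 3
        with pytest.raises(StitchGraphError):
            stitch_mosaic(tiles, [(0, 1, (5.0, 0.0))])


class TestDetectBlobs:
    def test_single_nucleus_found_at_center(self):
        gx, gy = np.mgrid[0:80, 0:80]
        img = 1000 * np.exp(-(((gx - 40.3) ** 2 + (gy - 37.6) ** 2)) / (2 * 8.0**2))
        blobs = detect_blobs(img, (1000.0, 2500.0))
        assert blobs.shape[0] == 1
        assert np.hypot(blobs[0, 0] - 40.3, blobs[0, 1] - 37.6) <= 1.0

    def test_planted_nuclei_recovered_without_duplicates(self):
        rng = np.random.default_rng(3)
        centers = []
        while len(centers) < 30:
            c = rng.uniform(15, 240, 2)
            if all(np.linalg.norm(c - o) > 24 for o in centers):
                centers.append(c)
        gx, gy = np.mgrid[0:256, 0:256]
        img = np.zeros((256, 256))
        for cx, cy in centers:
            img += 1000 * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * 6.0**2))
        blobs = detect_blobs(img, (600.0, 1500.0))
        d = np.linalg.norm(
            np.asarray(centers)[:, None, :] - blobs[None, :, :2], axis=2
        )
        assert (d.min(axis=1) <= 1.0).sum() >= 29
        # no two detections within 2 px
        bb = blobs[:, :2]
        pair = np.linalg.norm(bb[:, None, :] - bb[None, :, :], axis=2)
        np.fill_diagonal(pair, np.inf)
        assert pair.min() > 2.0

    def test_constant_image_yields_empty_set(self):
        assert detect_blobs(np.full((50, 50), 9.0)).shape == (0, 3)


class TestRansac:
    def _spread_points(self, rng, n=30):
        return rng.uniform(0, 200, size=(n, 2))

    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        a = self._spread_points(rng)
        truth = RigidTransform2D(5.0, 10.0, -3.0)
        b = truth.apply(a)
        fit, inliers = estimate_rigid_ransac(a, b, seed=1)
        assert fit.theta == pytest.approx(5.0, abs=1e-6)
        assert fit.dx == pytest.approx(10.0, abs=1e-6)
        assert fit.dy == pytest.approx(-3.0, abs=1e-6)
        assert inliers.all()

    def test_robust_to_outliers_and_noise(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = self._spread_points(rng, 40)
            truth = RigidTransform2D(-4.0, 6.0, 9.0)
            b = truth.apply(a) + rng.normal(0, 0.5, a.shape)
            n_out = 12  # 30% outliers
            b[:n_out] = rng.uniform(0, 200, (n_out, 2))
            fit, _ = estimate_rigid_ransac(a, b, inlier_tolerance_px=2.0, seed=seed)
            assert abs(fit.theta + 4.0) <= 0.5
            assert np.hypot(fit.dx - 6.0, fit.dy - 9.0) <= 0.5

    def test_identical_sets_give_identity(self):
        rng = np.random.default_rng(2)
        a = self._spread_points(rng)
        fit, _ = estimate_rigid_ransac(a, a, seed=0)
        assert fit.is_identity(tol=1e-9)

    def test_insufficient_points(self):
        with pytest.raises(InsufficientPointsError):
            estimate_rigid_ransac(np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]]))

    def test_no_consensus_on_scrambled_points(self):
        rng = np.random.default_rng(3)
        a = self._spread_points(rng, 20)
        b = rng.uniform(0, 200, (20, 2))
        with pytest.raises(NoConsensusError):
            estimate_rigid_ransac(a, b, inlier_tolerance_px=0.05, iterations=200, seed=0)


def _nuclei_scene(seed=0):
    return generate_scene(
        SceneSpec(
            shape=(256, 256, 1),
            synapse_density=0.0,
            channels={"DAPI-1": ChannelModel(kind="nuclei", amplitude_mean=30000.0, amplitude_sd=0.0)},
            nucleus_count=40,
            nucleus_radius_nm=1500.0,
            noise_sd=3000.0,
            seed=seed,
        )
    )


class TestRegisterSession:
    def test_recovers_planted_transform(self):
        scene = _nuclei_scene(seed=1)
        moved = apply_session_transform(scene, ["DAPI-1"], 2.0, (6.0, -4.0), seed=1)
        ref = scene.rendered.get_channel("DAPI-1").section(0)
        mov = moved.rendered.get_channel("DAPI-1").section(0)
        fit = register_session(ref, mov, seed=1)
        assert abs(fit.theta - 2.0) <= 0.5
        assert np.hypot(fit.dx - 6.0, fit.dy + 4.0) <= 0.5

    def test_identical_sessions_give_identity(self):
        scene = _nuclei_scene(seed=2)
        ref = scene.rendered.get_channel("DAPI-1").section(0)
        fit = register_session(ref, ref.copy(), seed=0)
        assert abs(fit.theta) <= 0.1 and np.hypot(fit.dx, fit.dy) <= 0.1

    def test_blob_free_session_fails_cleanly(self):
        rng = np.random.default_rng(0)
        flat = rng.normal(1000, 5, (128, 128))
        with pytest.raises((NoConsensusError, NoSignalError)):
            register_session(flat, flat + rng.normal(0, 5, flat.shape), seed=0)

    def test_transform_is_channel_independent(self):
        # warping any channel with the recovered session transform must
        # land planted content at the same residual
        scene = generate_scene(
            SceneSpec(
                shape=(192, 192, 1),
                synapse_density=1.0,
                channels={
                    "DAPI-1": ChannelModel(kind="nuclei", amplitude_mean=30000.0, amplitude_sd=0.0),
                    "PSD95-1": ChannelModel(participation=0.9),
                },
                nucleus_count=25,
                nucleus_radius_nm=1500.0,
                noise_sd=1000.0,
                seed=4,
            )
        )
        moved = apply_session_transform(scene, ["DAPI-1", "PSD95-1"], 1.5, (4.0, 3.0), seed=4)
        ref = scene.rendered.get_channel("DAPI-1").section(0)
        mov = moved.rendered.get_channel("DAPI-1").section(0)
        fit = register_session(ref, mov, seed=4)
        inv = fit.inverse()
        for name in ("DAPI-1", "PSD95-1"):
            orig = scene.rendered.get_channel(name).section(0)
            back = inv.warp(moved.rendered.get_channel(name).section(0))
            inner = (slice(20, -20), slice(20, -20))
            r = np.corrcoef(orig[inner].ravel(), back[inner].ravel())[0, 1]
            assert r > 0.95


class TestAlignStack:
    def test_reduces_planted_jitter(self):
        res = stack_alignment_benchmark(seed=0)
        assert res["planted_rms_px"] > 1.2
        assert res["residual_rms_px"] <= 0.5

    def test_aligned_stack_maps_to_near_identity(self):
        spec = SceneSpec(
            shape=(96, 96, 8),
            synapse_density=2.0,
            channels={"Synapsin1-1": ChannelModel(participation=1.0)},
            noise_sd=1000.0,
            seed=5,
        )
        chan = generate_scene(spec).rendered.get_channel("Synapsin1-1")
        chain = align_stack(chan)
        # adjacent 70 nm sections carry genuinely different content, so
        # per-pair subpixel estimates wander by a few hundredths of a px
        # and chaining accumulates a little of it
        for t in chain:
            assert np.hypot(t.dx, t.dy) <= 0.25 and abs(t.theta) <= 0.1

    def test_realigning_aligned_stack_is_near_identity(self):
        from arraytomo.registration import warp_volume

        spec = SceneSpec(
            shape=(128, 128, 12),
            synapse_density=2.0,
            channels={"Synapsin1-1": ChannelModel(participation=1.0)},
            noise_sd=2000.0,
            seed=9,
        )
        scene = generate_scene(spec)
        jittered = apply_session_transform(
            scene, ["Synapsin1-1"], per_section_jitter=1.4, seed=10
        )
        chan = jittered.rendered.get_channel("Synapsin1-1")
        aligned = warp_volume(chan, align_stack(chan))
        chain2 = align_stack(aligned)
        assert max(np.hypot(t.dx, t.dy) for t in chain2) <= 0.2

    def test_two_section_stack(self):
        rng = np.random.default_rng(6)
        base = rng.random((64, 64)) * 1000
        shifted = RigidTransform2D(0, 3, -2).warp(base)
        stack = np.stack([base, shifted], axis=2)
        chain = align_stack(stack)
        assert len(chain) == 2
        # anchor is section 1; section 0 must move by (3, -2) to match it
        assert chain[1].is_identity(tol=1e-9)
        assert chain[0].dx == pytest.approx(3, abs=0.2)
        assert chain[0].dy == pytest.approx(-2, abs=0.2)

    def test_single_section_rejected(self):
        with pytest.raises(InsufficientPointsError):
            align_stack(np.zeros((10, 10, 1)))
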