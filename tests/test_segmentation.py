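"""Vesselness, mask operations and surface extraction."""

from collections import deque

import numpy as np
import pytest
import trimesh

from aneugrowth.meshes import DomeMesh, boundary_loops
from aneugrowth.morphology import close_dome, compute_features
from aneugrowth.segmentation import (
    extract_surface,
    remove_small_components,
    threshold_merge,
    vesselness_filter,
)
from aneugrowth.synthetic import generate_dome, generate_vessel_tube, rasterize
from aneugrowth.volume import VolumeImage


def make_volume(voxels, spacing=1.0):
    return VolumeImage(np.asarray(voxels), np.full(3, spacing), np.zeros(3))


def flood_fill_components(mask):
    """Brute-force 26-connected labelling oracle (BFS)."""
    mask = np.asarray(mask) > 0
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        q = deque([start])
        labels[start] = current
        while q:
            x, y, z = q.popleft()
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= p[i] < mask.shape[i] for i in range(3)) and mask[p] and not labels[p]:
                    labels[p] = current
                    q.append(p)
    return labels, current


class TestVesselness:
    def test_constant_volume_zero_response(self):
        vol = make_volume(np.full((20, 20, 20), 5.0))
        resp = vesselness_filter(vol, [1.0])
        assert resp.voxels.max() < 1e-6

    def test_cylinder_contrast(self):
        n, sp = 64, 0.5
        x, y, _ = np.meshgrid(*[np.arange(n) * sp] * 3, indexing="ij")
        c = n * sp / 2
        cyl = (((x - c) ** 2 + (y - c) ** 2) <= 4.0).astype(float) * 100
        resp = vesselness_filter(make_volume(cyl, sp), [2.0])
        centerline = resp.voxels[(np.abs(x - c) < sp / 2) & (np.abs(y - c) < sp / 2)]
        background = resp.voxels[((x - c) ** 2 + (y - c) ** 2) > 25]
        assert centerline.mean() > 10 * max(background.mean(), 1e-12)

    def test_ball_scores_below_cylinder_with_blob_suppression(self):
        n, sp = 48, 0.5
        coords = np.meshgrid(*[np.arange(n) * sp] * 3, indexing="ij")
        c = n * sp / 2
        ball = ((sum((a - c) ** 2 for a in coords)) <= 4.0).astype(float) * 100
        cyl = (((coords[0] - c) ** 2 + (coords[1] - c) ** 2) <= 4.0).astype(float) * 100
        r_ball = vesselness_filter(make_volume(ball, sp), [2.0], response="frangi")
        r_cyl = vesselness_filter(make_volume(cyl, sp), [2.0], response="frangi")
        ci = int(round(c / sp))
        assert r_ball.voxels[ci, ci, ci] < r_cyl.voxels[ci, ci, ci]

    def test_invalid_scales(self):
        vol = make_volume(np.zeros((5, 5, 5)))
        with pytest.raises(ValueError):
            vesselness_filter(vol, [])
        with pytest.raises(ValueError):
            vesselness_filter(vol, [-1.0])


class TestThresholdMerge:
    def test_infinite_thresholds_empty_mask(self, rng):
        a = make_volume(rng.random((6, 6, 6)))
        b = a.with_voxels(rng.random((6, 6, 6)))
        assert threshold_merge(a, b, np.inf, np.inf).voxels.sum() == 0

    def test_minus_infinity_full_mask(self, rng):
        a = make_volume(rng.random((6, 6, 6)))
        b = a.with_voxels(rng.random((6, 6, 6)))
        assert threshold_merge(a, b, -np.inf, np.inf).voxels.all()

    def test_matches_voxelwise_brute_force(self, rng):
        for _ in range(10):
            a = make_volume(rng.random((7, 5, 6)))
            b = a.with_voxels(rng.random((7, 5, 6)))
            t1, t2 = rng.random(2)
            got = threshold_merge(a, b, t1, t2).voxels.astype(bool)
            want = (a.voxels >= t1) | (b.voxels >= t2)
            assert np.array_equal(got, want)

    def test_grid_mismatch_rejected(self, rng):
        a = make_volume(rng.random((6, 6, 6)))
        b = make_volume(rng.random((5, 6, 6)))
        with pytest.raises(ValueError):
            threshold_merge(a, b, 0.5, 0.5)


class TestRemoveSmallComponents:
    def test_59_removed_60_kept(self):
        vox = np.zeros((20, 20, 10), dtype=np.uint8)
        vox[1:6, 1:5, 1:4] = 1          # 5*4*3 = 60 voxels
        small = np.zeros_like(vox)
        small[10:15, 10:14, 1:4] = 1    # 60
        small[10, 10, 1] = 0            # -> 59
        vox |= small
        out = remove_small_components(make_volume(vox), min_voxels=60)
        assert out.voxels[1:6, 1:5, 1:4].all()
        assert out.voxels[10:15, 10:14, 1:4].sum() == 0

    def test_empty_mask_stays_empty(self):
        out = remove_small_components(make_volume(np.zeros((5, 5, 5), np.uint8)))
        assert out.voxels.sum() == 0

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(20):
            vox = (rng.random((14, 14, 14)) < 0.12).astype(np.uint8)
            k = int(rng.integers(2, 8))
            got = remove_small_components(make_volume(vox), min_voxels=k).voxels.astype(bool)
            labels, n = flood_fill_components(vox)
            counts = np.bincount(labels.ravel())
            want = np.zeros_like(vox, dtype=bool)
            for comp in range(1, n + 1):
                if counts[comp] >= k:
                    want |= labels == comp
            assert np.array_equal(got, want)

    def test_idempotent_and_never_adds(self, rng):
        vox = (rng.random((12, 12, 12)) < 0.15).astype(np.uint8)
        vol = make_volume(vox)
        once = remove_small_components(vol, 5)
        twice = remove_small_components(once, 5)
        assert np.array_equal(once.voxels, twice.voxels)
        assert not (once.voxels & ~vox).any()


class TestExtractSurface:
    def test_sphere_volume_and_nonshrinking(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
        mask = rasterize(sphere, 0.25, margin=1.0)
        smoothed = extract_surface(mask, smoothing_iterations=10)
        raw = extract_surface(mask, smoothing_iterations=0)
        exact = 4 * np.pi * 125 / 3
        assert smoothed.volume == pytest.approx(exact, rel=0.03)
        assert abs(smoothed.volume - raw.volume) / raw.volume < 0.02

    def test_single_voxel_octahedron(self):
        vox = np.zeros((5, 5, 5), np.uint8)
        vox[2, 2, 2] = 1
        mesh = extract_surface(make_volume(vox), smoothing_iterations=0)
        assert mesh.is_watertight
        # marching cubes turns one voxel into the dual octahedron, volume h^3/6
        assert mesh.volume == pytest.approx(1.0 / 6.0, rel=1e-6)

    def test_solid_block_watertight(self):
        vox = np.zeros((10, 10, 10), np.uint8)
        vox[2:8, 2:8, 2:8] = 1
        mesh = extract_surface(make_volume(vox), smoothing_iterations=5)
        assert mesh.is_watertight
        assert len(boundary_loops(mesh)) == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_surface(make_volume(np.zeros((4, 4, 4), np.uint8)))

    def test_volume_error_decreases_with_resolution(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
        exact = 4 * np.pi * 125 / 3
        errs = []
        for spacing in (0.5, 0.25):
            mask = rasterize(sphere, spacing, margin=1.0)
            mesh = extract_surface(mask, smoothing_iterations=10)
            errs.append(abs(mesh.volume - exact) / exact)
        assert errs[1] < errs[0]


class TestFullChain:
    def test_recovers_dome_nsi_from_tube_dome_phantom(self):
        dome = generate_dome(5.0, neck_ratio=0.8, irregularity=0.2, lobulations=1, subdivisions=4, seed=2)
        src_nsi = compute_features(dome).nsi
        closed = close_dome(dome)
        tube = generate_vessel_tube(1.5, 20.0, 0.0, subdivisions=3)
        tube.apply_translation([-10.0, 0.0, -0.9 * 1.5])
        sp = 0.2
        vd = rasterize(closed, sp, margin=1.0)
        vt = rasterize(tube, sp, margin=1.0)
        origin = np.minimum(vd.origin, vt.origin)
        top = np.maximum(
            vd.origin + (np.array(vd.shape) - 1) * sp,
            vt.origin + (np.array(vt.shape) - 1) * sp,
        )
        n = np.round((top - origin) / sp).astype(int) + 1
        vox = np.zeros(tuple(n), np.uint8)
        for v in (vd, vt):
            off = np.round((v.origin - origin) / sp).astype(int)
            vox[tuple(slice(o, o + d) for o, d in zip(off, v.shape))] |= v.voxels
        intensity = VolumeImage(vox * 100.0, np.full(3, sp), origin)
        filtered = vesselness_filter(intensity, [1.5])
        mask = threshold_merge(intensity, filtered, 50.0, 0.95)
        mask = remove_small_components(mask, 60)
        mesh = extract_surface(mask)
        # isolate the dome at the known neck plane and re-measure
        clipped = trimesh.intersections.slice_mesh_plane(
            mesh, plane_normal=[0, 0, 1], plane_origin=[0, 0, 7 * sp], cap=False
        )
        clipped = trimesh.Trimesh(vertices=clipped.vertices, faces=clipped.faces, process=True)
        clipped.update_faces(clipped.nondegenerate_faces())
        clipped.remove_unreferenced_vertices()
        apex = clipped.vertices[:, 2].argmax()
        part = next(
            p for p in clipped.split(only_watertight=False) if np.isclose(p.vertices[:, 2].max(), clipped.vertices[apex, 2])
        )
        rec_nsi = compute_features(DomeMesh.from_mesh(part)).nsi
        assert abs(rec_nsi - src_nsi) < 0.05
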