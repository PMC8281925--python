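"""Geometry oracles and invariances for the five morphologic indices."""

import numpy as np
import pytest
import trimesh

from aneugrowth.meshes import DomeMesh, as_trimesh
from aneugrowth.morphology import (
    aspect_ratio,
    close_dome,
    compute_features,
    fit_neck_frame,
    hmax,
    nsi,
    surface_area,
    volume,
)
from aneugrowth.synthetic import generate_cohort, generate_dome, GeneratorConfig

from conftest import random_rigid_motion


def tetra_sum_volume(mesh, ref):
    """Independent volume oracle: sum of signed tetrahedra to an arbitrary
    reference point."""
    v = mesh.vertices - ref
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


class TestAreaVolume:
    def test_unit_cube_exact(self):
        cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        assert surface_area(cube) == pytest.approx(6.0, abs=1e-12)
        assert volume(cube) == pytest.approx(1.0, abs=1e-12)

    def test_icosphere_closed_forms(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        assert surface_area(sphere) == pytest.approx(4 * np.pi, rel=0.01)
        assert volume(sphere) == pytest.approx(4 * np.pi / 3, rel=0.01)

    def test_volume_requires_closed_mesh(self, hemisphere_dome):
        with pytest.raises(ValueError, match="close"):
            volume(hemisphere_dome.mesh)

    def test_rigid_motion_invariance(self, rng):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
        R, t = random_rigid_motion(rng)
        moved = as_trimesh(sphere.vertices @ R.T + t, sphere.faces)
        assert surface_area(moved) == pytest.approx(surface_area(sphere), rel=1e-9)
        assert volume(moved) == pytest.approx(volume(sphere), rel=1e-9)

    def test_volume_against_tetra_sum_oracle(self, hemisphere_dome, rng):
        closed = close_dome(hemisphere_dome)
        ref = rng.normal(scale=10.0, size=3)
        assert volume(closed) == pytest.approx(tetra_sum_volume(closed, ref), rel=1e-9)


class TestNSI:
    def test_hemisphere_identity_exact(self):
        # V = 2*pi/3 and SA = 2*pi satisfy (18 pi)^(1/3) V^(2/3) = SA exactly
        assert nsi(2 * np.pi / 3, 2 * np.pi) == pytest.approx(0.0, abs=1e-12)

    def test_full_sphere_value(self):
        # 1 - 2^(-1/3) evaluated for V = 4*pi/3, SA = 4*pi
        assert nsi(4 * np.pi / 3, 4 * np.pi) == pytest.approx(0.2063, abs=1e-3)

    def test_scale_invariance(self):
        v, sa = 3.7, 14.2
        assert nsi(8 * v, 4 * sa) == pytest.approx(nsi(v, sa), rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            nsi(0.0, 1.0)
        with pytest.raises(ValueError):
            nsi(1.0, -2.0)

    def test_increases_with_radial_perturbation(self):
        values = [
            compute_features(
                generate_dome(5.0, neck_ratio=1.0, irregularity=a, subdivisions=4, seed=9)
            ).nsi
            for a in (0.0, 0.1, 0.2)
        ]
        assert values[0] < values[1] < values[2]


class TestNeckFrame:
    def test_hemisphere_plane_and_width(self, hemisphere_dome):
        frame = fit_neck_frame(hemisphere_dome)
        axis = np.array([0.0, 0.0, 1.0])
        angle = np.degrees(np.arccos(np.clip(abs(frame.plane_normal @ axis), -1, 1)))
        assert angle < 1.0
        assert frame.neck_width == pytest.approx(5.0, rel=0.01)

    def test_planar_loop_lies_on_plane(self, hemisphere_dome):
        frame = fit_neck_frame(hemisphere_dome)
        pts = hemisphere_dome.mesh.vertices[hemisphere_dome.neck_loop]
        dist = (pts - frame.plane_point) @ frame.plane_normal
        assert np.abs(dist).max() < 1e-9

    def test_equivariance_under_rotation(self, hemisphere_dome, rng):
        R, t = random_rigid_motion(rng)
        moved = DomeMesh(
            mesh=as_trimesh(hemisphere_dome.mesh.vertices @ R.T + t, hemisphere_dome.mesh.faces),
            neck_loop=hemisphere_dome.neck_loop,
        )
        f0 = fit_neck_frame(hemisphere_dome)
        f1 = fit_neck_frame(moved)
        assert f1.neck_width == pytest.approx(f0.neck_width, rel=1e-9)
        assert np.allclose(f1.plane_point, R @ f0.plane_point + t, atol=1e-9)
        assert np.allclose(np.abs(f1.plane_normal @ (R @ f0.plane_normal)), 1.0, atol=1e-9)

    def test_collinear_loop_rejected(self):
        verts = np.array([[float(i), 0.0, 0.0] for i in range(4)] + [[1.5, 0.0, 1.0]])
        faces = np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4]])
        mesh = as_trimesh(verts, faces)
        dome = DomeMesh(mesh=mesh, neck_loop=np.array([0, 1, 2, 3]))
        with pytest.raises(ValueError):
            fit_neck_frame(dome)


class TestCloseDome:
    def test_hemisphere_watertight_volume(self, hemisphere_dome):
        closed = close_dome(hemisphere_dome)
        assert closed.is_watertight
        assert volume(closed) == pytest.approx(2 * np.pi * 2.5 ** 3 / 3, rel=0.01)

    def test_closed_input_rejected(self):
        sphere = trimesh.creation.icosphere(subdivisions=2)
        with pytest.raises(ValueError):
            close_dome(DomeMesh(mesh=sphere, neck_loop=np.array([0])))

    def test_reflection_leaves_volume_unchanged(self, hemisphere_dome):
        # double reflection = rotation; unsigned volume must also survive one
        refl = np.diag([-1.0, 1.0, 1.0])
        mirrored = DomeMesh.from_mesh(
            as_trimesh(hemisphere_dome.mesh.vertices @ refl, hemisphere_dome.mesh.faces[:, ::-1])
        )
        assert volume(close_dome(mirrored)) == pytest.approx(
            volume(close_dome(hemisphere_dome)), rel=1e-9
        )


class TestHmaxAspectRatio:
    def test_hemisphere_values(self, hemisphere_dome):
        frame = fit_neck_frame(hemisphere_dome)
        assert hmax(hemisphere_dome, frame) == pytest.approx(2.5, rel=0.01)
        assert aspect_ratio(hemisphere_dome, frame) == pytest.approx(0.5, rel=0.02)

    def test_hmax_brute_force_and_homogeneity(self, rng):
        dome = generate_dome(4.0, neck_ratio=0.7, irregularity=0.2, lobulations=1, seed=5)
        frame = fit_neck_frame(dome)
        brute = max(np.linalg.norm(v - frame.plane_point) for v in dome.mesh.vertices)
        assert hmax(dome, frame) == pytest.approx(brute, rel=1e-12)
        doubled = DomeMesh(mesh=as_trimesh(dome.mesh.vertices * 2.0, dome.mesh.faces), neck_loop=dome.neck_loop)
        f2 = fit_neck_frame(doubled)
        assert hmax(doubled, f2) == pytest.approx(2 * hmax(dome, frame), rel=1e-9)

    def test_elongated_half_ellipsoid(self, hemisphere_dome):
        # stretch the hemisphere 3x along its axis: height 3r over width 2r
        stretched = DomeMesh(
            mesh=as_trimesh(hemisphere_dome.mesh.vertices * np.array([1.0, 1.0, 3.0]), hemisphere_dome.mesh.faces),
            neck_loop=hemisphere_dome.neck_loop,
        )
        frame = fit_neck_frame(stretched)
        assert aspect_ratio(stretched, frame) == pytest.approx(1.5, rel=0.02)

    def test_ar_scale_invariance(self, hemisphere_dome):
        frame = fit_neck_frame(hemisphere_dome)
        scaled = DomeMesh(
            mesh=as_trimesh(hemisphere_dome.mesh.vertices * 3.7, hemisphere_dome.mesh.faces),
            neck_loop=hemisphere_dome.neck_loop,
        )
        assert aspect_ratio(scaled, fit_neck_frame(scaled)) == pytest.approx(
            aspect_ratio(hemisphere_dome, frame), rel=1e-9
        )


class TestComputeFeatures:
    def test_hemisphere_reference_values(self, hemisphere_dome):
        f = compute_features(hemisphere_dome)
        assert f.hmax == pytest.approx(2.5, rel=0.01)
        assert f.ar == pytest.approx(0.5, rel=0.02)
        assert f.nsi < 0.05

    def test_rigid_motion_invariance_of_all_features(self, rng):
        dome = generate_dome(5.0, neck_ratio=0.75, irregularity=0.2, lobulations=2, seed=11)
        R, t = random_rigid_motion(rng)
        moved = DomeMesh(mesh=as_trimesh(dome.mesh.vertices @ R.T + t, dome.mesh.faces), neck_loop=dome.neck_loop)
        f0, f1 = compute_features(dome), compute_features(moved)
        assert np.allclose(f0.as_array(), f1.as_array(), rtol=1e-6)

    def test_scaling_laws(self):
        dome = generate_dome(5.0, neck_ratio=0.75, irregularity=0.15, lobulations=1, seed=3)
        s = 2.0
        scaled = DomeMesh(mesh=as_trimesh(dome.mesh.vertices * s, dome.mesh.faces), neck_loop=dome.neck_loop)
        f0, f1 = compute_features(dome), compute_features(scaled)
        assert f1.volume == pytest.approx(s ** 3 * f0.volume, rel=1e-9)
        assert f1.surface_area == pytest.approx(s ** 2 * f0.surface_area, rel=1e-9)
        assert f1.hmax == pytest.approx(s * f0.hmax, rel=1e-9)
        assert f1.nsi == pytest.approx(f0.nsi, rel=1e-9)
        assert f1.ar == pytest.approx(f0.ar, rel=1e-9)

    def test_total_over_cohort_no_nans(self):
        cases = generate_cohort(GeneratorConfig(n_growing=5, n_stable=4, mesh_subdivisions=3, seed=2))
        rows = np.stack([compute_features(c.dome).as_array() for c in cases])
        assert rows.shape == (9, 5)
        assert np.isfinite(rows).all()
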