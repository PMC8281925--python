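"""Synthetic aneurysm-cohort generator.

Stands in for a clinical cohort of saccular intracranial aneurysms: each
case is an open dome mesh clipped at the neck, optionally fused onto a
parent-vessel tube, with a binary growing/stable label.  The two classes
share the same size distribution (size is deliberately non-predictive)
and differ only in surface irregularity: growing-like domes carry a
larger amplitude of smooth radial noise and lobulation bumps, which
raises their non-sphericity index.

Everything is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .meshes import DomeMesh, LabeledCase, as_trimesh
from .volume import VolumeImage


@dataclass
class GeneratorConfig:
    """Cohort-level generation parameters.

    Defaults emulate a small clinical growth-surveillance cohort:
    44 cases split 25 growing / 19 stable, dome sizes 1.4-12.2 mm
    (log-uniform, median ~4 mm), and irregularity amplitudes chosen so
    that an NSI threshold separates the classes only moderately
    (univariate AUC in the 0.6-0.7 range on a 200-case cohort).
    Per-case amplitude is the class amplitude times a Gamma(2, 1/2)
    multiplier (mean 1), giving within-class shape heterogeneity.
    """

    n_growing: int = 25
    n_stable: int = 19
    dome_height_range: tuple[float, float] = (1.4, 12.2)   # mm
    neck_ratio_range: tuple[float, float] = (0.55, 0.95)   # unitless
    irregularity_growing: float = 0.24                     # fraction of dome radius
    irregularity_stable: float = 0.07
    lobulation_count_range: tuple[int, int] = (0, 3)
    vessel_radius: float = 1.5                             # mm
    mesh_subdivisions: int = 4
    include_vasculature: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_growing < 0 or self.n_stable < 0:
            raise ValueError("case counts must be non-negative")
        if self.irregularity_growing < 0 or self.irregularity_stable < 0:
            raise ValueError("irregularity amplitudes must be non-negative")
        if not (0 < self.dome_height_range[0] <= self.dome_height_range[1]):
            raise ValueError("dome_height_range must be a positive interval")
        if not (0 < self.neck_ratio_range[0] <= self.neck_ratio_range[1] <= 1):
            raise ValueError("neck_ratio_range must lie in (0, 1]")
        if self.vessel_radius <= 0:
            raise ValueError("vessel_radius must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        d = json.loads(Path(path).read_text())
        for key in ("dome_height_range", "neck_ratio_range", "lobulation_count_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# parent-vessel tube

def generate_vessel_tube(
    radius: float,
    length: float,
    bend_curvature: float = 0.0,
    subdivisions: int = 3,
    seed: int = 0,
) -> trimesh.Trimesh:
    """Closed tube following a circular arc of the given curvature (1/mm).

    ``bend_curvature = 0`` yields a straight cylinder along +x.  The seed
    is accepted for interface uniformity; the tube itself is a
    deterministic function of the geometric arguments.
    """
    del seed
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    n_phi = 4 * 2 ** subdivisions
    n_seg = max(8, n_phi)
    t = np.linspace(0.0, length, n_seg + 1)
    if abs(bend_curvature) < 1e-12:
        centers = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
        tangents = np.tile([1.0, 0.0, 0.0], (n_seg + 1, 1))
    else:
        # arc of radius R in the xz-plane, arc length parameterised
        R = 1.0 / bend_curvature
        ang = t / R
        centers = np.column_stack([R * np.sin(ang), np.zeros_like(t), R * (1 - np.cos(ang))])
        tangents = np.column_stack([np.cos(ang), np.zeros_like(t), np.sin(ang)])
    # frame: y axis is a global normal (arc stays in xz-plane)
    normal = np.array([0.0, 1.0, 0.0])
    binormals = np.cross(tangents, normal)
    binormals /= np.linalg.norm(binormals, axis=1, keepdims=True)
    phi = 2 * np.pi * np.arange(n_phi) / n_phi
    ring = np.cos(phi)[:, None] * normal[None, :]  # (n_phi, 3) per-section offsets
    verts = (
        centers[:, None, :]
        + radius * np.cos(phi)[None, :, None] * normal[None, None, :]
        + radius * np.sin(phi)[None, :, None] * binormals[:, None, :]
    ).reshape(-1, 3)
    del ring

    def vid(i: int, k: int) -> int:
        return i * n_phi + (k % n_phi)

    faces = []
    for i in range(n_seg):
        for k in range(n_phi):
            a, b = vid(i, k), vid(i, k + 1)
            c, d = vid(i + 1, k), vid(i + 1, k + 1)
            faces.append([a, c, d])
            faces.append([a, d, b])
    # end caps: fan to section centres
    start_c = len(verts)
    end_c = start_c + 1
    verts = np.vstack([verts, centers[0][None, :], centers[-1][None, :]])
    for k in range(n_phi):
        faces.append([start_c, vid(0, k + 1), vid(0, k)])
        faces.append([end_c, vid(n_seg, k), vid(n_seg, k + 1)])
    mesh = as_trimesh(verts, np.asarray(faces))
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# dome

def _smooth_field(rng: np.random.Generator, n_waves: int = 6) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random low-frequency field on the unit sphere: sum of plane-wave cosines."""
    dirs = rng.normal(size=(n_waves, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    freq = rng.uniform(1.5, 3.5, size=n_waves)
    amp = rng.normal(size=n_waves)
    phase = rng.uniform(0, 2 * np.pi, size=n_waves)
    # normalise so the field has unit RMS over the sphere
    amp = amp / np.sqrt(np.sum(amp ** 2) / 2.0)
    return dirs * freq[:, None], amp, phase


def generate_dome(
    height: float,
    neck_ratio: float = 0.8,
    irregularity: float = 0.0,
    lobulations: int = 0,
    subdivisions: int = 4,
    seed: int = 0,
) -> DomeMesh:
    """Open dome: a sphere cap cut at the neck plane, radially perturbed.

    ``neck_ratio`` is neck width over maximal dome diameter; 1 gives an
    exact hemisphere of radius ``height``.  ``irregularity`` is the RMS
    fractional radial perturbation; ``lobulations`` adds that many
    Gaussian bumps whose amplitude scales with ``irregularity``.  The
    perturbation is tapered to zero at the neck, so the neck loop stays
    an exact planar circle, and the finished dome is rescaled so that
    its maximal extent from the neck centroid equals ``height`` —
    irregularity therefore changes shape, never size.
    """
    if height <= 0:
        raise ValueError("height must be positive")
    if not (0 < neck_ratio <= 1):
        raise ValueError("neck_ratio must lie in (0, 1]")
    if irregularity < 0:
        raise ValueError("irregularity must be non-negative")
    if lobulations < 0:
        raise ValueError("lobulations must be non-negative")
    rng = np.random.default_rng(seed)

    n_phi = 4 * 2 ** subdivisions
    n_rings = n_phi // 2
    z0 = -np.sqrt(max(0.0, 1.0 - neck_ratio ** 2))  # cut plane on the unit sphere
    theta_neck = np.arccos(z0)

    theta = theta_neck * np.arange(1, n_rings + 1) / n_rings
    phi = 2 * np.pi * np.arange(n_phi) / n_phi
    st, ct = np.sin(theta), np.cos(theta)
    pts = np.empty((1 + n_rings * n_phi, 3))
    pts[0] = (0.0, 0.0, 1.0)  # apex
    grid = np.stack(
        [
            np.outer(st, np.cos(phi)),
            np.outer(st, np.sin(phi)),
            np.outer(ct, np.ones(n_phi)),
        ],
        axis=-1,
    )  # (n_rings, n_phi, 3)
    pts[1:] = grid.reshape(-1, 3)

    if irregularity > 0:
        waves, amp, phase = _smooth_field(rng)
        f = np.cos(pts @ waves.T + phase[None, :]) @ amp
        bump = np.zeros(len(pts))
        for _ in range(lobulations):
            centre = rng.normal(size=3)
            centre[2] = abs(centre[2]) + 0.2  # bumps live on the upper dome
            centre /= np.linalg.norm(centre)
            sigma = rng.uniform(0.25, 0.5)
            b_amp = rng.uniform(1.0, 2.0)
            ang = np.arccos(np.clip(pts @ centre, -1.0, 1.0))
            bump += b_amp * np.exp(-0.5 * (ang / sigma) ** 2)
        theta_all = np.arccos(np.clip(pts[:, 2], -1.0, 1.0))
        taper = 1.0 - (theta_all / theta_neck) ** 2  # exactly 0 on the neck ring
        radial = 1.0 + irregularity * (f + bump) * taper
        radial = np.maximum(radial, 0.2)  # guard against self-intersection
        pts = pts * radial[:, None]

    # faces: apex fan + quad strips
    faces = [[0, 1 + k, 1 + (k + 1) % n_phi] for k in range(n_phi)]
    for i in range(n_rings - 1):
        up = 1 + i * n_phi
        lo = 1 + (i + 1) * n_phi
        for k in range(n_phi):
            k1 = (k + 1) % n_phi
            faces.append([up + k, lo + k, lo + k1])
            faces.append([up + k, lo + k1, up + k1])

    # neck plane to z=0, then scale so max extent from neck centroid = height
    pts[:, 2] -= z0
    scale = height / np.linalg.norm(pts, axis=1).max()
    pts *= scale
    mesh = as_trimesh(pts, np.asarray(faces))
    dome = DomeMesh.from_mesh(mesh)
    return dome


# ---------------------------------------------------------------------------
# rasterization (voxel-centre parity test along z columns)

def rasterize(mesh: trimesh.Trimesh, voxel_spacing: float, margin: float = 1.0) -> VolumeImage:
    """Binary occupancy volume of a closed mesh on an axis-aligned grid.

    A voxel is inside when its centre has odd crossing parity along the
    z column, which is exact for watertight meshes up to the grid
    resolution.
    """
    if voxel_spacing <= 0:
        raise ValueError("voxel_spacing must be positive")
    if not mesh.is_watertight:
        raise ValueError("rasterize requires a closed (watertight) mesh")
    s = float(voxel_spacing)
    lo = mesh.bounds[0] - margin
    hi = mesh.bounds[1] + margin
    # tiny irrational offset avoids rays hitting vertices/edges exactly
    origin = lo + s * np.array([1.37e-4, 2.41e-4, 3.53e-4])
    n = np.maximum(np.ceil((hi - origin) / s).astype(int) + 1, 1)
    nx, ny, nz = (int(v) for v in n)

    tri = mesh.triangles  # (m, 3, 3)
    cols: list[np.ndarray] = []
    zs: list[np.ndarray] = []
    for v0, v1, v2 in tri:
        e1 = v1[:2] - v0[:2]
        e2 = v2[:2] - v0[:2]
        area2 = e1[0] * e2[1] - e1[1] * e2[0]
        if abs(area2) < 1e-14:
            continue  # vertical triangle: no z crossing
        xmin, xmax = min(v0[0], v1[0], v2[0]), max(v0[0], v1[0], v2[0])
        ymin, ymax = min(v0[1], v1[1], v2[1]), max(v0[1], v1[1], v2[1])
        i0 = max(0, int(np.ceil((xmin - origin[0]) / s)))
        i1 = min(nx - 1, int(np.floor((xmax - origin[0]) / s)))
        j0 = max(0, int(np.ceil((ymin - origin[1]) / s)))
        j1 = min(ny - 1, int(np.floor((ymax - origin[1]) / s)))
        if i1 < i0 or j1 < j0:
            continue
        xs = origin[0] + s * np.arange(i0, i1 + 1)
        ys = origin[1] + s * np.arange(j0, j1 + 1)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        px = X - v0[0]
        py = Y - v0[1]
        # barycentric coordinates in the xy projection
        b1 = (px * e2[1] - py * e2[0]) / area2
        b2 = (e1[0] * py - e1[1] * px) / area2
        inside = (b1 >= 0) & (b2 >= 0) & (b1 + b2 <= 1)
        if not inside.any():
            continue
        z = v0[2] + b1 * (v1[2] - v0[2]) + b2 * (v2[2] - v0[2])
        I, J = np.nonzero(inside)
        cols.append(((I + i0) * ny + (J + j0)).astype(np.int64))
        zs.append(z[inside])
    if not cols:
        raise ValueError("mesh has empty interior at this resolution")
    col = np.concatenate(cols)
    z = np.concatenate(zs)
    order = np.lexsort((z, col))
    col, z = col[order], z[order]

    vox = np.zeros((nx, ny, nz), dtype=np.uint8)
    starts = np.flatnonzero(np.r_[True, col[1:] != col[:-1]])
    ends = np.r_[starts[1:], len(col)]
    oz = origin[2]
    for a, b in zip(starts, ends):
        crossings = z[a:b]
        c = col[a]
        i, j = divmod(int(c), ny)
        m = len(crossings) - (len(crossings) % 2)
        for p in range(0, m, 2):
            k0 = max(0, int(np.ceil((crossings[p] - oz) / s)))
            k1 = min(nz - 1, int(np.floor((crossings[p + 1] - oz) / s)))
            if k1 >= k0:
                vox[i, j, k0 : k1 + 1] = 1
    if vox.sum() == 0:
        raise ValueError("mesh has empty interior at this resolution")
    return VolumeImage(voxels=vox, spacing=np.full(3, s), origin=origin)


# ---------------------------------------------------------------------------
# cohort

def _fuse_dome_vessel(
    dome: DomeMesh, vessel_radius: float, height: float, subdivisions: int
) -> trimesh.Trimesh:
    """Boolean union of the neck-closed dome and a vessel tube, via a
    shared occupancy grid and surface re-extraction (robust against the
    near-tangent contact that defeats mesh-based CSG)."""
    from .morphology import close_dome
    from .segmentation import extract_surface

    closed = close_dome(dome)
    length = 4.0 * height + 6.0 * vessel_radius
    tube = generate_vessel_tube(vessel_radius, length, 0.0, subdivisions=max(2, subdivisions - 1))
    # dome neck plane is z=0; sink the tube so its surface pokes just above it
    tube.apply_translation([-length / 2.0, 0.0, -0.9 * vessel_radius])
    spacing = max(max(height, 2 * vessel_radius) / 64.0, 0.05)
    vol_d = rasterize(closed, spacing, margin=2 * spacing)
    vol_t = rasterize(tube, spacing, margin=2 * spacing)
    # merge the two masks on a common grid covering both
    origin = np.minimum(vol_d.origin, vol_t.origin)
    top = np.maximum(
        vol_d.origin + (np.array(vol_d.shape) - 1) * spacing,
        vol_t.origin + (np.array(vol_t.shape) - 1) * spacing,
    )
    n = np.round((top - origin) / spacing).astype(int) + 1
    vox = np.zeros(tuple(n), dtype=np.uint8)
    for v in (vol_d, vol_t):
        off = np.round((v.origin - origin) / spacing).astype(int)
        sl = tuple(slice(o, o + d) for o, d in zip(off, v.shape))
        vox[sl] |= v.voxels.astype(np.uint8)
    mask = VolumeImage(voxels=vox, spacing=np.full(3, spacing), origin=origin)
    return extract_surface(mask, smoothing_iterations=5)


def generate_cohort(config: GeneratorConfig) -> list[LabeledCase]:
    """Labelled synthetic cohort per the configuration."""
    cases: list[LabeledCase] = []
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_growing + config.n_stable
    children = ss.spawn(n_total)
    labels = ["growing"] * config.n_growing + ["stable"] * config.n_stable
    lo, hi = config.dome_height_range
    for idx, (label, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        height = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        neck_ratio = float(rng.uniform(*config.neck_ratio_range))
        base_amp = (
            config.irregularity_growing if label == "growing" else config.irregularity_stable
        )
        irregularity = float(base_amp * rng.gamma(shape=2.0, scale=0.5))
        lob_lo, lob_hi = config.lobulation_count_range
        lobulations = int(rng.integers(lob_lo, lob_hi + 1))
        dome_seed = int(rng.integers(0, 2 ** 31 - 1))
        dome = generate_dome(
            height=height,
            neck_ratio=neck_ratio,
            irregularity=irregularity,
            lobulations=lobulations,
            subdivisions=config.mesh_subdivisions,
            seed=dome_seed,
        )
        vasculature = None
        if config.include_vasculature:
            vasculature = _fuse_dome_vessel(
                dome, config.vessel_radius, height, config.mesh_subdivisions
            )
        cases.append(
            LabeledCase(
                case_id=f"case_{idx:03d}",
                dome=dome,
                label=label,
                vasculature=vasculature,
                params={
                    "height_mm": height,
                    "neck_ratio": neck_ratio,
                    "irregularity": irregularity,
                    "lobulations": lobulations,
                    "dome_seed": dome_seed,
                },
            )
        )
    return cases


def write_cohort(cases: list[LabeledCase], out_dir: str | Path, config: GeneratorConfig | None = None) -> None:
    """Persist a cohort: PLY meshes plus a CSV manifest (and config JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        dome_path = out / f"{case.case_id}_dome.ply"
        case.dome.save(dome_path)
        row = {"case_id": case.case_id, "label": case.label, **case.params}
        if case.vasculature is not None:
            vasc_path = out / f"{case.case_id}_vasculature.ply"
            case.vasculature.export(str(vasc_path))
            row["vasculature_file"] = vasc_path.name
        row["dome_file"] = dome_path.name
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    if config is not None:
        config.to_json(out / "config.json")


def load_cohort(in_dir: str | Path) -> list[LabeledCase]:
    """Load a cohort previously written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    cases = []
    for _, row in manifest.iterrows():
        dome = DomeMesh.load(in_dir / row["dome_file"])
        vasculature = None
        if "vasculature_file" in row and isinstance(row.get("vasculature_file"), str):
            vasculature = trimesh.load_mesh(str(in_dir / row["vasculature_file"]), process=False)
        params = {
            k: row[k]
            for k in ("height_mm", "neck_ratio", "irregularity", "lobulations", "dome_seed")
            if k in row
        }
        cases.append(
            LabeledCase(
                case_id=row["case_id"],
                dome=dome,
                label=row["label"],
                vasculature=vasculature,
                params=params,
            )
        )
    return cases
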