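"""Morphologic indices of an isolated aneurysm dome.

Five indices characterise dome size and shape:

* ``hmax`` — maximal distance (mm) from the neck centroid to any dome vertex,
  the 3D analogue of the clinically measured aneurysm size;
* ``volume`` — enclosed volume (mm^3) of the dome closed at the neck;
* ``surface_area`` — area (mm^2) of the open dome surface (neck cap excluded);
* ``nsi`` — non-sphericity index ``1 - (18*pi)^(1/3) * V^(2/3) / SA``, zero for
  an exact hemispherical dome and growing with surface irregularity and
  elongation;
* ``ar`` — aspect ratio: perpendicular dome height over neck width.

With the hemispherical reference, V = 2*pi*r^3/3 and SA (dome only) = 2*pi*r^2
give ``(18*pi)^(1/3) * V^(2/3) = 2*pi*r^2`` identically, hence NSI = 0.  The
neck cap created when closing the dome is an artefact of the closure and is
deliberately excluded from SA; including it would shift the hemisphere from
0 to 1/3.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .meshes import DomeMesh, as_trimesh, boundary_loops

_NSI_CONST = (18.0 * np.pi) ** (1.0 / 3.0)

FEATURE_NAMES = ("hmax", "volume", "surface_area", "nsi", "ar")


@dataclass
class MorphologyFeatures:
    hmax: float          # mm
    volume: float        # mm^3
    surface_area: float  # mm^2
    nsi: float           # unitless
    ar: float            # unitless

    def as_array(self) -> np.ndarray:
        return np.array([self.hmax, self.volume, self.surface_area, self.nsi, self.ar])


@dataclass
class NeckFrame:
    """Least-squares neck plane with a caliper neck width."""

    plane_point: np.ndarray   # neck centroid, mm
    plane_normal: np.ndarray  # unit vector pointing into the dome
    neck_width: float         # mm, max pairwise distance of projected loop vertices


def fit_neck_frame(dome: DomeMesh) -> NeckFrame:
    """Fit the neck plane and measure the neck width.

    The plane is the total-least-squares plane of the neck-loop vertices;
    its normal is oriented toward the dome centroid.  Neck width is the
    caliper (maximal pairwise) diameter of the loop projected onto the
    plane, which stays meaningful for non-circular necks.
    """
    loops = boundary_loops(dome.mesh)
    if len(loops) != 1:
        raise ValueError(f"dome must have exactly one boundary loop, found {len(loops)}")
    pts = dome.mesh.vertices[dome.neck_loop]
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    # smallest right-singular vector = plane normal
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("neck loop is collinear; plane is undefined")
    normal = vt[2]
    dome_centroid = dome.mesh.vertices.mean(axis=0)
    if np.dot(dome_centroid - centroid, normal) < 0:
        normal = -normal
    proj = centred - np.outer(centred @ normal, normal)
    d2 = ((proj[:, None, :] - proj[None, :, :]) ** 2).sum(axis=2)
    width = float(np.sqrt(d2.max()))
    if width <= 0:
        raise ValueError("neck width is zero")
    return NeckFrame(plane_point=centroid, plane_normal=normal, neck_width=width)


def close_dome(dome: DomeMesh) -> trimesh.Trimesh:
    """Close the neck aperture with a triangle fan to the loop centroid.

    The cap triangles reverse the boundary-edge direction induced by the
    dome faces, so the winding of the closed mesh stays consistent.
    """
    loops = boundary_loops(dome.mesh)
    if len(loops) == 0:
        raise ValueError("mesh is already closed: no boundary loop to cap")
    if len(loops) > 1:
        raise ValueError("dome is non-manifold: multiple boundary loops")
    loop = loops[0]
    verts = dome.mesh.vertices
    centroid = verts[loop].mean(axis=0)
    c_idx = len(verts)
    new_verts = np.vstack([verts, centroid[None, :]])
    nxt = np.roll(loop, -1)
    cap = np.column_stack([nxt, loop, np.full(len(loop), c_idx)])
    new_faces = np.vstack([dome.mesh.faces, cap])
    closed = as_trimesh(new_verts, new_faces)
    return closed


def surface_area(mesh: trimesh.Trimesh) -> float:
    """Total triangle area in mm^2."""
    return float(mesh.area)


def volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume (mm^3) of a closed mesh by the divergence theorem."""
    if len(boundary_loops(mesh)) != 0:
        raise ValueError("mesh is open; close it first (see close_dome)")
    return float(abs(mesh.volume))


def nsi(volume_mm3: float, dome_surface_area_mm2: float) -> float:
    """Non-sphericity index from neck-closed volume and open-dome area."""
    if volume_mm3 <= 0 or dome_surface_area_mm2 <= 0:
        raise ValueError("volume and surface area must be positive")
    return float(1.0 - _NSI_CONST * volume_mm3 ** (2.0 / 3.0) / dome_surface_area_mm2)


def hmax(dome: DomeMesh, frame: NeckFrame) -> float:
    """Maximal distance from the neck centroid to any dome vertex (mm)."""
    verts = dome.mesh.vertices
    if len(verts) == 0:
        raise ValueError("dome has no vertices")
    return float(np.linalg.norm(verts - frame.plane_point, axis=1).max())


def aspect_ratio(dome: DomeMesh, frame: NeckFrame) -> float:
    """Perpendicular dome height over neck width."""
    if frame.neck_width <= 0:
        raise ValueError("neck width must be positive")
    heights = (dome.mesh.vertices - frame.plane_point) @ frame.plane_normal
    return float(heights.max() / frame.neck_width)


def compute_features(dome: DomeMesh) -> MorphologyFeatures:
    """All five indices for one dome."""
    frame = fit_neck_frame(dome)
    closed = close_dome(dome)
    v = volume(closed)
    sa = surface_area(dome.mesh)  # open dome only: cap excluded from SA
    return MorphologyFeatures(
        hmax=hmax(dome, frame),
        volume=v,
        surface_area=sa,
        nsi=nsi(v, sa),
        ar=aspect_ratio(dome, frame),
    )


def features_table(domes: dict[str, DomeMesh]) -> pd.DataFrame:
    """Feature rows for a set of named domes."""
    rows = []
    for case_id, dome in domes.items():
        f = compute_features(dome)
        rows.append(
            {
                "case_id": case_id,
                "hmax_mm": f.hmax,
                "volume_mm3": f.volume,
                "surface_area_mm2": f.surface_area,
                "nsi": f.nsi,
                "ar": f.ar,
            }
        )
    return pd.DataFrame(rows)


def write_features(domes: dict[str, DomeMesh], path: str | Path) -> pd.DataFrame:
    df = features_table(domes)
    df.to_csv(path, index=False)
    return df
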