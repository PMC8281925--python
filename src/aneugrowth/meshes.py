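"""Mesh containers shared by all pipeline stages.

Meshes are carried as :class:`trimesh.Trimesh` objects with vertices in
millimetres.  An aneurysm dome is an *open* mesh clipped at the neck; the
:class:`DomeMesh` wrapper pairs it with the ordered loop of boundary
vertices that traces the neck aperture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh


def as_trimesh(vertices: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    """Build a Trimesh without any automatic merging/repair."""
    return trimesh.Trimesh(
        vertices=np.asarray(vertices, dtype=float),
        faces=np.asarray(faces, dtype=np.int64),
        process=False,
    )


def boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Ordered vertex loops of the mesh boundary.

    A boundary edge is one referenced by exactly one face.  Each returned
    loop preserves the winding direction the faces induce on the boundary,
    i.e. for a consistently wound open surface the loop runs counter-
    clockwise when seen from outside.
    """
    edges = mesh.edges  # directed, one per face corner
    edges_sorted = np.sort(edges, axis=1)
    # count undirected occurrences
    _, inverse, counts = np.unique(
        edges_sorted, axis=0, return_inverse=True, return_counts=True
    )
    boundary = edges[counts[inverse] == 1]
    if len(boundary) == 0:
        return []
    nxt = {int(a): int(b) for a, b in boundary}
    if len(nxt) != len(boundary):
        raise ValueError("non-manifold boundary: vertex with multiple outgoing boundary edges")
    loops: list[np.ndarray] = []
    remaining = dict(nxt)
    while remaining:
        start = next(iter(remaining))
        loop = [start]
        cur = remaining.pop(start)
        while cur != start:
            loop.append(cur)
            if cur not in remaining:
                raise ValueError("boundary edges do not form closed loops")
            cur = remaining.pop(cur)
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


@dataclass
class DomeMesh:
    """An isolated aneurysm dome: open surface plus ordered neck loop."""

    mesh: trimesh.Trimesh
    neck_loop: np.ndarray

    def __post_init__(self) -> None:
        self.neck_loop = np.asarray(self.neck_loop, dtype=np.int64)

    @classmethod
    def from_mesh(cls, mesh: trimesh.Trimesh) -> "DomeMesh":
        """Infer the neck loop from the (single) open boundary of ``mesh``."""
        loops = boundary_loops(mesh)
        if len(loops) == 0:
            raise ValueError("mesh is closed: a dome must be open at the neck")
        if len(loops) > 1:
            raise ValueError(f"mesh has {len(loops)} boundary loops, expected exactly 1")
        return cls(mesh=mesh, neck_loop=loops[0])

    @classmethod
    def load(cls, path: str | Path) -> "DomeMesh":
        mesh = trimesh.load_mesh(str(path), process=False)
        return cls.from_mesh(mesh)

    def save(self, path: str | Path) -> None:
        self.mesh.export(str(path))


@dataclass
class LabeledCase:
    """One aneurysm case: dome, optional fused dome+vessel surface, label."""

    case_id: str
    dome: DomeMesh
    label: str  # "growing" | "stable"
    vasculature: Optional[trimesh.Trimesh] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ("growing", "stable"):
            raise ValueError(f"label must be 'growing' or 'stable', got {self.label!r}")

    @property
    def y(self) -> int:
        """Binary label, growing = 1 (the positive class)."""
        return 1 if self.label == "growing" else 0
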