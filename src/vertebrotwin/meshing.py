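"""Tubular surface meshing of centerlines and divergence-theorem volumes.

The tube mesh serves as an independent geometric oracle: its enclosed
volume (computed from signed tetrahedra via the divergence theorem) must
agree with the centerline cross-section integral, mirroring how vascular
surface models relate to their centerlines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .centerline import Centerline
from .frenet import frenet_profile


class MeshError(ValueError):
    pass


@dataclass(frozen=True)
class TriMesh:
    vertices: np.ndarray  # (nv, 3)
    faces: np.ndarray     # (nf, 3) int, outward-oriented

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]


def _parallel_transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimising normal/binormal frames along a polyline."""
    tang = np.gradient(points, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    # seed normal: any unit vector orthogonal to the first tangent
    t0 = tang[0]
    seed = np.array([1.0, 0.0, 0.0]) if abs(t0[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n = seed - (seed @ t0) * t0
    n /= np.linalg.norm(n)
    normals = [n]
    for i in range(1, len(points)):
        t_prev, t_cur = tang[i - 1], tang[i]
        axis = np.cross(t_prev, t_cur)
        s = np.linalg.norm(axis)
        c = float(np.clip(t_prev @ t_cur, -1.0, 1.0))
        n_prev = normals[-1]
        if s < 1e-14:
            normals.append(n_prev)
            continue
        axis = axis / s
        ang = np.arctan2(s, c)
        n_rot = (
            n_prev * np.cos(ang)
            + np.cross(axis, n_prev) * np.sin(ang)
            + axis * (axis @ n_prev) * (1.0 - np.cos(ang))
        )
        n_rot -= (n_rot @ t_cur) * t_cur
        n_rot /= np.linalg.norm(n_rot)
        normals.append(n_rot)
    normals = np.asarray(normals)
    binormals = np.cross(tang, normals)
    return normals, binormals


def tube_mesh(c: Centerline, circumferential_segments: int = 64) -> TriMesh:
    """Sweep a circle of the local radius along the centerline.

    Raises :class:`MeshError` when the tube self-intersects locally, i.e.
    the radius exceeds the local radius of curvature anywhere.
    """
    if circumferential_segments < 3:
        raise MeshError("need at least 3 circumferential segments")
    prof = frenet_profile(c)
    interior_r = c.radii[1:-1]
    if np.any(interior_r * prof.curvature >= 1.0):
        raise MeshError("tube self-intersects: radius exceeds local curvature radius")

    normals, binormals = _parallel_transport_frames(c.points)
    phi = np.linspace(0.0, 2.0 * np.pi, circumferential_segments, endpoint=False)
    ring = (
        c.points[:, None, :]
        + c.radii[:, None, None]
        * (np.cos(phi)[None, :, None] * normals[:, None, :] + np.sin(phi)[None, :, None] * binormals[:, None, :])
    )
    n_pts, ns = ring.shape[0], circumferential_segments
    verts = ring.reshape(-1, 3)

    faces = []
    for i in range(n_pts - 1):
        base0, base1 = i * ns, (i + 1) * ns
        for j in range(ns):
            j1 = (j + 1) % ns
            faces.append([base0 + j, base1 + j1, base1 + j])
            faces.append([base0 + j, base0 + j1, base1 + j1])
    # end caps: fan around the end-ring centroids
    c0 = len(verts)
    c1 = c0 + 1
    verts = np.vstack([verts, c.points[0], c.points[-1]])
    for j in range(ns):
        j1 = (j + 1) % ns
        faces.append([c0, j1, j])                               # start cap
        faces.append([c1, (n_pts - 1) * ns + j, (n_pts - 1) * ns + j1])  # end cap
    faces = np.asarray(faces, dtype=int)

    mesh = TriMesh(verts, faces)
    if mesh_volume(mesh, signed=True) < 0:
        mesh = TriMesh(verts, faces[:, ::-1])
    return mesh


def mesh_volume(mesh: TriMesh, signed: bool = False) -> float:
    """Enclosed volume by the divergence theorem (signed tetrahedra)."""
    v = mesh.vertices
    f = mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    vol = float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)
    return vol if signed else abs(vol)


def write_stl(mesh: TriMesh, path) -> None:
    """Binary STL export."""
    import struct

    v, f = mesh.vertices, mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, nn, out=np.zeros_like(n), where=nn > 0)
    with open(path, "wb") as fh:
        fh.write(b"\0" * 80)
        fh.write(struct.pack("<I", len(f)))
        for i in range(len(f)):
            fh.write(struct.pack("<12fH", *n[i], *a[i], *b[i], *c[i], 0))


def write_obj(mesh: TriMesh, path) -> None:
    with open(path, "w") as fh:
        for p in mesh.vertices:
            fh.write(f"v {p[0]:.9f} {p[1]:.9f} {p[2]:.9f}\n")
        for tri in mesh.faces:
            fh.write(f"f {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n")
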