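"""Stacked-contour 3D lumen reconstruction and mesh export.

Per-frame contours are placed in parallel planes along a straight
pullback axis at a fixed frame spacing, resampled at equal polar angles
about their centroids (angle 0 first) so that ring vertices correspond
index-to-index, and lofted into a triangle tube.  Optional centroid-fan
caps close the ends into a watertight surface.  Meshes export as binary
STL or Wavefront OBJ.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .contour import LumenContour
from .morphometry import _centroid, _polar_profile

__all__ = [
    "VesselModel",
    "SurfaceMesh",
    "stack_contours",
    "loft_mesh",
    "export_mesh",
    "read_obj",
]


@dataclass(frozen=True)
class VesselModel:
    """Ordered per-frame contours along a straight pullback axis."""

    contours: tuple[LumenContour, ...]
    frame_spacing_mm: float

    def __post_init__(self) -> None:
        if self.frame_spacing_mm <= 0:
            raise ValueError("frame_spacing_mm must be > 0")

    @property
    def z_positions(self) -> np.ndarray:
        return np.arange(len(self.contours)) * self.frame_spacing_mm

    @property
    def length_mm(self) -> float:
        return (len(self.contours) - 1) * self.frame_spacing_mm


@dataclass(frozen=True)
class SurfaceMesh:
    vertices: np.ndarray  # (V, 3) mm
    faces: np.ndarray  # (F, 3) int vertex indices
    capped: bool

    def __post_init__(self) -> None:
        if len(self.faces) and (self.faces.min() < 0 or
                                self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    def edge_face_counts(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for f in self.faces:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                key = (min(a, b), max(a, b))
                counts[key] = counts.get(key, 0) + 1
        return counts

    def is_watertight(self) -> bool:
        return all(c == 2 for c in self.edge_face_counts().values())

    def euler_characteristic(self) -> int:
        v = len(self.vertices)
        e = len(self.edge_face_counts())
        f = len(self.faces)
        return v - e + f


def stack_contours(contours, frame_spacing_mm: float) -> VesselModel:
    """Place contour i in the plane z = i * frame_spacing_mm."""
    contours = tuple(contours)
    if len(contours) < 2:
        raise ValueError("stack_contours requires at least 2 contours")
    return VesselModel(contours=contours, frame_spacing_mm=frame_spacing_mm)


def _ring_at_angles(contour: LumenContour, ring_samples: int) -> np.ndarray:
    """Resample a contour at equal polar angles about its centroid.

    Vertex j sits at polar angle j * 360 / ring_samples, angle 0 first,
    so rings of consecutive frames correspond index-to-index without
    twist (the contours share the angular parameterization).
    """
    dense = contour.sample(max(8 * ring_samples, 720))
    center = _centroid(dense)
    theta_pad, r_pad = _polar_profile(dense, center)
    phi = np.linspace(0.0, 2 * np.pi, ring_samples, endpoint=False)
    r = np.interp(phi, theta_pad, r_pad)
    return np.column_stack([center[0] + r * np.cos(phi),
                            center[1] + r * np.sin(phi)])


def loft_mesh(model: VesselModel, ring_samples: int = 120,
              cap_ends: bool = True) -> SurfaceMesh:
    """Loft the stacked contours into a triangle tube mesh.

    Consecutive rings are joined by 2 * ring_samples triangles; caps are
    centroid fans.  Outward orientation follows from the anticlockwise
    in-plane contours and increasing z.
    """
    if ring_samples < 8:
        raise ValueError("ring_samples must be >= 8")
    rings = []
    for i, contour in enumerate(model.contours):
        ring = _ring_at_angles(contour, ring_samples)
        d = ring - ring.mean(axis=0)
        area2 = np.sum(d[:, 0] * np.roll(d[:, 1], -1) - np.roll(d[:, 0], -1) * d[:, 1])
        if abs(area2) < 1e-12:
            raise ValueError(f"degenerate (zero-area) contour at frame {i}")
        rings.append(ring)
    n, R = len(rings), ring_samples
    z = model.z_positions
    vertices = np.concatenate(
        [np.column_stack([ring, np.full(R, zi)]) for ring, zi in zip(rings, z)])
    faces: list[tuple[int, int, int]] = []
    for i in range(n - 1):
        base, nxt = i * R, (i + 1) * R
        for j in range(R):
            jn = (j + 1) % R
            # anticlockwise rings + increasing z -> outward normals
            faces.append((base + j, base + jn, nxt + j))
            faces.append((base + jn, nxt + jn, nxt + j))
    if cap_ends:
        c0 = np.append(rings[0].mean(axis=0), z[0])
        c1 = np.append(rings[-1].mean(axis=0), z[-1])
        i0 = len(vertices)
        vertices = np.vstack([vertices, c0[None, :], c1[None, :]])
        i1 = i0 + 1
        top = (n - 1) * R
        for j in range(R):
            jn = (j + 1) % R
            faces.append((i0, jn, j))  # bottom cap faces -z
            faces.append((i1, top + j, top + jn))  # top cap faces +z
    return SurfaceMesh(vertices=np.asarray(vertices, dtype=float),
                       faces=np.asarray(faces, dtype=np.int64),
                       capped=cap_ends)


def export_mesh(mesh: SurfaceMesh, fmt: str, path) -> None:
    """Write the mesh as binary STL or Wavefront OBJ.

    The binary STL layout is the standard 80-byte header, uint32 facet
    count, and 50 bytes per facet, giving a file size of exactly
    84 + 50 * F bytes.
    """
    if len(mesh.faces) == 0:
        raise ValueError("cannot export an empty mesh")
    fmt = fmt.lower()
    if fmt == "stl":
        _write_stl(mesh, path)
    elif fmt == "obj":
        _write_obj(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format: {fmt!r}")


def _write_stl(mesh: SurfaceMesh, path) -> None:
    tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, norm, out=np.zeros_like(normals), where=norm > 0)
    f = len(mesh.faces)
    rec = np.zeros(f, dtype=np.dtype([
        ("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]))
    rec["normal"] = normals
    rec["v"] = tri
    with open(path, "wb") as fh:
        fh.write(b"octlumen binary STL".ljust(80, b"\0"))
        fh.write(struct.pack("<I", f))
        fh.write(rec.tobytes())


def _write_obj(mesh: SurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def read_obj(path) -> SurfaceMesh:
    """Read back a Wavefront OBJ written by :func:`export_mesh`."""
    vertices, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                vertices.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    return SurfaceMesh(vertices=np.asarray(vertices, dtype=float),
                       faces=np.asarray(faces, dtype=np.int64), capped=False)
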