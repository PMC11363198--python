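"""Core geometric containers.

Everything downstream of the readers works in a single canonical space:
world RAS millimeters.  Each reader converts on ingest, so a streamline
endpoint, a voxel center and a mesh vertex can be compared with plain
Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError


def validate_affine(matrix: np.ndarray) -> np.ndarray:
    """Validate and normalize a 4x4 affine (homogeneous mm transform).

    The upper-left 3x3 block must be invertible and the last row must be
    (0, 0, 0, 1).  Returns the matrix as a float64 array.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.shape != (4, 4):
        raise ValidationError(f"affine must be 4x4, got shape {m.shape}")
    if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
        raise ValidationError(f"affine last row must be (0,0,0,1), got {m[3]}")
    if abs(np.linalg.det(m[:3, :3])) < 1e-12:
        raise ValidationError("affine upper-left 3x3 block is singular")
    return m


def apply_affine_to_points(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map an (N, 3) array of points through a 4x4 affine."""
    pts = np.asarray(points, dtype=np.float64)
    return pts @ affine[:3, :3].T + affine[:3, 3]


@dataclass
class VolumeImage:
    """Scalar volume on a voxel grid with a voxel-index -> world-RAS-mm affine."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(
                f"volume must be 3-D, got {self.values.ndim}-D shape {self.values.shape}"
            )
        self.affine = validate_affine(self.affine)
        edge = np.linalg.norm(self.affine[:3, :3], axis=0)
        if np.any(edge <= 0):
            raise ValidationError("voxel edge lengths must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return apply_affine_to_points(self.affine, np.asarray(ijk, dtype=np.float64))

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return apply_affine_to_points(np.linalg.inv(self.affine), xyz)

    def same_grid(self, other: "VolumeImage", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class BinaryMask(VolumeImage):
    """VolumeImage whose values are exactly {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.asarray(self.values)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("mask values must all be exactly 0 or 1")
        self.values = vals.astype(np.uint8)

    @property
    def n_set(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_set * self.voxel_volume_mm3

    @classmethod
    def from_volume(cls, vol: VolumeImage) -> "BinaryMask":
        return cls(values=(np.asarray(vol.values) != 0).astype(np.uint8), affine=vol.affine)


def as_streamline(points: Sequence) -> np.ndarray:
    """Validate one streamline: (N>=2, 3) finite float32 array, world RAS mm."""
    pts = np.asarray(points, dtype=np.float32)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"streamline must be (N, 3), got shape {pts.shape}")
    if pts.shape[0] < 2:
        raise ValidationError("streamline needs at least 2 points")
    if not np.isfinite(pts).all():
        raise ValidationError("streamline contains non-finite coordinates")
    return pts


@dataclass
class Tractogram:
    """Ordered streamlines in world RAS mm with optional per-streamline weights."""

    streamlines: list[np.ndarray]
    weights: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.streamlines = [as_streamline(s) for s in self.streamlines]
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=np.float64)
            if w.ndim != 1 or len(w) != len(self.streamlines):
                raise ValidationError(
                    f"need one weight per streamline: {len(w)} weights, "
                    f"{len(self.streamlines)} streamlines"
                )
            if not (w > 0).all():
                raise ValidationError("streamline weights must all be > 0")
            self.weights = w

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths_mm(self) -> np.ndarray:
        """Per-streamline arc length: sum of segment lengths in mm."""
        return np.array(
            [float(np.linalg.norm(np.diff(s, axis=0), axis=1).sum()) for s in self.streamlines]
        )


@dataclass
class SurfaceMesh:
    """Triangulated cortical mesh.

    FreeSurfer stores surface coordinates in its "tkr" (surface RAS) frame;
    adding the c_ras offset from the volume-geometry footer yields world RAS.
    """

    vertices: np.ndarray
    faces: np.ndarray
    space_tag: str = "world"  # {"tkr", "world"}
    cras_offset: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be (N, 3)")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise ValidationError("faces must be (M, 3)")
        if self.space_tag not in ("tkr", "world"):
            raise ValidationError(f"unknown space_tag {self.space_tag!r}")
        n = len(self.vertices)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= n:
                raise ValidationError(
                    f"face vertex index out of range [0, {n})"
                )
            same = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if same.any():
                raise ValidationError(
                    f"degenerate faces (repeated vertex index): {np.where(same)[0][:10]}"
                )
        if self.cras_offset is not None:
            self.cras_offset = np.asarray(self.cras_offset, dtype=np.float64).reshape(3)
        if not np.isfinite(self.vertices).all():
            raise ValidationError("non-finite vertex coordinates")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def to_world(self) -> "SurfaceMesh":
        """Return a copy in world RAS mm (tkr coordinates shifted by c_ras)."""
        if self.space_tag == "world":
            return self
        offset = self.cras_offset if self.cras_offset is not None else np.zeros(3)
        return SurfaceMesh(
            vertices=self.vertices + offset,
            faces=self.faces,
            space_tag="world",
            cras_offset=self.cras_offset,
        )


@dataclass
class VertexLabel:
    """A set of mesh vertices, optionally carrying one scalar each."""

    vertex_indices: np.ndarray
    values: Optional[np.ndarray] = None
    hemisphere: str = "lh"

    def __post_init__(self) -> None:
        idx = np.asarray(self.vertex_indices, dtype=np.int64).ravel()
        if len(np.unique(idx)) != len(idx):
            raise ValidationError("label vertex indices must be unique")
        order = np.argsort(idx)
        self.vertex_indices = idx[order]
        if self.values is not None:
            v = np.asarray(self.values, dtype=np.float64).ravel()
            if len(v) != len(idx):
                raise ValidationError("need one value per labeled vertex")
            self.values = v[order]
        if self.hemisphere not in ("lh", "rh"):
            raise ValidationError(f"hemisphere must be lh or rh, got {self.hemisphere!r}")

    def __len__(self) -> int:
        return len(self.vertex_indices)

    def check_bounds(self, mesh: SurfaceMesh) -> None:
        if len(self) and self.vertex_indices.max() >= mesh.n_vertices:
            raise ValidationError(
                f"label indexes vertex {self.vertex_indices.max()} but mesh has "
                f"{mesh.n_vertices} vertices"
            )


@dataclass
class SurfaceMap:
    """One real value per mesh vertex (a statistical map on the surface)."""

    values: np.ndarray
    missing: Optional[np.ndarray] = None  # boolean flags, True where undefined

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.missing is None:
            if not np.isfinite(self.values).all():
                raise ValidationError("non-finite map values without missing flags")
        else:
            self.missing = np.asarray(self.missing, dtype=bool).ravel()
            if len(self.missing) != len(self.values):
                raise ValidationError("missing flags length mismatch")

    def __len__(self) -> int:
        return len(self.values)
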