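"""Surface geometry: normals, volume sampling, label projection, thresholding.

The functional ROI lives on the cortical surface; the streamline search
space lives on a voxel grid at the gray/white interface.  These operations
bridge the two: sampling a volume onto vertices (a native vol2surf), and
voxelizing a vertex label by marching each labeled vertex inward along its
normal (a native surf2vol).  Projection deliberately follows normals only --
radial dilation would overestimate the ROI footprint.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .core import (
    BinaryMask,
    SurfaceMap,
    SurfaceMesh,
    Tractogram,
    VertexLabel,
    VolumeImage,
    apply_affine_to_points,
    validate_affine,
)
from .errors import EmptyInputError, ParameterError, SpaceMismatchError

logger = logging.getLogger(__name__)


@dataclass
class ProjectionParams:
    """How far, and how finely, to march inward from each vertex.

    inward_depth_mm : total inward travel (of the order of cortical
        thickness, so the march reaches the gray/white interface).
    step_mm : sampling step along the inward segment; at or below a
        quarter-voxel it leaves no holes when voxelizing.
    combine : how multiple depth samples collapse to one vertex value.
    """

    inward_depth_mm: float = 2.0
    step_mm: float = 0.25
    combine: str = "max"

    def __post_init__(self) -> None:
        if self.inward_depth_mm < 0:
            raise ParameterError("inward_depth_mm must be >= 0")
        if self.step_mm <= 0:
            raise ParameterError("step_mm must be > 0")
        if self.inward_depth_mm > 0 and self.step_mm > self.inward_depth_mm:
            raise ParameterError("step_mm must not exceed inward_depth_mm")
        if self.combine not in ("max", "mean"):
            raise ParameterError(f"combine must be max or mean, got {self.combine!r}")

    def depths(self) -> np.ndarray:
        """Sampling depths {0, step, 2·step, ..., depth} (endpoint included)."""
        if self.inward_depth_mm == 0:
            return np.array([0.0])
        n = int(np.floor(self.inward_depth_mm / self.step_mm + 1e-9))
        d = np.arange(n + 1) * self.step_mm
        if d[-1] < self.inward_depth_mm - 1e-9:
            d = np.append(d, self.inward_depth_mm)
        return d


def compute_vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex outward unit normals.

    Each vertex normal is the normalized sum of incident face normals
    weighted by face area (the cross-product magnitude provides the area
    weight for free).  Outward means consistent with counter-clockwise face
    winding.  Vertices with no incident face get a zero normal and a warning.
    """
    v = mesh.vertices
    f = mesh.faces
    normals = np.zeros_like(v)
    if len(f):
        e1 = v[f[:, 1]] - v[f[:, 0]]
        e2 = v[f[:, 2]] - v[f[:, 0]]
        face_n = np.cross(e1, e2)  # magnitude = 2 * area
        for k in range(3):
            np.add.at(normals, f[:, k], face_n)
    norm = np.linalg.norm(normals, axis=1)
    isolated = norm < 1e-30
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} vertices have no incident face; "
            f"zero normals at indices {np.where(isolated)[0][:20].tolist()}",
            stacklevel=2,
        )
    safe = np.where(isolated, 1.0, norm)
    unit = normals / safe[:, None]
    unit[isolated] = 0.0
    return unit


def _sample_world_points(
    vol: VolumeImage, points: np.ndarray, interp: str
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a volume at world-mm points; out-of-grid points get 0 + flag."""
    ijk = vol.world_to_voxel(points)
    order = {"nearest": 0, "trilinear": 1}.get(interp)
    if order is None:
        raise ParameterError(f"interp must be nearest or trilinear, got {interp!r}")
    shape = np.array(vol.shape)
    inside = ((ijk > -0.5) & (ijk < shape - 0.5)).all(axis=1)
    vals = map_coordinates(
        np.asarray(vol.values, dtype=np.float64),
        ijk.T,
        order=order,
        mode="nearest",
        prefilter=False,
    )
    vals[~inside] = 0.0
    return vals, ~inside


def sample_volume_at_vertices(
    vol: VolumeImage,
    mesh: SurfaceMesh,
    params: ProjectionParams | None = None,
    interp: str = "trilinear",
) -> SurfaceMap:
    """Native vol2surf: sample a volume along each vertex's inward normal.

    For vertex v with outward normal n, samples at v - d*n for each depth d
    and combines per ``params.combine``.  Samples falling outside the grid
    contribute 0 and are flagged missing.
    """
    params = params or ProjectionParams()
    mesh = mesh.to_world()
    vol_bbox_lo = vol.voxel_to_world(np.zeros(3))
    # heuristic unit-mismatch check: every vertex outside the grid bbox
    corners = np.array(
        [[i, j, k] for i in (0, vol.shape[0] - 1) for j in (0, vol.shape[1] - 1)
         for k in (0, vol.shape[2] - 1)],
        dtype=float,
    )
    world_corners = vol.voxel_to_world(corners)
    lo, hi = world_corners.min(axis=0) - 1.0, world_corners.max(axis=0) + 1.0
    inside_bbox = ((mesh.vertices >= lo) & (mesh.vertices <= hi)).all(axis=1)
    if len(mesh.vertices) and not inside_bbox.any():
        raise SpaceMismatchError(
            "every mesh vertex lies outside the volume bounding box; "
            "surface and volume are probably in different spaces "
            f"(bbox low corner {vol_bbox_lo})"
        )

    normals = compute_vertex_normals(mesh)
    depths = params.depths()
    stacked = np.empty((len(depths), mesh.n_vertices))
    missing_all = np.ones(mesh.n_vertices, dtype=bool)
    for i, d in enumerate(depths):
        pts = mesh.vertices - d * normals
        vals, miss = _sample_world_points(vol, pts, interp)
        stacked[i] = vals
        missing_all &= miss
    combined = stacked.max(axis=0) if params.combine == "max" else stacked.mean(axis=0)
    combined[missing_all] = 0.0
    return SurfaceMap(values=combined, missing=missing_all)


def project_label_to_volume(
    mesh: SurfaceMesh,
    label: VertexLabel,
    grid: VolumeImage,
    params: ProjectionParams | None = None,
) -> BinaryMask:
    """Native surf2vol: voxelize a vertex label by inward normal marching.

    A voxel is set iff some labeled vertex's inward segment
    [v, v - depth*n], discretized at step_mm, passes through it.
    """
    params = params or ProjectionParams()
    if len(label) == 0:
        raise EmptyInputError("empty fROI: label contains no vertices")
    mesh = mesh.to_world()
    label.check_bounds(mesh)

    verts = mesh.vertices[label.vertex_indices]
    normals = compute_vertex_normals(mesh)[label.vertex_indices]
    depths = params.depths()
    # all sample points: (n_depth * n_vertex, 3)
    pts = (verts[None, :, :] - depths[:, None, None] * normals[None, :, :]).reshape(-1, 3)
    ijk = np.round(grid.world_to_voxel(pts)).astype(np.int64)
    shape = np.array(grid.shape)
    ok = ((ijk >= 0) & (ijk < shape)).all(axis=1)
    if not ok.any():
        raise EmptyInputError(
            "all labeled vertices project outside the volume grid"
        )
    mask = np.zeros(grid.shape, dtype=np.uint8)
    kept = ijk[ok]
    mask[kept[:, 0], kept[:, 1], kept[:, 2]] = 1
    return BinaryMask(values=mask, affine=grid.affine)


def threshold_percentile(
    stat: SurfaceMap,
    searchspace: VertexLabel,
    value_percentile: float,
) -> VertexLabel:
    """Keep search-space vertices strictly above the nearest-rank percentile.

    The threshold is the value at index ceil(p/100 * n) of the ascending sort
    of the statistic restricted to the search space; selection uses strict
    ``>`` so a constant map selects nothing (warned, not an error).
    """
    if not (0 <= value_percentile < 100):
        raise ParameterError(
            f"value_percentile must be in [0, 100), got {value_percentile}"
        )
    if len(searchspace) == 0:
        raise EmptyInputError("empty search space")
    if searchspace.vertex_indices.max() >= len(stat):
        raise ParameterError("search space indexes beyond the statistical map")

    vals = stat.values[searchspace.vertex_indices]
    n = len(vals)
    srt = np.sort(vals)
    rank = int(np.ceil(value_percentile / 100.0 * n))
    rank = min(max(rank, 1), n)  # nearest-rank; percentile 0 -> minimum
    thresh = srt[rank - 1]
    keep = vals > thresh
    if not keep.any():
        warnings.warn(
            "percentile threshold selects no vertices "
            "(all search-space values <= threshold; constant map?)",
            stacklevel=2,
        )
    return VertexLabel(
        vertex_indices=searchspace.vertex_indices[keep],
        values=vals[keep],
        hemisphere=searchspace.hemisphere,
    )


def apply_affine(obj, xform: np.ndarray):
    """Map points / a mesh / a tractogram / a volume grid through a 4x4 affine.

    Mesh normals are recomputed downstream rather than transformed, so a
    transformed mesh simply carries moved vertices.  For volumes the affine
    is composed onto the voxel-to-world matrix (values untouched).
    """
    xform = validate_affine(xform)
    if isinstance(obj, SurfaceMesh):
        world = obj.to_world()
        return SurfaceMesh(
            vertices=apply_affine_to_points(xform, world.vertices),
            faces=world.faces,
            space_tag="world",
        )
    if isinstance(obj, Tractogram):
        return Tractogram(
            streamlines=[
                apply_affine_to_points(xform, s).astype(np.float32)
                for s in obj.streamlines
            ],
            weights=obj.weights,
            meta=dict(obj.meta),
        )
    if isinstance(obj, BinaryMask):
        return BinaryMask(values=obj.values, affine=xform @ obj.affine)
    if isinstance(obj, VolumeImage):
        return VolumeImage(values=obj.values, affine=xform @ obj.affine)
    pts = np.asarray(obj, dtype=np.float64)
    squeeze = pts.ndim == 1
    out = apply_affine_to_points(xform, np.atleast_2d(pts))
    return out[0] if squeeze else out
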