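"""Streamline-endpoint-to-ROI assignment and sub-bundle extraction.

This is the heart of the method: given a tractogram and the voxel mask of an
fROI intersected with the gray/white interface, decide for each streamline
endpoint whether it "reaches" the ROI, and keep the streamlines that do.

Three search criteria are supported:

* ``endpoint`` -- the endpoint itself must fall inside a set voxel;
* ``radial``  -- nearest set-voxel center within ``search_dist_mm``
  (default 2 mm; equidistant voxels break ties lexicographically by
  voxel index so results are platform-independent);
* ``forward`` -- march beyond the endpoint along the outward terminal
  tangent in ``forward_step_mm`` steps, stopping at the first step that
  lands inside a set voxel.

Distances are measured endpoint to voxel *center*, which keeps the
brute-force oracle and tie-breaking exact.  Extraction is pure filtering:
kept streamlines are bitwise-identical to their inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .core import BinaryMask, Tractogram
from .errors import EmptyInputError, ParameterError, SpaceMismatchError, ValidationError

SEARCH_TYPES = ("endpoint", "radial", "forward")


@dataclass
class MatchParams:
    """Endpoint-matching criteria.

    search_dist_mm defaults to the 2 mm radial search; 3 mm is the other
    commonly used operating point.  forward_step_mm only matters for the
    forward criterion.
    """

    search_type: str = "radial"
    search_dist_mm: float = 2.0
    forward_step_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.search_type not in SEARCH_TYPES:
            raise ParameterError(
                f"search_type must be one of {SEARCH_TYPES}, got {self.search_type!r}"
            )
        if self.search_dist_mm < 0:
            raise ParameterError("search_dist_mm must be >= 0")
        if self.search_dist_mm == 0 and self.search_type != "endpoint":
            raise ParameterError("search_dist_mm = 0 only makes sense with search_type=endpoint")
        if self.forward_step_mm <= 0:
            raise ParameterError("forward_step_mm must be > 0")


@dataclass
class EndpointAssignment:
    streamline_index: int
    which_end: str  # {"first", "last"}
    voxel_index: Optional[tuple[int, int, int]] = None
    distance_mm: Optional[float] = None

    @property
    def matched(self) -> bool:
        return self.voxel_index is not None


@dataclass
class FSuBResult:
    selected: np.ndarray  # sorted unique streamline indices
    assignments: list[EndpointAssignment]
    n_input: int
    roi_names: list[str]
    params: MatchParams
    warnings: list[str] = field(default_factory=list)


class VoxelIndex:
    """Spatial index over the world-mm centers of a mask's set voxels.

    Backed by a k-d tree for candidate generation, but the final pick
    (nearest, then lexicographic voxel index among exact ties) is computed
    with plain arithmetic so results match a brute-force scan exactly.
    """

    def __init__(self, mask: BinaryMask):
        if mask.n_set == 0:
            raise EmptyInputError("empty target mask")
        self.mask = mask
        ijk = np.argwhere(mask.values > 0)
        # argwhere returns C order == lexicographic (i, j, k) order
        self.voxels = ijk
        self.centers = mask.voxel_to_world(ijk.astype(np.float64))
        self._tree = cKDTree(self.centers)
        inv = np.linalg.inv(mask.affine)
        self._inv_affine = inv

    def nearest_within(
        self, point: np.ndarray, radius_mm: float
    ) -> tuple[Optional[tuple[int, int, int]], Optional[float]]:
        """Nearest set-voxel center within radius; lexicographic tie-break."""
        point = np.asarray(point, dtype=np.float64)
        # small slack so candidates at exactly the radius are not lost to fp
        cand = self._tree.query_ball_point(point, radius_mm * (1 + 1e-12) + 1e-9)
        if not cand:
            return None, None
        cand = np.sort(np.asarray(cand))  # sorted row index == lexicographic ijk
        d = np.linalg.norm(self.centers[cand] - point, axis=1)
        ok = d <= radius_mm
        if not ok.any():
            return None, None
        cand, d = cand[ok], d[ok]
        best = cand[np.argmin(d)]  # argmin returns first minimum -> lexicographic
        dist = float(np.min(d))
        return tuple(int(x) for x in self.voxels[best]), dist

    def contains(self, point: np.ndarray) -> Optional[tuple[int, int, int]]:
        """Voxel index if the point falls inside a set voxel, else None."""
        ijk = np.round(
            np.asarray(point, np.float64) @ self._inv_affine[:3, :3].T
            + self._inv_affine[:3, 3]
        ).astype(np.int64)
        if ((ijk < 0) | (ijk >= np.array(self.mask.shape))).any():
            return None
        if self.mask.values[ijk[0], ijk[1], ijk[2]]:
            return tuple(int(x) for x in ijk)
        return None


def build_voxel_index(mask: BinaryMask) -> VoxelIndex:
    return VoxelIndex(mask)


def match_endpoint(
    streamline: np.ndarray,
    which_end: str,
    index: VoxelIndex,
    params: MatchParams,
    streamline_index: int = 0,
) -> EndpointAssignment:
    """Assign one streamline endpoint to a target voxel (or to nothing)."""
    if which_end not in ("first", "last"):
        raise ParameterError(f"which_end must be first or last, got {which_end!r}")
    pts = np.asarray(streamline, dtype=np.float64)
    endpoint = pts[0] if which_end == "first" else pts[-1]
    result = EndpointAssignment(streamline_index=streamline_index, which_end=which_end)

    if params.search_type == "endpoint":
        vox = index.contains(endpoint)
        if vox is not None:
            center = index.mask.voxel_to_world(np.array(vox, dtype=np.float64))
            result.voxel_index = vox
            result.distance_mm = float(np.linalg.norm(endpoint - center))
        return result

    if params.search_type == "radial":
        vox, dist = index.nearest_within(endpoint, params.search_dist_mm)
        result.voxel_index, result.distance_mm = vox, dist
        return result

    # forward: march along the outward terminal tangent
    neighbor = pts[1] if which_end == "first" else pts[-2]
    tangent = endpoint - neighbor
    norm = np.linalg.norm(tangent)
    if norm < 1e-12:
        warnings.warn(
            f"streamline {streamline_index} ({which_end} end): degenerate terminal "
            "tangent; falling back to radial search",
            stacklevel=2,
        )
        vox, dist = index.nearest_within(endpoint, params.search_dist_mm)
        result.voxel_index, result.distance_mm = vox, dist
        return result
    tangent /= norm
    d = 0.0
    while d <= params.search_dist_mm + 1e-9:
        vox = index.contains(endpoint + d * tangent)
        if vox is not None:
            result.voxel_index = vox
            result.distance_mm = float(d)
            return result
        d += params.forward_step_mm
    return result


def _match_all_endpoints(
    t: Tractogram, index: VoxelIndex, params: MatchParams
) -> list[EndpointAssignment]:
    out = []
    for i, s in enumerate(t.streamlines):
        out.append(match_endpoint(s, "first", index, params, streamline_index=i))
        out.append(match_endpoint(s, "last", index, params, streamline_index=i))
    return out


def extract_fsub(
    t: Tractogram,
    roi1: BinaryMask,
    roi2: Optional[BinaryMask] = None,
    params: Optional[MatchParams] = None,
    roi_names: Optional[list[str]] = None,
    small_fsub_floor: int = 5,
) -> FSuBResult:
    """Filter a tractogram down to its functional sub-bundle.

    One-ROI mode keeps streamlines with at least one endpoint matching
    ``roi1``.  Two-ROI mode keeps streamlines that *connect* the ROIs: one
    endpoint must match ``roi1`` and the other endpoint ``roi2`` (either
    orientation); a single endpoint matching both does not qualify.
    """
    params = params or MatchParams()
    if len(t) == 0:
        raise EmptyInputError("empty tractogram")
    if roi1.n_set == 0:
        raise EmptyInputError("empty roi1 mask")
    names = roi_names or (["roi1", "roi2"] if roi2 is not None else ["roi1"])
    if roi2 is not None and not roi1.same_grid(roi2, atol=1e-4):
        raise SpaceMismatchError("roi1 and roi2 are not on the same voxel grid")

    index1 = build_voxel_index(roi1)
    a1 = _match_all_endpoints(t, index1, params)
    warn_list: list[str] = []

    if roi2 is None:
        matched = {a.streamline_index for a in a1 if a.matched}
        selected = np.array(sorted(matched), dtype=np.int64)
        assignments = [a for a in a1 if a.matched and a.streamline_index in matched]
    else:
        if roi2.n_set == 0:
            raise EmptyInputError("empty roi2 mask")
        index2 = build_voxel_index(roi2)
        a2 = _match_all_endpoints(t, index2, params)
        by_end1 = {(a.streamline_index, a.which_end): a for a in a1}
        by_end2 = {(a.streamline_index, a.which_end): a for a in a2}
        selected_list = []
        assignments = []
        for i in range(len(t)):
            f1 = by_end1[(i, "first")].matched
            l1 = by_end1[(i, "last")].matched
            f2 = by_end2[(i, "first")].matched
            l2 = by_end2[(i, "last")].matched
            # the two matches must lie on distinct ends
            if (f1 and l2) or (l1 and f2):
                selected_list.append(i)
                if f1 and l2:
                    assignments.append(by_end1[(i, "first")])
                    assignments.append(by_end2[(i, "last")])
                else:
                    assignments.append(by_end1[(i, "last")])
                    assignments.append(by_end2[(i, "first")])
        selected = np.array(selected_list, dtype=np.int64)

    if 0 < len(selected) <= small_fsub_floor:
        msg = (
            f"very small FSuB: only {len(selected)} streamline(s) selected; "
            "interpret with caution"
        )
        warnings.warn(msg, stacklevel=2)
        warn_list.append(msg)

    return FSuBResult(
        selected=selected,
        assignments=assignments,
        n_input=len(t),
        roi_names=names,
        params=params,
        warnings=warn_list,
    )


def subset_tractogram(t: Tractogram, indices) -> Tractogram:
    """Keep the listed streamlines (geometry bitwise unchanged, weights subset)."""
    idx = np.asarray(indices, dtype=np.int64).ravel()
    if len(idx) and (idx.min() < 0 or idx.max() >= len(t)):
        raise ValidationError(
            f"streamline index out of range [0, {len(t)})"
        )
    streamlines = [t.streamlines[i] for i in idx]
    weights = t.weights[idx] if t.weights is not None else None
    meta = dict(t.meta)
    meta["subset_of"] = meta.get("source_file", "<memory>")
    if not streamlines:
        # Tractogram validation allows empty lists; keep weights aligned
        return Tractogram(streamlines=[], weights=None, meta=meta)
    return Tractogram(streamlines=streamlines, weights=weights, meta=meta)
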