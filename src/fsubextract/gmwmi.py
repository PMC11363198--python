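"""Gray-matter--white-matter interface (GMWMI) from a 5-tissue-type image.

The 5tt convention stacks five partial-volume maps: cortical gray matter,
subcortical gray matter, white matter, CSF, pathological tissue.  The
interface score used here is ``min(1, 4 * g * w)``: it peaks at exactly 1.0
for a 50/50 gray/white mix and vanishes in pure tissue, which is precisely
the boundary layer streamlines should terminate in.  The probabilistic image
is binarized at an adjustable threshold and intersected with projected fROIs
to form the streamline search space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, VolumeImage, validate_affine
from .errors import EmptyInputError, ParameterError, SpaceMismatchError, ValidationError
from .io_formats import PathLike, read_volume_4d

TISSUE_NAMES = ("cortical_gm", "subcortical_gm", "wm", "csf", "pathological")


@dataclass
class TissueSegmentation:
    """Five partial-volume maps (values in [0, 1]) on one grid."""

    maps: np.ndarray  # (x, y, z, 5)
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 4 or self.maps.shape[3] != 5:
            raise ValidationError(
                f"5tt image must be (x, y, z, 5), got shape {self.maps.shape}"
            )
        self.affine = validate_affine(self.affine)
        if self.maps.min() < -1e-9 or self.maps.max() > 1 + 1e-9:
            raise ValidationError("partial volumes must lie in [0, 1]")
        total = self.maps.sum(axis=3)
        if total.max() > 1.05:
            raise ValidationError(
                f"per-voxel tissue sum exceeds 1.05 (max {total.max():.3f})"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.maps.shape[:3]  # type: ignore[return-value]

    def tissue(self, name: str) -> np.ndarray:
        return self.maps[..., TISSUE_NAMES.index(name)]

    @classmethod
    def from_nifti(cls, path: PathLike) -> "TissueSegmentation":
        data, affine = read_volume_4d(path)
        return cls(maps=data, affine=affine)


def compute_gmwmi(
    seg: TissueSegmentation, include_subcortical: bool = False
) -> VolumeImage:
    """Probabilistic interface image: score = min(1, 4 * g * w) per voxel.

    g is cortical gray-matter partial volume (plus subcortical if flagged),
    w is white matter.  Scores are in [0, 1], zero wherever either tissue is
    absent, and exactly 1 at 50/50 mixing.
    """
    if not np.any(seg.maps):
        raise EmptyInputError("all-zero tissue segmentation")
    g = seg.tissue("cortical_gm")
    if include_subcortical:
        g = g + seg.tissue("subcortical_gm")
    w = seg.tissue("wm")
    score = np.minimum(1.0, 4.0 * g * w)
    return VolumeImage(values=score, affine=seg.affine)


def binarize(prob: VolumeImage, threshold: float = 0.25) -> BinaryMask:
    """Strict thresholding: mask = (prob > threshold)."""
    if not (0 <= threshold < 1):
        raise ParameterError(f"threshold must be in [0, 1), got {threshold}")
    vals = np.asarray(prob.values)
    if vals.min() < -1e-9 or vals.max() > 1 + 1e-9:
        raise ParameterError("probability image values must lie in [0, 1]")
    mask = (vals > threshold).astype(np.uint8)
    if not mask.any():
        warnings.warn("binarized image is empty (no voxel above threshold)", stacklevel=2)
    return BinaryMask(values=mask, affine=prob.affine)


def intersect_masks(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise product of two masks on the same grid (no resampling).

    A grid mismatch is an error by design: silently resampling would hide
    registration problems, the main practical failure mode of endpoint
    matching.
    """
    if not a.same_grid(b, atol=1e-4):
        raise SpaceMismatchError(
            f"mask grids differ (shapes {a.shape} vs {b.shape}); "
            "resample explicitly before intersecting"
        )
    out = (a.values.astype(np.uint8) * b.values.astype(np.uint8)).astype(np.uint8)
    if not out.any():
        warnings.warn("mask intersection is empty", stacklevel=2)
    return BinaryMask(values=out, affine=a.affine)
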