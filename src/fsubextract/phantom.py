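"""Deterministic slab phantom: synthetic inputs with known ground truth.

The phantom emulates a flat piece of cortex: white matter fills z < 0,
cortical gray matter the slab 0 <= z < thickness, CSF above, with exact
analytic partial volumes in the voxel layers straddling each boundary.
The gray/white boundary surface is a regular triangulation of the z = 0
plane with outward normals (0, 0, +1).  Functional patches are discs on
that surface carrying a radial statistical bump; bundles are smooth
quadratic Bezier arcs dipping into the white matter whose endpoints
terminate at a controlled signed offset from the interface; decoys
terminate at least a configurable margin away from every patch.

What it does *not* emulate: cortical folding, fanning/crossing fiber
geometry, partial voluming from image resolution, registration error.
Every output is a pure function of the spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import BinaryMask, SurfaceMap, SurfaceMesh, Tractogram, VertexLabel
from .errors import ParameterError, ValidationError
from .gmwmi import TissueSegmentation
from .matching import FSuBResult
from . import io_formats


@dataclass
class PatchSpec:
    """A functional patch: a disc on the z = 0 boundary surface."""

    name: str
    center_xy: tuple[float, float]
    radius_mm: float = 5.0
    peak_stat: float = 10.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ParameterError(f"patch {self.name}: radius must be > 0")


@dataclass
class BundleSpec:
    """A streamline bundle from one patch to another patch or a free end."""

    name: str
    source_patch: str
    sink_patch: Optional[str] = None
    n_streamlines: int = 100
    endpoint_offset_mm: float = 0.0  # signed: + above interface (into GM)
    jitter_sd_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.n_streamlines < 0:
            raise ParameterError(f"bundle {self.name}: n_streamlines must be >= 0")
        if self.jitter_sd_mm < 0:
            raise ParameterError(f"bundle {self.name}: jitter_sd_mm must be >= 0")


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (40, 40, 24)
    voxel_size_mm: float = 1.0
    gm_thickness_mm: float = 3.0
    mesh_spacing_mm: float = 1.0
    patches: list[PatchSpec] = field(default_factory=list)
    bundles: list[BundleSpec] = field(default_factory=list)
    n_decoys: int = 0
    decoy_margin_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ParameterError("grid_shape entries must be positive")
        if self.voxel_size_mm <= 0 or self.gm_thickness_mm <= 0:
            raise ParameterError("voxel size and GM thickness must be > 0")
        names = [p.name for p in self.patches]
        if len(set(names)) != len(names):
            raise ParameterError("patch names must be unique")
        for b in self.bundles:
            for pn in (b.source_patch, b.sink_patch):
                if pn is not None and pn not in names:
                    raise ParameterError(f"bundle {b.name}: unknown patch {pn!r}")

    def patch(self, name: str) -> PatchSpec:
        for p in self.patches:
            if p.name == name:
                return p
        raise KeyError(name)

    # -- key-value text serialization ------------------------------------
    def to_file(self, path) -> Path:
        path = Path(path)
        lines = [
            f"grid_shape = {self.grid_shape[0]} {self.grid_shape[1]} {self.grid_shape[2]}",
            f"voxel_size_mm = {self.voxel_size_mm}",
            f"gm_thickness_mm = {self.gm_thickness_mm}",
            f"mesh_spacing_mm = {self.mesh_spacing_mm}",
            f"n_decoys = {self.n_decoys}",
            f"decoy_margin_mm = {self.decoy_margin_mm}",
            f"seed = {self.seed}",
        ]
        for p in self.patches:
            lines.append(
                f"patch = {p.name} {p.center_xy[0]} {p.center_xy[1]} "
                f"{p.radius_mm} {p.peak_stat}"
            )
        for b in self.bundles:
            sink = b.sink_patch if b.sink_patch is not None else "-"
            lines.append(
                f"bundle = {b.name} {b.source_patch} {sink} {b.n_streamlines} "
                f"{b.endpoint_offset_mm} {b.jitter_sd_mm}"
            )
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_file(cls, path) -> "PhantomSpec":
        kwargs: dict = {"patches": [], "bundles": []}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#")[0].strip()
            if not line or "=" not in line:
                continue
            key, _, val = line.partition("=")
            key, parts = key.strip(), val.split()
            if key == "grid_shape":
                kwargs["grid_shape"] = tuple(int(x) for x in parts)
            elif key in ("voxel_size_mm", "gm_thickness_mm", "mesh_spacing_mm",
                         "decoy_margin_mm"):
                kwargs[key] = float(parts[0])
            elif key in ("n_decoys", "seed"):
                kwargs[key] = int(parts[0])
            elif key == "patch":
                kwargs["patches"].append(PatchSpec(
                    name=parts[0],
                    center_xy=(float(parts[1]), float(parts[2])),
                    radius_mm=float(parts[3]),
                    peak_stat=float(parts[4]),
                ))
            elif key == "bundle":
                kwargs["bundles"].append(BundleSpec(
                    name=parts[0],
                    source_patch=parts[1],
                    sink_patch=None if parts[2] == "-" else parts[2],
                    n_streamlines=int(parts[3]),
                    endpoint_offset_mm=float(parts[4]),
                    jitter_sd_mm=float(parts[5]),
                ))
            else:
                raise ParameterError(f"unknown phantom spec key {key!r}")
        return cls(**kwargs)


@dataclass
class PhantomDataset:
    spec: PhantomSpec
    mesh: SurfaceMesh  # GM/WM boundary, world space
    seg: TissueSegmentation
    statmap: SurfaceMap
    labels: dict[str, VertexLabel]
    bundles: dict[str, Tractogram]
    truth: pd.DataFrame  # one row per streamline (global index over bundles)

    def combined_tractogram(self) -> Tractogram:
        """All bundles concatenated in definition order (matches truth index)."""
        streamlines: list[np.ndarray] = []
        for name in self.bundles:
            streamlines.extend(self.bundles[name].streamlines)
        return Tractogram(streamlines=streamlines, meta={"source_format": "phantom"})

    def positives(
        self, source: Optional[str] = None, sink: Optional[str] = None
    ) -> np.ndarray:
        """Global indices of truth streamlines touching the given patch(es).

        ``source`` alone: streamlines with either terminus at that patch.
        ``source`` and ``sink``: streamlines connecting the two patches.
        """
        df = self.truth
        if source is None:
            raise ParameterError("need at least a source patch name")
        if sink is None:
            hit = (df["source_patch"] == source) | (df["sink_patch"] == source)
        else:
            hit = (
                ((df["source_patch"] == source) & (df["sink_patch"] == sink))
                | ((df["source_patch"] == sink) & (df["sink_patch"] == source))
            )
        return df.index.values[hit.values & ~df["is_decoy"].values]


def _slab_partial_volumes(spec: PhantomSpec) -> TissueSegmentation:
    """Analytic 5tt maps: WM below z=0, GM slab, CSF above.

    Voxel layer k has world-z extent [zc - h/2, zc + h/2]; each tissue's
    partial volume is its exact overlap fraction with that extent.
    """
    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size_mm
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = [
        -vs * (nx - 1) / 2.0,
        -vs * (ny - 1) / 2.0,
        -vs * (nz // 2),  # voxel layer nz//2 is centered on z = 0
    ]
    zc = vs * np.arange(nz) + affine[2, 3]
    lo, hi = zc - vs / 2.0, zc + vs / 2.0

    def overlap(a: float, b: float) -> np.ndarray:
        return np.clip(np.minimum(hi, b) - np.maximum(lo, a), 0.0, None) / vs

    wm = overlap(-np.inf, 0.0)
    gm = overlap(0.0, spec.gm_thickness_mm)
    csf = overlap(spec.gm_thickness_mm, np.inf)
    maps = np.zeros((nx, ny, nz, 5))
    maps[..., 0] = gm[None, None, :]
    maps[..., 2] = wm[None, None, :]
    maps[..., 3] = csf[None, None, :]
    return TissueSegmentation(maps=maps, affine=affine)


def _boundary_mesh(spec: PhantomSpec) -> SurfaceMesh:
    """Regular triangulation of the z = 0 plane, CCW from +z (normals +z)."""
    nx, ny, _ = spec.grid_shape
    vs = spec.voxel_size_mm
    half_x, half_y = vs * (nx - 1) / 2.0, vs * (ny - 1) / 2.0
    xs = np.arange(-half_x, half_x + 1e-9, spec.mesh_spacing_mm)
    ys = np.arange(-half_y, half_y + 1e-9, spec.mesh_spacing_mm)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    vertices = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    n_x, n_y = len(xs), len(ys)

    def vid(i: int, j: int) -> int:
        return i * n_y + j

    faces = []
    for i in range(n_x - 1):
        for j in range(n_y - 1):
            v00, v10 = vid(i, j), vid(i + 1, j)
            v01, v11 = vid(i, j + 1), vid(i + 1, j + 1)
            faces.append([v00, v10, v11])  # CCW viewed from +z
            faces.append([v00, v11, v01])
    return SurfaceMesh(
        vertices=vertices, faces=np.array(faces, dtype=np.int64), space_tag="world",
        cras_offset=np.zeros(3),
    )


def _bezier_arc(p0: np.ndarray, p2: np.ndarray, dip_mm: float,
                sample_mm: float = 0.5) -> np.ndarray:
    """Quadratic Bezier from p0 to p2 dipping dip_mm into -z, ~sample_mm spacing."""
    p1 = (p0 + p2) / 2.0
    p1[2] -= dip_mm
    chord = float(np.linalg.norm(p2 - p0))
    n = max(int(np.ceil((chord + 2 * dip_mm) / sample_mm)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    return pts.astype(np.float32)


def make_slab_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Build the full synthetic dataset from a spec (pure function of spec)."""
    rng = np.random.default_rng(spec.seed)
    seg = _slab_partial_volumes(spec)
    mesh = _boundary_mesh(spec)

    # patches must keep clear of the decoy margin of each other's bundles
    for i, a in enumerate(spec.patches):
        for b in spec.patches[i + 1:]:
            gap = float(np.hypot(a.center_xy[0] - b.center_xy[0],
                                 a.center_xy[1] - b.center_xy[1]))
            if gap <= a.radius_mm + b.radius_mm:
                raise ParameterError(
                    f"patches {a.name} and {b.name} overlap (gap {gap:.1f} mm)"
                )

    xy = mesh.vertices[:, :2]
    stat = np.zeros(mesh.n_vertices)
    labels: dict[str, VertexLabel] = {}
    for p in spec.patches:
        d = np.linalg.norm(xy - np.asarray(p.center_xy), axis=1)
        stat += p.peak_stat * np.clip(1.0 - d / (2.0 * p.radius_mm), 0.0, None)
        inside = np.where(d <= p.radius_mm)[0]
        if len(inside) == 0:
            raise ParameterError(f"patch {p.name} captures no mesh vertices")
        labels[p.name] = VertexLabel(
            vertex_indices=inside, values=stat[inside].copy(), hemisphere="lh"
        )
    statmap = SurfaceMap(values=stat)

    def sample_in_patch(p: PatchSpec, n: int) -> np.ndarray:
        """Uniform points in the inner 80% of the patch disc (z = 0)."""
        r = 0.8 * p.radius_mm * np.sqrt(rng.uniform(size=n))
        theta = rng.uniform(0, 2 * np.pi, size=n)
        out = np.zeros((n, 3))
        out[:, 0] = p.center_xy[0] + r * np.cos(theta)
        out[:, 1] = p.center_xy[1] + r * np.sin(theta)
        return out

    bundles: dict[str, Tractogram] = {}
    truth_rows: list[dict] = []
    half_x = spec.voxel_size_mm * (spec.grid_shape[0] - 1) / 2.0
    half_y = spec.voxel_size_mm * (spec.grid_shape[1] - 1) / 2.0

    for b in spec.bundles:
        src = spec.patch(b.source_patch)
        starts = sample_in_patch(src, b.n_streamlines)
        if b.sink_patch is not None:
            ends = sample_in_patch(spec.patch(b.sink_patch), b.n_streamlines)
        else:
            # free ends: deep in white matter, away from every patch
            ends = np.zeros((b.n_streamlines, 3))
            ends[:, 0] = rng.uniform(-half_x * 0.9, half_x * 0.9, b.n_streamlines)
            ends[:, 1] = rng.uniform(-half_y * 0.9, half_y * 0.9, b.n_streamlines)
            ends[:, 2] = -0.6 * spec.voxel_size_mm * (spec.grid_shape[2] // 2)
        starts[:, 2] += b.endpoint_offset_mm
        if b.sink_patch is not None:
            ends[:, 2] += b.endpoint_offset_mm
        if b.jitter_sd_mm > 0:
            starts += rng.normal(0.0, b.jitter_sd_mm, starts.shape)
            ends += rng.normal(0.0, b.jitter_sd_mm, ends.shape)
        streamlines = []
        for k in range(b.n_streamlines):
            dip = max(3.0, 0.4 * float(np.linalg.norm(ends[k] - starts[k])))
            streamlines.append(_bezier_arc(starts[k], ends[k], dip))
            truth_rows.append({
                "bundle": b.name,
                "source_patch": b.source_patch,
                "sink_patch": b.sink_patch if b.sink_patch is not None else "",
                "is_decoy": False,
            })
        bundles[b.name] = Tractogram(
            streamlines=streamlines, meta={"source_format": "phantom", "seed": spec.seed}
        )

    if spec.n_decoys:
        decoy_streamlines = []
        centers = np.array([p.center_xy for p in spec.patches]) if spec.patches \
            else np.zeros((0, 2))
        radii = np.array([p.radius_mm for p in spec.patches]) if spec.patches \
            else np.zeros(0)
        count = 0
        attempts = 0
        while count < spec.n_decoys:
            attempts += 1
            if attempts > 200 * spec.n_decoys:
                raise ParameterError(
                    "cannot place decoys: decoy margin leaves no room in the slab"
                )
            p0 = np.array([
                rng.uniform(-half_x * 0.95, half_x * 0.95),
                rng.uniform(-half_y * 0.95, half_y * 0.95),
                0.0,
            ])
            if len(centers):
                dist_to_patch = np.linalg.norm(centers - p0[:2], axis=1) - radii
                if dist_to_patch.min() < spec.decoy_margin_mm:
                    continue
            p2 = p0 + np.array([
                rng.uniform(-4.0, 4.0), rng.uniform(-4.0, 4.0),
                -0.5 * spec.voxel_size_mm * (spec.grid_shape[2] // 2),
            ])
            decoy_streamlines.append(_bezier_arc(p0, p2, dip_mm=3.0))
            truth_rows.append({
                "bundle": "decoys", "source_patch": "", "sink_patch": "",
                "is_decoy": True,
            })
            count += 1
        bundles["decoys"] = Tractogram(
            streamlines=decoy_streamlines,
            meta={"source_format": "phantom", "seed": spec.seed},
        )

    truth = pd.DataFrame(truth_rows)
    if len(truth) == 0:
        truth = pd.DataFrame(
            columns=["bundle", "source_patch", "sink_patch", "is_decoy"]
        ).astype({"is_decoy": bool})
    return PhantomDataset(
        spec=spec, mesh=mesh, seg=seg, statmap=statmap,
        labels=labels, bundles=bundles, truth=truth,
    )


@dataclass
class RecoveryMetrics:
    precision: float
    recall: float
    precision_defined: bool = True


def evaluate_recovery(truth_positives, result: FSuBResult) -> RecoveryMetrics:
    """Precision/recall of a selection against ground-truth positive indices.

    Both are 1 when selection and truth are both empty; precision is
    reported as 0 with ``precision_defined=False`` when nothing was
    selected but positives exist.
    """
    pos = set(int(i) for i in np.asarray(truth_positives, dtype=np.int64).ravel())
    sel = set(int(i) for i in np.asarray(result.selected, dtype=np.int64).ravel())
    if not sel and not pos:
        return RecoveryMetrics(1.0, 1.0)
    hits = len(sel & pos)
    if not sel:
        return RecoveryMetrics(0.0, 0.0, precision_defined=False)
    precision = hits / len(sel)
    recall = hits / len(pos) if pos else 1.0
    return RecoveryMetrics(precision, recall)


def write_phantom_tree(dataset: PhantomDataset, outdir) -> dict[str, Path]:
    """Serialize a phantom as a BIDS-like fixture tree (all text/standard formats)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    manifest["spec"] = dataset.spec.to_file(outdir / "phantom_spec.txt")
    manifest["5tt"] = io_formats.write_volume_4d(
        dataset.seg.maps, dataset.seg.affine, outdir / "sub-phantom_desc-5tt_probseg.nii"
    )
    manifest["surface"] = io_formats.write_fs_surface(
        dataset.mesh, outdir / "lh.white"
    )
    manifest["statmap"] = io_formats.write_surface_map(
        dataset.statmap.values, outdir / "sub-phantom_hemi-L_statmap.txt"
    )
    for name, label in dataset.labels.items():
        manifest[f"label_{name}"] = io_formats.write_label(
            label, dataset.mesh, outdir / f"lh.{name}.label"
        )
    for name, bundle in dataset.bundles.items():
        manifest[f"bundle_{name}"] = io_formats.write_tck(
            bundle, outdir / f"sub-phantom_desc-{name}_tractography.tck"
        )
    truth_path = outdir / "sub-phantom_desc-truth.tsv"
    dataset.truth.to_csv(truth_path, sep="\t", index_label="streamline_index")
    manifest["truth"] = truth_path
    return manifest
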