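"""Readers and writers for the on-disk formats the pipeline touches.

Tractograms (TCK, TRK), FreeSurfer binary triangle surfaces and ASCII
``.label`` files are parsed natively so every byte and every coordinate
convention is explicit and auditable; NIfTI volumes go through nibabel.
All readers convert into the canonical internal space, world RAS mm:

* TCK stores world/scanner mm natively -- no conversion.
* TRK stores corner-origin voxel-mm: stored point ``p`` maps to voxel index
  ``p / voxel_size - 0.5`` and then through the header's voxel-to-RAS matrix.
* FreeSurfer surfaces store "tkr" surface-RAS coordinates; adding the
  ``cras`` offset from the volume-geometry footer yields world RAS.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np

from .core import (
    SurfaceMesh,
    Tractogram,
    VertexLabel,
    VolumeImage,
    as_streamline,
    validate_affine,
)
from .errors import (
    CorruptFileError,
    FormatError,
    UnsupportedDialectError,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

TCK_MAGIC = b"mrtrix tracks"
FS_TRIANGLE_MAGIC = 16777214  # 0xFFFFFE, three big-endian bytes


# ---------------------------------------------------------------------------
# TCK (MRtrix tracks)
# ---------------------------------------------------------------------------

def read_tck(path: PathLike) -> Tractogram:
    """Read an MRtrix ``.tck`` file.

    Coordinates are returned exactly as stored (TCK is world RAS mm).
    Only Float32LE / Float32BE payloads are accepted; anything else raises
    :class:`UnsupportedDialectError` rather than risking a silent misread.
    """
    path = Path(path)
    raw = path.read_bytes()
    if not raw.startswith(TCK_MAGIC):
        raise FormatError(f"{path}: missing TCK magic line 'mrtrix tracks'")

    # Header: text "key: value" lines up to the END keyword.
    end_idx = raw.find(b"\nEND")
    if end_idx < 0:
        raise CorruptFileError(f"{path}: TCK header has no END line")
    header_text = raw[:end_idx].decode("utf-8", errors="replace")
    header: dict[str, str] = {}
    for line in header_text.splitlines()[1:]:
        if ":" in line:
            key, _, val = line.partition(":")
            header[key.strip()] = val.strip()

    dtype_name = header.get("datatype", "")
    if dtype_name == "Float32LE":
        dt = np.dtype("<f4")
    elif dtype_name == "Float32BE":
        dt = np.dtype(">f4")
    else:
        raise UnsupportedDialectError(
            f"{path}: unsupported TCK datatype {dtype_name!r} "
            "(only Float32LE/Float32BE are accepted)"
        )

    if "file" not in header:
        raise CorruptFileError(f"{path}: TCK header missing 'file' entry")
    file_field = header["file"].split()
    if file_field[0] != ".":
        raise UnsupportedDialectError(f"{path}: external TCK data files not supported")
    offset = int(file_field[1])

    payload = raw[offset:]
    if len(payload) % 12 != 0:
        raise CorruptFileError(
            f"{path}: data section truncated at byte {offset + len(payload)} "
            "(not a whole number of coordinate triplets)"
        )
    triplets = np.frombuffer(payload, dtype=dt).reshape(-1, 3).astype(np.float32)

    streamlines: list[np.ndarray] = []
    current: list[np.ndarray] = []
    terminated = False
    for row in triplets:
        if np.isinf(row).all():
            terminated = True
            break
        if np.isnan(row).all():
            if current:
                streamlines.append(np.array(current, dtype=np.float32))
                current = []
            continue
        if not np.isfinite(row).all():
            raise CorruptFileError(f"{path}: mixed finite/non-finite coordinate triplet")
        current.append(row)
    if not terminated:
        raise CorruptFileError(
            f"{path}: data section truncated at byte {offset + len(payload)} "
            "(no Inf terminator triplet)"
        )
    if current:  # tolerate a missing final NaN separator before the terminator
        streamlines.append(np.array(current, dtype=np.float32))

    if "count" in header:
        declared = int(header["count"])
        if declared != len(streamlines):
            raise CorruptFileError(
                f"{path}: header declares count {declared} but data holds "
                f"{len(streamlines)} streamlines"
            )

    meta = {"source_format": "tck", "source_file": str(path)}
    if "count" in header:
        meta["declared_count"] = int(header["count"])
    return Tractogram(streamlines=streamlines, meta=meta)


def write_tck(t: Tractogram, path: PathLike) -> Path:
    """Write a Tractogram as ``.tck`` (datatype Float32LE, count recorded)."""
    path = Path(path)
    prefix = (
        "mrtrix tracks\n"
        "datatype: Float32LE\n"
        f"count: {len(t)}\n"
        "timestamp: 0\n"
    )
    # The 'file' line records the byte offset of the data, which depends on
    # its own printed length; iterate until the offset is self-consistent.
    offset = len(prefix) + len("file: . \nEND\n")
    while True:
        header = prefix + f"file: . {offset}\nEND\n"
        if len(header.encode("utf-8")) == offset:
            break
        offset = len(header.encode("utf-8"))

    chunks: list[np.ndarray] = []
    nan_row = np.full((1, 3), np.nan, dtype="<f4")
    for s in t.streamlines:
        chunks.append(np.asarray(s, dtype="<f4"))
        chunks.append(nan_row)
    chunks.append(np.full((1, 3), np.inf, dtype="<f4"))
    data = np.concatenate(chunks, axis=0) if chunks else np.empty((0, 3), "<f4")

    with open(path, "wb") as f:
        f.write(header.encode("utf-8"))
        f.write(data.astype("<f4").tobytes())
    return path


# ---------------------------------------------------------------------------
# TRK (TrackVis v2)
# ---------------------------------------------------------------------------

_TRK_HEADER = struct.Struct(
    "<6s3h3f3fh200sh200s16f444s4s4s6f2s6B3i"
)
# layout: id_string, dim, voxel_size, origin, n_scalars, scalar_name,
#         n_properties, property_name, vox_to_ras, reserved, voxel_order,
#         pad2, image_orientation_patient, pad1,
#         (invert_x..z, swap_xy/yz/zx), n_count, version, hdr_size
assert _TRK_HEADER.size == 1000


def _trk_world_affine(voxel_size: np.ndarray, vox_to_ras: np.ndarray) -> np.ndarray:
    """Affine taking a stored TRK point to world RAS mm.

    stored p -> voxel index p / voxel_size - 0.5 -> vox_to_ras.
    """
    scale = np.diag(np.r_[1.0 / voxel_size, 1.0])
    shift = np.eye(4)
    shift[:3, 3] = -0.5
    return vox_to_ras @ shift @ scale


def read_trk(path: PathLike) -> Tractogram:
    """Read a TrackVis ``.trk`` v2 file into world RAS mm.

    Per-streamline properties and per-point scalars are retained as opaque
    metadata; the coordinate conversion uses the header's voxel sizes and
    voxel-to-RAS matrix with the corner-origin half-voxel convention.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 1000:
        raise FormatError(f"{path}: file shorter than the 1000-byte TRK header")

    for byteorder in ("<", ">"):
        hdr_size = struct.unpack(byteorder + "i", raw[996:1000])[0]
        if hdr_size == 1000:
            break
    else:
        raise FormatError(
            f"{path}: hdr_size is not 1000 under either byte order; not a TRK v2 file"
        )

    fields = struct.Struct(byteorder + _TRK_HEADER.format[1:]).unpack(raw[:1000])
    id_string = fields[0]
    if not id_string.startswith(b"TRACK"):
        raise FormatError(f"{path}: TRK magic 'TRACK' not found")
    voxel_size = np.array(fields[4:7], dtype=np.float64)
    n_scalars = int(fields[10])
    n_properties = int(fields[12])
    vox_to_ras = np.array(fields[14:30], dtype=np.float64).reshape(4, 4)
    n_count = int(fields[-3])
    version = int(fields[-2])
    if version != 2:
        raise UnsupportedDialectError(f"{path}: TRK version {version}, only v2 supported")
    if vox_to_ras[3, 3] == 0 or not np.any(vox_to_ras[:3, :3]):
        raise FormatError(
            f"{path}: voxel-to-RAS matrix is zero/absent; supply a reference "
            "volume affine to define world space"
        )
    if np.any(voxel_size <= 0):
        raise FormatError(f"{path}: non-positive voxel sizes {voxel_size}")

    world_affine = _trk_world_affine(voxel_size, vox_to_ras)

    fdt = np.dtype(byteorder + "f4")
    idt = np.dtype(byteorder + "i4")
    pos = 1000
    streamlines: list[np.ndarray] = []
    per_streamline_props: list[np.ndarray] = []
    per_point_scalars: list[np.ndarray] = []
    while pos < len(raw):
        if pos + 4 > len(raw):
            raise CorruptFileError(f"{path}: truncated at byte {pos} (point count)")
        npts = int(np.frombuffer(raw, dtype=idt, count=1, offset=pos)[0])
        pos += 4
        if npts < 0:
            raise CorruptFileError(f"{path}: negative point count at byte {pos - 4}")
        nfloats = npts * (3 + n_scalars)
        if pos + 4 * (nfloats + n_properties) > len(raw):
            raise CorruptFileError(f"{path}: truncated streamline data at byte {pos}")
        block = np.frombuffer(raw, dtype=fdt, count=nfloats, offset=pos).reshape(
            npts, 3 + n_scalars
        )
        pos += 4 * nfloats
        props = np.frombuffer(raw, dtype=fdt, count=n_properties, offset=pos).copy()
        pos += 4 * n_properties
        world = (
            block[:, :3].astype(np.float64) @ world_affine[:3, :3].T + world_affine[:3, 3]
        )
        streamlines.append(world.astype(np.float32))
        per_streamline_props.append(props)
        if n_scalars:
            per_point_scalars.append(block[:, 3:].copy())
    if n_count and n_count != len(streamlines):
        raise CorruptFileError(
            f"{path}: header declares {n_count} streamlines, parsed {len(streamlines)}"
        )

    meta: dict = {
        "source_format": "trk",
        "source_file": str(path),
        "trk_voxel_size": voxel_size,
        "trk_vox_to_ras": vox_to_ras,
    }
    if n_count:
        meta["declared_count"] = n_count
    if n_properties:
        meta["trk_properties"] = per_streamline_props
    if n_scalars:
        meta["trk_scalars"] = per_point_scalars
    return Tractogram(streamlines=streamlines, meta=meta)


def write_trk(
    t: Tractogram,
    path: PathLike,
    reference_affine: Optional[np.ndarray] = None,
    reference_shape: Optional[tuple[int, int, int]] = None,
) -> Path:
    """Write a Tractogram as TrackVis ``.trk`` v2.

    ``reference_affine`` (voxel -> world RAS) defines the TRK voxel frame;
    identity with unit voxels is used when omitted.  World coordinates are
    converted into the corner-origin voxel-mm convention on write.
    """
    path = Path(path)
    affine = np.eye(4) if reference_affine is None else validate_affine(reference_affine)
    voxel_size = np.linalg.norm(affine[:3, :3], axis=0)
    dim = reference_shape if reference_shape is not None else (1, 1, 1)

    world_affine = _trk_world_affine(voxel_size, affine)
    inv = np.linalg.inv(world_affine)

    axcodes = nib.orientations.aff2axcodes(affine)
    voxel_order = ("".join(axcodes) + "\x00")[:4].encode("ascii")

    header = struct.Struct("<" + _TRK_HEADER.format[1:]).pack(
        b"TRACK\x00",
        *[int(d) for d in dim],
        *[float(v) for v in voxel_size],
        0.0, 0.0, 0.0,              # origin (unused per spec)
        0,                           # n_scalars
        b"\x00" * 200,
        0,                           # n_properties
        b"\x00" * 200,
        *affine.astype(np.float32).ravel().tolist(),
        b"\x00" * 444,
        voxel_order,
        b"\x00" * 4,
        1.0, 0.0, 0.0, 0.0, 1.0, 0.0,  # image_orientation_patient
        b"\x00" * 2,
        0, 0, 0, 0, 0, 0,
        len(t),
        2,
        1000,
    )
    with open(path, "wb") as f:
        f.write(header)
        for s in t.streamlines:
            stored = np.asarray(s, np.float64) @ inv[:3, :3].T + inv[:3, 3]
            f.write(struct.pack("<i", len(s)))
            f.write(stored.astype("<f4").tobytes())
    return path


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volume(path: PathLike) -> VolumeImage:
    """Read a 3-D NIfTI volume (best available header affine)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValidationError(
            f"{path}: expected a 3-D volume, got shape {data.shape}"
        )
    return VolumeImage(values=np.asarray(data, dtype=np.float64), affine=img.affine)


def read_volume_4d(path: PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read a 4-D NIfTI (e.g. a 5tt image); returns (data[x,y,z,t], affine)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValidationError(f"{path}: expected a 4-D volume, got shape {data.shape}")
    return np.asarray(data, dtype=np.float64), np.asarray(img.affine, dtype=np.float64)


def write_volume(vol: VolumeImage, path: PathLike) -> Path:
    path = Path(path)
    dtype = np.uint8 if np.isin(vol.values, (0, 1)).all() else np.float32
    img = nib.Nifti1Image(vol.values.astype(dtype), vol.affine)
    nib.save(img, str(path))
    return path


def write_volume_4d(data: np.ndarray, affine: np.ndarray, path: PathLike) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
    return path


# ---------------------------------------------------------------------------
# FreeSurfer binary triangle surface
# ---------------------------------------------------------------------------

def _fread3(raw: bytes, pos: int) -> tuple[int, int]:
    b1, b2, b3 = raw[pos], raw[pos + 1], raw[pos + 2]
    return (b1 << 16) + (b2 << 8) + b3, pos + 3


def read_fs_surface(path: PathLike) -> SurfaceMesh:
    """Read a FreeSurfer binary triangle surface (big-endian).

    Vertices come back tagged ``space_tag='tkr'`` with ``cras_offset``
    populated from the volume-geometry footer; without a footer the offset is
    zero and a warning is logged.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 3:
        raise FormatError(f"{path}: too short for a FreeSurfer surface")
    magic, pos = _fread3(raw, 0)
    if magic != FS_TRIANGLE_MAGIC:
        raise FormatError(
            f"{path}: magic {magic} is not the triangle-file magic {FS_TRIANGLE_MAGIC}"
        )
    stamp_end = raw.find(b"\n\n", pos)
    if stamp_end < 0:
        raise CorruptFileError(f"{path}: creation stamp not terminated")
    pos = stamp_end + 2
    if pos + 8 > len(raw):
        raise CorruptFileError(f"{path}: truncated at vertex/face counts")
    n_vertices, n_faces = np.frombuffer(raw, dtype=">i4", count=2, offset=pos)
    pos += 8
    n_vertices, n_faces = int(n_vertices), int(n_faces)
    need = 12 * n_vertices + 12 * n_faces
    if pos + need > len(raw):
        raise CorruptFileError(
            f"{path}: truncated geometry (need {need} bytes at offset {pos})"
        )
    vertices = (
        np.frombuffer(raw, dtype=">f4", count=3 * n_vertices, offset=pos)
        .reshape(n_vertices, 3)
        .astype(np.float64)
    )
    pos += 12 * n_vertices
    faces = (
        np.frombuffer(raw, dtype=">i4", count=3 * n_faces, offset=pos)
        .reshape(n_faces, 3)
        .astype(np.int64)
    )
    pos += 12 * n_faces

    cras = _read_surface_footer_cras(raw, pos)
    if cras is None:
        logger.warning(
            "%s: no volume-geometry footer; assuming cras offset (0, 0, 0)", path
        )
        cras = np.zeros(3)
    return SurfaceMesh(vertices=vertices, faces=faces, space_tag="tkr", cras_offset=cras)


def _read_surface_footer_cras(raw: bytes, pos: int) -> Optional[np.ndarray]:
    """Parse cras from the volume-geometry footer, if present."""
    if pos + 4 > len(raw):
        return None
    head = int(np.frombuffer(raw, ">i4", count=1, offset=pos)[0])
    if head == 20:
        pos += 4
    elif pos + 12 <= len(raw):
        triple = np.frombuffer(raw, ">i4", count=3, offset=pos)
        if triple[0] == 2 and triple[2] == 20:
            pos += 12
        else:
            return None
    else:
        return None
    text = raw[pos:].decode("utf-8", errors="replace")
    for line in text.splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            if key.strip() == "cras":
                return np.array([float(x) for x in val.split()], dtype=np.float64)
    return None


def write_fs_surface(mesh: SurfaceMesh, path: PathLike) -> Path:
    """Write a FreeSurfer binary triangle surface with a volume-geometry footer."""
    path = Path(path)
    cras = mesh.cras_offset if mesh.cras_offset is not None else np.zeros(3)
    with open(path, "wb") as f:
        f.write(bytes([0xFF, 0xFF, 0xFE]))
        f.write(b"created by fsubextract\n\n")
        f.write(np.array([mesh.n_vertices, len(mesh.faces)], dtype=">i4").tobytes())
        f.write(mesh.vertices.astype(">f4").tobytes())
        f.write(mesh.faces.astype(">i4").tobytes())
        # volume-geometry footer (tag triple 2, 0, 20 then key = value text)
        f.write(np.array([2, 0, 20], dtype=">i4").tobytes())
        f.write(b"valid = 1  # volume info valid\n")
        f.write(b"filename = synthetic\n")
        f.write(b"volume = 256 256 256\n")
        f.write(b"voxelsize = 1.0000000000 1.0000000000 1.0000000000\n")
        f.write(b"xras   = 1.0000000000 0.0000000000 0.0000000000\n")
        f.write(b"yras   = 0.0000000000 1.0000000000 0.0000000000\n")
        f.write(b"zras   = 0.0000000000 0.0000000000 1.0000000000\n")
        f.write(
            f"cras   = {cras[0]:.10f} {cras[1]:.10f} {cras[2]:.10f}\n".encode("ascii")
        )
    return path


# ---------------------------------------------------------------------------
# FreeSurfer ASCII .label
# ---------------------------------------------------------------------------

def read_label(path: PathLike, hemisphere: str = "lh") -> VertexLabel:
    """Read a FreeSurfer ASCII .label file (comment, count, then rows)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty label file")
    start = 1 if lines[0].lstrip().startswith("#") else 0
    try:
        declared = int(lines[start].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: missing vertex-count line") from exc
    rows = lines[start + 1 :]
    if len(rows) != declared:
        raise CorruptFileError(
            f"{path}: declares {declared} vertices but has {len(rows)} data rows"
        )
    indices = np.empty(declared, dtype=np.int64)
    values = np.empty(declared, dtype=np.float64)
    for i, row in enumerate(rows):
        parts = row.split()
        if len(parts) < 5:
            raise CorruptFileError(f"{path}: malformed row {i + 1}: {row!r}")
        indices[i] = int(parts[0])
        values[i] = float(parts[4])
    try:
        return VertexLabel(vertex_indices=indices, values=values, hemisphere=hemisphere)
    except ValidationError as exc:
        raise CorruptFileError(f"{path}: {exc}") from exc


def write_label(
    label: VertexLabel, mesh: SurfaceMesh, path: PathLike, comment: str = "fsubextract"
) -> Path:
    """Write a .label file; vertex coordinates are taken from the bound mesh."""
    label.check_bounds(mesh)
    path = Path(path)
    values = label.values if label.values is not None else np.zeros(len(label))
    with open(path, "w") as f:
        f.write(f"#!ascii label {comment}\n")
        f.write(f"{len(label)}\n")
        for idx, val in zip(label.vertex_indices, values):
            x, y, z = mesh.vertices[idx]
            f.write(f"{idx}  {x:.6f}  {y:.6f}  {z:.6f} {val:.10f}\n")
    return path


# ---------------------------------------------------------------------------
# Plain-text affines and streamline weights
# ---------------------------------------------------------------------------

def read_affine_text(path: PathLike) -> np.ndarray:
    """Read a 4x4 affine from text (plain matrix or ITK transform file).

    Plain dialect: 16 (or 12) whitespace-delimited numbers, row-major.
    ITK dialect (``#Insight Transform File V1.0``): the 9 matrix entries and
    3 translation components of the ``Parameters:`` line, composed with the
    ``FixedParameters:`` center of rotation.
    """
    path = Path(path)
    text = path.read_text()
    first_line = text.splitlines()[0] if text.strip() else ""
    if "Insight Transform File" in first_line:
        return _read_itk_affine(path, text)
    numbers = []
    for token in text.replace(",", " ").split():
        try:
            numbers.append(float(token))
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric token {token!r}") from exc
    if len(numbers) == 16:
        m = np.array(numbers, dtype=np.float64).reshape(4, 4)
    elif len(numbers) == 12:
        m = np.vstack([np.array(numbers).reshape(3, 4), [0, 0, 0, 1]])
    else:
        raise FormatError(
            f"{path}: expected 16 (or 12) numbers for a 4x4 affine, got {len(numbers)}"
        )
    logger.info("%s: read plain-matrix affine", path)
    return validate_affine(m)


def _read_itk_affine(path: Path, text: str) -> np.ndarray:
    params = None
    fixed = np.zeros(3)
    for line in text.splitlines():
        if line.startswith("Parameters:"):
            params = np.array([float(x) for x in line.split()[1:]])
        elif line.startswith("FixedParameters:"):
            fixed = np.array([float(x) for x in line.split()[1:]])[:3]
    if params is None or len(params) != 12:
        raise FormatError(f"{path}: ITK transform must carry 12 Parameters")
    mat = params[:9].reshape(3, 3)
    translation = params[9:12]
    m = np.eye(4)
    m[:3, :3] = mat
    m[:3, 3] = translation + fixed - mat @ fixed
    logger.info("%s: read ITK-dialect affine", path)
    return validate_affine(m)


def write_affine_text(affine: np.ndarray, path: PathLike) -> Path:
    path = Path(path)
    np.savetxt(path, validate_affine(affine), fmt="%.12g")
    return path


def read_surface_map(path: PathLike) -> np.ndarray:
    """Read a plain-text per-vertex scalar map (one float per line)."""
    path = Path(path)
    try:
        return np.array([float(t) for t in path.read_text().split()], dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric map entry") from exc


def write_surface_map(values: np.ndarray, path: PathLike) -> Path:
    path = Path(path)
    with open(path, "w") as f:
        for v in np.asarray(values).ravel():
            f.write(f"{v:.10g}\n")
    return path


def read_weights(path: PathLike, n_expected: Optional[int] = None) -> np.ndarray:
    """Read a one-float-per-line streamline weight file (SIFT2-style sidecar)."""
    path = Path(path)
    tokens = path.read_text().split()
    try:
        w = np.array([float(t) for t in tokens], dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric weight entry") from exc
    if n_expected is not None and len(w) != n_expected:
        raise ValidationError(
            f"{path}: {len(w)} weights for {n_expected} streamlines"
        )
    if len(w) and not (w > 0).all():
        raise ValidationError(f"{path}: weights must all be > 0")
    return w


def write_weights(weights: np.ndarray, path: PathLike) -> Path:
    path = Path(path)
    with open(path, "w") as f:
        for w in np.asarray(weights).ravel():
            f.write(f"{w:.10g}\n")
    return path
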