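"""Labeled-volume I/O, structure hierarchy, oblique slicing and rendering.

A :class:`LabeledVolume` is a 3D raster of non-negative integer structure
IDs (0 = background) indexed ``labels[x, y, z]`` in the fixed atlas frame.
Slicing an oblique plane out of it uses nearest-neighbor lookup only --
interpolating IDs would fabricate structures that do not exist.

The structure taxonomy is a single-rooted tree (:class:`StructureGraph`)
with per-node hierarchy level and a fiber-tract flag; aggregation of a
label raster to a coarser level walks each ID up to its ancestor at that
level.
"""

from __future__ import annotations

import gzip
import io
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from sliceloc.frames import BrainFrame, PlaneParams, plane_geometry

# ---------------------------------------------------------------------------
# Structure hierarchy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructureNode:
    id: int
    parent_id: int | None
    acronym: str
    name: str
    level: int
    is_fiber_tract: bool = False


class StructureGraph:
    """Single-rooted structure taxonomy with levels and fiber-tract flags.

    Invariants enforced at construction: exactly one root, acyclic,
    ``level(child) == level(parent) + 1``, and fiber-tract status is
    hereditary (every descendant of a fiber-tract node is one too).
    """

    def __init__(self, nodes: Iterable[StructureNode]):
        self._nodes: dict[int, StructureNode] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise ValueError(f"duplicate structure id {node.id}")
            if node.id == 0:
                raise ValueError("structure id 0 is reserved for background")
            self._nodes[node.id] = node
        roots = [n for n in self._nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"structure graph must have exactly one root, found {len(roots)}")
        self._root = roots[0]
        for node in self._nodes.values():
            if node.parent_id is None:
                continue
            parent = self._nodes.get(node.parent_id)
            if parent is None:
                raise ValueError(f"node {node.id} refers to unknown parent {node.parent_id}")
            if node.level != parent.level + 1:
                raise ValueError(
                    f"node {node.id} has level {node.level}, parent {parent.id} "
                    f"has level {parent.level}; levels must increase by 1"
                )
            if parent.is_fiber_tract and not node.is_fiber_tract:
                raise ValueError(
                    f"node {node.id} under fiber-tract parent {parent.id} "
                    "must be flagged fiber tract"
                )
        # acyclicity: every node must reach the root
        for node in self._nodes.values():
            seen = set()
            cur = node
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise ValueError(f"cycle detected at node {node.id}")
                seen.add(cur.id)
                cur = self._nodes[cur.parent_id]

    # -- basic accessors ----------------------------------------------------

    @property
    def root(self) -> StructureNode:
        return self._root

    def __contains__(self, structure_id: int) -> bool:
        return int(structure_id) in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, structure_id: int) -> StructureNode:
        try:
            return self._nodes[int(structure_id)]
        except KeyError:
            raise KeyError(f"unknown structure id {structure_id}") from None

    def ids(self) -> list[int]:
        return sorted(self._nodes)

    def acronym(self, structure_id: int) -> str:
        return self.node(structure_id).acronym

    def children(self, structure_id: int) -> list[StructureNode]:
        return [n for n in self._nodes.values() if n.parent_id == int(structure_id)]

    def leaves(self) -> list[StructureNode]:
        parents = {n.parent_id for n in self._nodes.values() if n.parent_id is not None}
        return [n for n in self._nodes.values() if n.id not in parents]

    def ancestors(self, structure_id: int) -> list[StructureNode]:
        """Path from the node itself up to the root (inclusive)."""
        path = [self.node(structure_id)]
        while path[-1].parent_id is not None:
            path.append(self._nodes[path[-1].parent_id])
        return path

    def is_fiber_tract(self, structure_id: int) -> bool:
        """True if the node or any ancestor is flagged as a fiber tract."""
        return any(n.is_fiber_tract for n in self.ancestors(structure_id))

    def ancestor_at_level(self, structure_id: int, level: int) -> int:
        """ID of the ancestor at ``level`` (itself if already there; 0 if shallower)."""
        node = self.node(structure_id)
        if node.level < level:
            return 0
        while node.level > level:
            node = self._nodes[node.parent_id]
        return node.id

    def subtree_ids(self, structure_id: int) -> set[int]:
        """IDs of the node and all its descendants."""
        out = {int(structure_id)}
        frontier = [int(structure_id)]
        while frontier:
            nxt = [n.id for n in self._nodes.values() if n.parent_id in frontier]
            nxt = [i for i in nxt if i not in out]
            out.update(nxt)
            frontier = nxt
        return out

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": n.id,
                "parent_id": -1 if n.parent_id is None else n.parent_id,
                "acronym": n.acronym,
                "name": n.name,
                "level": n.level,
                "is_fiber_tract": int(n.is_fiber_tract),
            }
            for n in sorted(self._nodes.values(), key=lambda n: n.id)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StructureGraph":
        nodes = [
            StructureNode(
                id=int(r.id),
                parent_id=None if int(r.parent_id) < 0 else int(r.parent_id),
                acronym=str(r.acronym),
                name=str(r.name),
                level=int(r.level),
                is_fiber_tract=bool(int(r.is_fiber_tract)),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(nodes)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "StructureGraph":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "StructureGraph":
        with open(path) as fh:
            records = json.load(fh)
        return cls.from_frame(pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# Volume and slice containers
# ---------------------------------------------------------------------------


@dataclass
class LabeledVolume:
    """3D integer structure-ID raster in a physical frame (labels[x, y, z])."""

    labels: np.ndarray
    frame: BrainFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError(f"labels must be integer-typed, got {self.labels.dtype}")
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        if self.labels.min() < 0:
            raise ValueError("structure IDs must be non-negative")
        if tuple(self.labels.shape) != tuple(self.frame.shape_vox):
            raise ValueError(
                f"raster shape {self.labels.shape} != frame shape {self.frame.shape_vox}"
            )

    def id_set(self) -> set[int]:
        return set(np.unique(self.labels).tolist())

    def validate_against(self, graph: StructureGraph) -> None:
        missing = sorted(i for i in self.id_set() if i != 0 and i not in graph)
        if missing:
            raise ValueError(f"volume contains IDs absent from the structure graph: {missing}")


@dataclass
class LabeledSlice:
    """2D structure-ID raster extracted from a volume.

    ``labels[row, col]`` with rows along y (dorsal->ventral) and columns
    along x (left->right).  ``plane`` is the generating PlaneParams, or a
    list of per-component planes for multiplane extractions.
    """

    labels: np.ndarray
    pixel_size_um: float
    plane: PlaneParams | list[PlaneParams]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError(f"slice labels must be integer-typed, got {self.labels.dtype}")
        if self.labels.ndim != 2:
            raise ValueError(f"slice labels must be 2D, got shape {self.labels.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel size must be positive, got {self.pixel_size_um}")

    def id_set(self) -> set[int]:
        return set(np.unique(self.labels).tolist())


# ---------------------------------------------------------------------------
# Volume I/O: NIfTI via nibabel, NRRD via a minimal built-in codec
# ---------------------------------------------------------------------------

_NRRD_DTYPES = {
    "uint8": np.uint8, "uint16": np.uint16, "uint32": np.uint32, "uint64": np.uint64,
    "int8": np.int8, "int16": np.int16, "int32": np.int32, "int64": np.int64,
    "unsigned char": np.uint8, "unsigned short": np.uint16, "unsigned int": np.uint32,
    "signed char": np.int8, "short": np.int16, "int": np.int32,
}


def _read_nrrd(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Minimal NRRD reader: text header, raw or gzip encoding, C order."""
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n"):
                break
            if not line:
                raise ValueError(f"{path}: truncated NRRD header")
            text = line.decode("ascii").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, _, value = text.partition(":")
            fields[key.strip().lower()] = value.lstrip("=").strip()
        data = fh.read()

    dtype_name = fields.get("type", "")
    if dtype_name not in _NRRD_DTYPES:
        raise ValueError(f"{path}: voxel type must be integer, got {dtype_name!r}")
    dtype = np.dtype(_NRRD_DTYPES[dtype_name])
    sizes = tuple(int(s) for s in fields["sizes"].split())
    if len(sizes) != 3:
        raise ValueError(f"{path}: expected a 3D volume, sizes={sizes}")
    if "spacings" in fields:
        spacing = tuple(float(s) for s in fields["spacings"].split())
    elif "space directions" in fields:
        spacing = tuple(
            float(np.linalg.norm([float(x) for x in vec.strip("()").split(",")]))
            for vec in fields["space directions"].split(") (")
        )
    else:
        raise ValueError(f"{path}: NRRD header missing spacing information")
    endian = fields.get("endian", "little")
    encoding = fields.get("encoding", "raw")
    if encoding in ("gzip", "gz"):
        data = gzip.decompress(data)
    elif encoding != "raw":
        raise ValueError(f"{path}: unsupported NRRD encoding {encoding!r}")
    arr = np.frombuffer(data, dtype=dtype.newbyteorder("<" if endian == "little" else ">"))
    if arr.size != int(np.prod(sizes)):
        raise ValueError(f"{path}: data size {arr.size} does not match sizes {sizes}")
    # NRRD lists sizes fastest-first; raw buffer is fastest-axis contiguous,
    # i.e. Fortran order w.r.t. the (x, y, z) size tuple.
    return arr.reshape(sizes, order="F").astype(dtype), spacing


def _write_nrrd(
    path: str | os.PathLike,
    labels: np.ndarray,
    spacing_um: Sequence[float],
) -> None:
    dtype = labels.dtype
    name = {np.dtype(np.uint8): "uint8", np.dtype(np.uint16): "uint16",
            np.dtype(np.uint32): "uint32", np.dtype(np.uint64): "uint64",
            np.dtype(np.int8): "int8", np.dtype(np.int16): "int16",
            np.dtype(np.int32): "int32", np.dtype(np.int64): "int64"}.get(dtype)
    if name is None:
        raise TypeError(f"cannot write non-integer voxel type {dtype} to NRRD")
    header = (
        "NRRD0004\n"
        f"type: {name}\n"
        "dimension: 3\n"
        f"sizes: {labels.shape[0]} {labels.shape[1]} {labels.shape[2]}\n"
        f"spacings: {spacing_um[0]:g} {spacing_um[1]:g} {spacing_um[2]:g}\n"
        "endian: little\n"
        "encoding: gzip\n"
        "\n"
    )
    payload = gzip.compress(
        np.ascontiguousarray(labels.transpose(2, 1, 0)).astype(dtype.newbyteorder("<")).tobytes()
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload)


def _format_of(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    s = str(path).lower()
    if s.endswith(".nrrd"):
        return "nrrd"
    if s.endswith(".nii") or s.endswith(".nii.gz"):
        return "nifti"
    raise ValueError(f"cannot infer volume format from {path}; pass format explicitly")


def read_labeled_volume(
    path: str | os.PathLike, format: str | None = None, origin_um=(0.0, 0.0, 0.0)
) -> LabeledVolume:
    """Read a labeled volume from NRRD or NIfTI-1, normalizing axes to (x, y, z).

    Spacing is taken from the file header (interpreted as micrometers).
    Non-integer voxel types are rejected: structure IDs are categorical.
    """
    fmt = _format_of(path, format)
    if fmt == "nrrd":
        labels, spacing = _read_nrrd(path)
    elif fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        if not np.issubdtype(img.get_data_dtype(), np.integer):
            raise ValueError(f"{path}: voxel type must be integer, got {img.get_data_dtype()}")
        labels = np.asarray(img.dataobj).astype(img.get_data_dtype())
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        if any(z <= 0 for z in spacing):
            raise ValueError(f"{path}: missing or non-positive voxel spacing {spacing}")
    else:
        raise ValueError(f"unknown volume format {fmt!r}; use 'nrrd' or 'nifti'")
    frame = BrainFrame(voxel_size_um=spacing, shape_vox=labels.shape, origin_um=origin_um)
    return LabeledVolume(labels=labels, frame=frame)


def write_labeled_volume(volume: LabeledVolume, path: str | os.PathLike,
                         format: str | None = None) -> None:
    """Write a labeled volume as NRRD (built-in codec) or NIfTI-1 (nibabel)."""
    fmt = _format_of(path, format)
    if fmt == "nrrd":
        _write_nrrd(path, volume.labels, volume.frame.voxel_size_um)
    elif fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(volume.frame.voxel_size_um) + [1.0])
        affine[:3, 3] = volume.frame.origin_um
        img = nib.Nifti1Image(volume.labels, affine)
        img.header.set_zooms(volume.frame.voxel_size_um)
        nib.save(img, str(path))
    else:
        raise ValueError(f"unknown volume format {fmt!r}; use 'nrrd' or 'nifti'")


# ---------------------------------------------------------------------------
# Oblique and multiplane slicing
# ---------------------------------------------------------------------------


def slice_grid_um(
    plane: PlaneParams, out_pixel_um: float, out_shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, y) coordinates of each output pixel center.

    The output canvas is centered on the plane's in-plane anchor point:
    pixel (row r, col c) sits at x = x_c + (c - (W-1)/2) * pix and
    y = y_c + (r - (H-1)/2) * pix.
    """
    h, w = out_shape
    xc, yc = plane.center_xy_um
    cols = (np.arange(w) - (w - 1) / 2.0) * out_pixel_um + xc
    rows = (np.arange(h) - (h - 1) / 2.0) * out_pixel_um + yc
    return np.meshgrid(cols, rows)  # x[r, c], y[r, c]


def _default_canvas(volume: LabeledVolume, out_pixel_um: float) -> tuple[int, int]:
    ex, ey, _ = volume.frame.extent_um
    return (int(round(ey / out_pixel_um)) + 1, int(round(ex / out_pixel_um)) + 1)


def slice_oblique(
    volume: LabeledVolume,
    plane: PlaneParams,
    out_pixel_um: float | None = None,
    out_shape: tuple[int, int] | None = None,
) -> LabeledSlice:
    """Extract the oblique plane as a 2D label raster (nearest-neighbor).

    For each output pixel, the physical (x, y) comes from the pixel grid and
    z from the plane's height function; the label is the nearest voxel.
    Coordinates outside the volume map to background 0.  The default pixel
    size is the volume's x voxel size and the default canvas spans the full
    x-y extent.
    """
    if out_pixel_um is None:
        out_pixel_um = volume.frame.voxel_size_um[0]
    if out_shape is None:
        out_shape = _default_canvas(volume, out_pixel_um)

    lo, hi = volume.frame.ap_range_um()
    zc = plane_geometry(plane)(plane.center_xy_um[0], plane.center_xy_um[1])
    if not (lo <= float(zc) <= hi):
        raise ValueError(
            f"plane AP position {float(zc):g} um at the anchor lies outside the "
            f"volume extent [{lo:g}, {hi:g}] um"
        )

    x_um, y_um = slice_grid_um(plane, out_pixel_um, out_shape)
    z_um = plane_geometry(plane)(x_um, y_um)
    labels = sample_volume_nearest(volume, x_um, y_um, z_um)
    return LabeledSlice(
        labels=labels, pixel_size_um=float(out_pixel_um), plane=plane,
        provenance="slice_oblique",
    )


def sample_volume_nearest(
    volume: LabeledVolume, x_um: np.ndarray, y_um: np.ndarray, z_um: np.ndarray
) -> np.ndarray:
    """Nearest-voxel label lookup at physical coordinates; out of volume -> 0."""
    ox, oy, oz = volume.frame.origin_um
    vx, vy, vz = volume.frame.voxel_size_um
    ix = np.rint((np.asarray(x_um, float) - ox) / vx).astype(np.int64)
    iy = np.rint((np.asarray(y_um, float) - oy) / vy).astype(np.int64)
    iz = np.rint((np.asarray(z_um, float) - oz) / vz).astype(np.int64)
    nx, ny, nz = volume.frame.shape_vox
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
    out = np.zeros(np.broadcast(ix, iy, iz).shape, dtype=volume.labels.dtype)
    out[inside] = volume.labels[ix[inside], iy[inside], iz[inside]]
    return out


def slice_multiplane(
    volume: LabeledVolume,
    component_planes: Mapping[str, PlaneParams],
    component_boxes: Mapping[str, tuple[int, int, int, int]],
    out_pixel_um: float | None = None,
    out_shape: tuple[int, int] | None = None,
    canvas_plane: PlaneParams | None = None,
) -> LabeledSlice:
    """Compose a slice from per-component planes, each filling its own box.

    ``component_boxes`` maps component name -> (row0, row1, col0, col1)
    half-open pixel ranges on the shared output canvas; boxes must be
    disjoint and every boxed component must have a plane.  Pixels outside
    all boxes are background.  The canvas geometry (pixel grid placement)
    follows ``canvas_plane`` if given, else the first component plane.
    """
    if out_pixel_um is None:
        out_pixel_um = volume.frame.voxel_size_um[0]
    if set(component_boxes) - set(component_planes):
        missing = sorted(set(component_boxes) - set(component_planes))
        raise ValueError(f"components without a plane: {missing}")

    planes = list(component_planes.values())
    ref = canvas_plane if canvas_plane is not None else (
        planes[0] if planes else PlaneParams(0.0, 0.0, volume.frame.ap_range_um()[0])
    )
    if out_shape is None:
        out_shape = _default_canvas(volume, out_pixel_um)

    occupancy = np.zeros(out_shape, dtype=np.uint8)
    out = np.zeros(out_shape, dtype=volume.labels.dtype)
    for name, (r0, r1, c0, c1) in component_boxes.items():
        if not (0 <= r0 <= r1 <= out_shape[0] and 0 <= c0 <= c1 <= out_shape[1]):
            raise ValueError(f"component {name!r} box {(r0, r1, c0, c1)} exceeds canvas {out_shape}")
        if occupancy[r0:r1, c0:c1].any():
            raise ValueError(f"component {name!r} box overlaps a previous component")
        occupancy[r0:r1, c0:c1] = 1
        plane = component_planes[name]
        # same canvas grid for every component: anchor the grid at the
        # reference plane's center, evaluate z under the component's plane
        x_um, y_um = slice_grid_um(
            PlaneParams(plane.alpha_deg, plane.beta_deg, plane.d_um, ref.center_xy_um),
            out_pixel_um, out_shape,
        )
        z_um = plane_geometry(
            PlaneParams(plane.alpha_deg, plane.beta_deg, plane.d_um, ref.center_xy_um)
        )(x_um, y_um)
        sub = sample_volume_nearest(
            volume, x_um[r0:r1, c0:c1], y_um[r0:r1, c0:c1], z_um[r0:r1, c0:c1]
        )
        out[r0:r1, c0:c1] = sub
    return LabeledSlice(
        labels=out, pixel_size_um=float(out_pixel_um),
        plane=[component_planes[k] for k in component_boxes],
        provenance="slice_multiplane",
    )


# ---------------------------------------------------------------------------
# Simplified rendering and hierarchical aggregation
# ---------------------------------------------------------------------------

#: Rendering palette: background, generic foreground, fiber tracts.
COLOR_BACKGROUND = (0, 0, 0)
COLOR_FOREGROUND = (0, 160, 0)
COLOR_FIBER_TRACT = (128, 128, 128)


def simplify_atlas_slice(
    slc: LabeledSlice,
    graph: StructureGraph,
    background_rgb: tuple[int, int, int] = COLOR_BACKGROUND,
    foreground_rgb: tuple[int, int, int] = COLOR_FOREGROUND,
    fiber_rgb: tuple[int, int, int] = COLOR_FIBER_TRACT,
) -> np.ndarray:
    """Render a label slice with fiber tracts gray on a plain green foreground.

    The simplified representation carries only the contrast a histological
    section actually shows (white matter vs everything else), so that an
    intensity-based similarity metric can compare the two.  Output is an
    RGB uint8 image with at most 3 distinct colors.
    """
    ids = np.unique(slc.labels)
    unknown = sorted(int(i) for i in ids if i != 0 and int(i) not in graph)
    if unknown:
        raise KeyError(f"slice contains IDs absent from the structure graph: {unknown}")
    out = np.empty(slc.labels.shape + (3,), dtype=np.uint8)
    out[...] = background_rgb
    fiber_ids = {int(i) for i in ids if i != 0 and graph.is_fiber_tract(int(i))}
    fg = slc.labels != 0
    out[fg] = foreground_rgb
    if fiber_ids:
        fiber_mask = np.isin(slc.labels, sorted(fiber_ids))
        out[fiber_mask] = fiber_rgb
    return out


def aggregate_labels(slc: LabeledSlice, graph: StructureGraph, level: int) -> LabeledSlice:
    """Replace each ID by its ancestor at ``level`` (0 if the ID is shallower).

    Background stays background.  Aggregation at a fixed level is
    idempotent and commutes with nearest-neighbor slicing.
    """
    if level < 1:
        raise ValueError(f"level must be >= 1, got {level}")
    ids = np.unique(slc.labels)
    lut = {0: 0}
    for i in ids:
        i = int(i)
        if i == 0:
            continue
        if i not in graph:
            raise KeyError(f"unknown structure id {i}")
        lut[i] = graph.ancestor_at_level(i, level)
    out = np.zeros_like(slc.labels)
    for src, dst in lut.items():
        if dst != 0:
            out[slc.labels == src] = dst
    return LabeledSlice(
        labels=out, pixel_size_um=slc.pixel_size_um, plane=slc.plane,
        provenance=f"{slc.provenance}|aggregated@{level}",
    )


def aggregate_volume(volume: LabeledVolume, graph: StructureGraph, level: int) -> LabeledVolume:
    """Volume-wise version of :func:`aggregate_labels` (used by commutation tests)."""
    if level < 1:
        raise ValueError(f"level must be >= 1, got {level}")
    ids = np.unique(volume.labels)
    out = np.zeros_like(volume.labels)
    for i in ids:
        i = int(i)
        if i == 0:
            continue
        dst = graph.ancestor_at_level(i, level)
        if dst != 0:
            out[volume.labels == i] = dst
    return LabeledVolume(labels=out, frame=volume.frame)
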