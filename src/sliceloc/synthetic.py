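"""Synthetic fixtures: labeled brain phantom, simulated sections and raters.

The phantom stands in for the real annotated reference volume.  It is a
bilaterally symmetric arrangement of ellipsoidal solids laid out along the
anteroposterior (z) axis so that the same plate-number zones used for group
routing exist in the phantom:

* an anterior olfactory bulb (plates 1-22) built of concentric layers, the
  material for group-A segmentation;
* a mid cerebrum (plates 23-83) with per-hemisphere cortex, subcortical
  plate, deep nuclei and a designated fiber-tract ring whose radii modulate
  continuously with z, making the AP position identifiable from a single
  cross-section;
* a posterior zone (plates 84-103) where the cerebrum is split
  mid-sagittally into left/right components and a detached ventral
  brainstem appears -- the group-C configuration;
* a hindbrain zone (plates 104+) where a dorsal cerebellum rejoins the
  brainstem into a single blob (group B').

Sections are simulated by oblique slicing followed by a known smooth
deformation, a staining-style rendering and optional artifacts (uneven
staining, shrinkage, tears, loss of a cerebrum, an independent brainstem
plane), with the full ground truth retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from sliceloc.atlas import (
    LabeledSlice,
    LabeledVolume,
    StructureGraph,
    StructureNode,
    sample_volume_nearest,
    slice_grid_um,
    slice_oblique,
)
from sliceloc.frames import ARA_MAX, BrainFrame, PlaneParams, plane_geometry
from sliceloc.localization import ComponentBox, ComponentReport

# AP zone boundaries (micrometers), aligned with the published group ranges:
# plates 1-22 anterior, 23-83 mid, 84-103 posterior, 104-132 hindbrain.
Z_A_END = 2150.0
Z_C_START = 8350.0
Z_C_END = 10250.0


# ---------------------------------------------------------------------------
# Phantom specification and structure table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic phantom parameters.

    The default shape at 50 um voxels spans the full plate range along z
    (13.15 mm); ``n_ap_lobes`` sets how many AP label bands subdivide each
    cerebral shell, so neighboring plates carry different leaf IDs.
    """

    shape_vox: tuple[int, int, int] = (160, 128, 264)
    voxel_um: float = 50.0
    n_ap_lobes: int = 3
    seed: int = 0


def _phantom_nodes(n_lobes: int) -> list[StructureNode]:
    N = StructureNode
    nodes = [
        N(1, None, "BRAIN", "whole brain", 1),
        N(2, 1, "CER", "cerebrum", 2),
        N(3, 1, "HB", "brainstem and hindbrain", 2),
        N(4, 1, "OLF", "olfactory areas", 2),
        N(5, 1, "FIB", "fiber systems", 2, True),
        N(21, 2, "CTX", "cortical shell", 3),
        N(25, 2, "SUB", "subcortical plate", 3),
        N(31, 2, "NUC", "deep nuclei", 3),
        N(41, 4, "MOB", "main olfactory bulb", 3),
        N(47, 4, "AOBg", "accessory olfactory bulb group", 3),
        N(51, 3, "BSC", "brainstem core group", 3),
        N(55, 3, "BSS", "brainstem shell group", 3),
        N(57, 3, "CB", "cerebellum", 3),
        N(61, 5, "cing", "cerebral tracts", 3, True),
        N(65, 5, "olt", "olfactory tracts", 3, True),
        N(42, 41, "MOBgl", "MOB glomerular layer", 4),
        N(43, 41, "MOBopl", "MOB outer plexiform layer", 4),
        N(44, 41, "MOBgr", "MOB granule layer", 4),
        N(48, 47, "AOB", "accessory olfactory bulb", 4),
        N(52, 51, "BSc", "brainstem core", 4),
        N(56, 55, "BSs", "brainstem shell", 4),
        N(58, 57, "CBctx", "cerebellar cortex", 4),
        N(62, 61, "fr-L", "fiber ring left", 4, True),
        N(63, 61, "fr-R", "fiber ring right", 4, True),
        N(66, 65, "olt-c", "olfactory tract core", 4, True),
        N(67, 61, "dmf", "dorsal midline fibers", 4, True),
    ]
    for k in range(n_lobes):
        nodes += [
            N(210 + 2 * k, 21, f"CTX{k}-L", f"cortex band {k} left", 4),
            N(211 + 2 * k, 21, f"CTX{k}-R", f"cortex band {k} right", 4),
            N(250 + 2 * k, 25, f"SUB{k}-L", f"subplate band {k} left", 4),
            N(251 + 2 * k, 25, f"SUB{k}-R", f"subplate band {k} right", 4),
            N(310 + 2 * k, 31, f"NUC{k}-L", f"nuclei band {k} left", 4),
            N(311 + 2 * k, 31, f"NUC{k}-R", f"nuclei band {k} right", 4),
        ]
    return nodes


def mirror_label_map(graph: StructureGraph) -> dict[int, int]:
    """Left<->right structure-ID swap map (midline structures map to self)."""
    by_acronym = {graph.node(i).acronym: i for i in graph.ids()}
    out = {}
    for i in graph.ids():
        ac = graph.node(i).acronym
        if ac.endswith("-L"):
            out[i] = by_acronym[ac[:-2] + "-R"]
        elif ac.endswith("-R"):
            out[i] = by_acronym[ac[:-2] + "-L"]
        else:
            out[i] = i
    return out


def make_phantom(spec: PhantomSpec | None = None) -> tuple[LabeledVolume, StructureGraph]:
    """Build the labeled phantom volume and its structure taxonomy.

    Deterministic given the spec (the seed only perturbs the phase of the
    radial modulations).  The volume is mirror-symmetric about the
    mid-sagittal plane under the left<->right label swap.
    """
    spec = spec or PhantomSpec()
    nx, ny, nz = spec.shape_vox
    if min(nx, ny, nz) < 32:
        raise ValueError(f"phantom shape must be at least 32 on every axis, got {spec.shape_vox}")
    frame = BrainFrame(voxel_size_um=(spec.voxel_um,) * 3, shape_vox=spec.shape_vox)
    graph = StructureGraph(_phantom_nodes(spec.n_ap_lobes))

    Lx, Ly, Lz = frame.extent_um
    v = spec.voxel_um
    x = (np.arange(nx) * v)[:, None, None]
    y = (np.arange(ny) * v)[None, :, None]
    z = (np.arange(nz) * v)[None, None, :]
    cx = Lx / 2.0

    rng = np.random.default_rng(spec.seed)
    ph1, ph2, ph3 = rng.uniform(0, 2 * math.pi, size=3)

    labels = np.zeros(spec.shape_vox, dtype=np.int16)
    zA = min(Z_A_END, 0.35 * Lz)           # clip zones for short volumes
    zC0 = min(Z_C_START, 0.75 * Lz)
    zC1 = min(Z_C_END, 0.90 * Lz)

    def inplane_u(xc_, yc_, ax_, ay_, zc_, az_):
        """Normalized in-plane radius inside an ellipsoid; >1 outside."""
        g = 1.0 - ((z - zc_) / az_) ** 2
        scale = np.sqrt(np.clip(g, 1e-9, None))
        u = np.sqrt(((x - xc_) / (ax_ * scale)) ** 2 + ((y - yc_) / (ay_ * scale)) ** 2)
        u[np.broadcast_to(g <= 0, u.shape)] = 2.0
        return u

    # --- olfactory bulb (anterior) -----------------------------------------
    bulb_zc, bulb_az = zA * 0.45, zA * 1.05
    u_bulb = inplane_u(cx, 0.42 * Ly, 0.30 * Lx, 0.26 * Ly, bulb_zc, bulb_az)
    in_bulb = (u_bulb <= 1.0) & (z < zA)
    labels[in_bulb & (u_bulb > 0.78)] = 42                      # MOBgl
    labels[in_bulb & (u_bulb > 0.52) & (u_bulb <= 0.78)] = 43   # MOBopl
    labels[in_bulb & (u_bulb > 0.18) & (u_bulb <= 0.52)] = 44   # MOBgr
    labels[in_bulb & (u_bulb <= 0.18)] = 66                     # olfactory tract
    # accessory bulb: small dorsal blob near the posterior end of the zone
    u_aob = inplane_u(cx, 0.26 * Ly, 0.12 * Lx, 0.10 * Ly, zA * 0.85, zA * 0.25)
    labels[(u_aob <= 1.0) & (z < zA)] = 48

    # --- cerebrum (mid + posterior) -----------------------------------------
    cer_yc = 0.40 * Ly
    cer_zc = 0.45 * Lz
    cer_az = 0.38 * Lz
    # outline wobble: the cross-section radius breathes along z so the outer
    # contour itself identifies the AP position of an oblique cut
    wobble = 1.0 + 0.05 * np.sin(2 * math.pi * z / 2100.0 + ph1) \
                 + 0.05 * np.sin(2 * math.pi * z / 800.0 + ph3) \
                 - 0.06 * (z / max(Lz, 1.0))  # monotone taper breaks AP aliasing
    u_cer = inplane_u(cx, cer_yc, 0.42 * Lx * wobble, 0.33 * Ly * wobble,
                      cer_zc, cer_az)
    in_cer = (u_cer <= 1.0) & (z >= zA) & (z <= zC1)
    # ventral flat cut whose depth oscillates along AP: localizes the
    # dorsoventral tilt (beta) from the outline alone
    scale_cer = np.sqrt(np.clip(1.0 - ((z - cer_zc) / cer_az) ** 2, 0.0, None))
    vcut = 0.55 + 0.30 * np.sin(2 * math.pi * z / 1100.0 + ph2)
    in_cer &= np.broadcast_to(
        (y - cer_yc) < 0.33 * Ly * wobble * scale_cer * vcut, in_cer.shape
    )

    span = max(zC0 - zA, 1.0)
    band = np.clip(((z - zA) / span * spec.n_ap_lobes).astype(int), 0, spec.n_ap_lobes - 1)
    band = np.broadcast_to(band, labels.shape)
    right = np.broadcast_to(x >= cx, labels.shape)

    zz = np.broadcast_to((z - zA), labels.shape)
    r_fib = 0.58 + 0.12 * np.sin(2 * math.pi * zz / 1600.0 + ph1)
    r_nuc = 0.38 + 0.12 * np.sin(2 * math.pi * zz / 1800.0 + ph2)
    r_ctx = 0.82 + 0.06 * np.sin(2 * math.pi * zz / 3400.0 + ph3)

    ctx = in_cer & (u_cer > r_ctx)
    fib = in_cer & (u_cer > r_fib) & (u_cer <= r_fib + 0.12) & ~ctx
    nuc = in_cer & (u_cer <= r_nuc)
    sub = in_cer & ~ctx & ~fib & ~nuc
    for k in range(spec.n_ap_lobes):
        bk = band == k
        labels[ctx & bk & ~right] = 210 + 2 * k
        labels[ctx & bk & right] = 211 + 2 * k
        labels[sub & bk & ~right] = 250 + 2 * k
        labels[sub & bk & right] = 251 + 2 * k
        labels[nuc & bk & ~right] = 310 + 2 * k
        labels[nuc & bk & right] = 311 + 2 * k
    labels[fib & ~right] = 62
    labels[fib & right] = 63
    # dorsal midline fiber column with AP-varying width (second beta marker)
    wxd = Lx * (0.050 + 0.042 * np.sin(2 * math.pi * z / 900.0 + ph3))
    dmf = in_cer & (u_cer > 0.30) & np.broadcast_to(
        (y < cer_yc) & (np.abs(x - cx) < wxd), in_cer.shape
    )
    labels[dmf] = 67

    # posterior mid-sagittal gap: the cerebrum detaches into two components
    gap = max(2.0 * v, 100.0)
    post = np.broadcast_to(z >= zC0, labels.shape)
    mid = np.broadcast_to(np.abs(x - cx) < gap, labels.shape)
    labels[post & mid & in_cer] = 0

    # --- brainstem (posterior + hindbrain) ----------------------------------
    bs_zc = min(0.81 * Lz, zC0 + 0.5 * (Lz - zC0) + 0.06 * Lz)
    bs_az = max(Lz - bs_zc, 0.16 * Lz) * 1.05
    u_bs = inplane_u(cx, 0.78 * Ly, 0.22 * Lx, 0.14 * Ly, bs_zc, bs_az)
    in_bs = (u_bs <= 1.0) & (z >= zC0)
    # cerebellum: dorsal blob in the hindbrain zone, touching the brainstem
    u_cb = inplane_u(cx, 0.42 * Ly, 0.30 * Lx, 0.28 * Ly,
                     (zC1 + Lz) / 2.0, (Lz - zC1) * 0.70)
    in_cb = (u_cb <= 1.0) & (z > zC1)
    labels[in_cb] = 58
    labels[in_bs & (u_bs <= 0.62)] = 52
    labels[in_bs & (u_bs > 0.62)] = 56

    volume = LabeledVolume(labels=labels, frame=frame)
    volume.validate_against(graph)
    return volume, graph


# ---------------------------------------------------------------------------
# Histology-style rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HistologyStyle:
    """Rendering knobs for the simulated stain.

    ``bias_amplitude`` bounds the multiplicative uneven-staining field to
    [1-a, 1+a] (so any two pixels' bias ratio is <= (1+a)/(1-a));
    ``noise_sd`` is the additive Gaussian noise level on [0, 1] intensities;
    ``fiber_intensity`` is the low base intensity of white matter, which is
    visibly darker than gray matter in fluorescent sections.
    """

    bias_amplitude: float = 0.2
    noise_sd: float = 0.02
    bias_grid: int = 4
    fiber_intensity: float = 0.12


def _base_intensity(structure_id: int) -> float:
    """Deterministic per-region stain intensity in [0.30, 0.90]."""
    h = (structure_id * 2654435761) % (2**32)
    return 0.30 + 0.60 * (h / 2**32)


def render_histology(
    truth_labels: LabeledSlice | np.ndarray,
    style: HistologyStyle | None = None,
    seed: int = 0,
    graph: StructureGraph | None = None,
) -> np.ndarray:
    """Render a label slice as a grayscale 'stained' image in [0, 1].

    Per-region base intensity (fiber tracts dark when a graph is supplied),
    a smooth multiplicative bias field (uneven staining) and Gaussian
    noise; background stays 0.  Deterministic per (inputs, seed).
    """
    style = style or HistologyStyle()
    labels = truth_labels.labels if isinstance(truth_labels, LabeledSlice) else np.asarray(truth_labels)
    rng = np.random.default_rng(seed)
    img = np.zeros(labels.shape, dtype=float)
    for i in np.unique(labels):
        i = int(i)
        if not i:
            continue
        if graph is not None and i in graph and graph.is_fiber_tract(i):
            img[labels == i] = style.fiber_intensity
        else:
            img[labels == i] = _base_intensity(i)
    g = style.bias_grid
    coarse = rng.uniform(-1.0, 1.0, size=(g, g))
    bias = sktransform.resize(coarse, labels.shape, order=3, mode="reflect",
                              preserve_range=True)
    peak = np.abs(bias).max()
    if peak > 0:
        bias = bias / peak
    bias = 1.0 + style.bias_amplitude * bias
    img *= bias
    img += rng.normal(0.0, style.noise_sd, size=labels.shape) * (labels != 0)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Section simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeformSpec:
    """Smooth random deformation and artifact magnitudes for one section.

    The deformation is a Gaussian-smoothed random displacement capped at
    ``max_displacement_px``; ``shrink_scale`` < 1 adds a global tissue
    shrinkage about the canvas center; tears punch background blobs into
    the image only.  ``delete_cerebrum`` in {None, 'left', 'right'} and
    ``brainstem_offset_um`` inject the posterior detachment artifacts.
    """

    max_displacement_px: float = 3.0
    grid: int = 6
    shrink_scale: float = 1.0
    n_tears: int = 0
    tear_frac: float = 0.05
    delete_cerebrum: str | None = None
    brainstem_offset_um: float = 0.0


def artifact_defaults(level: int) -> tuple[DeformSpec, HistologyStyle]:
    """Stated artifact taxonomy: 1 = staining only, 2 = + shrinkage and
    noise, 3 = + tears (posterior options are opt-in via DeformSpec)."""
    if level == 1:
        # uneven staining only, no morphological change beyond slight warp
        return DeformSpec(max_displacement_px=1.0), HistologyStyle()
    if level == 2:
        return (DeformSpec(max_displacement_px=5.0, shrink_scale=0.95),
                HistologyStyle(noise_sd=0.04))
    if level == 3:
        return (DeformSpec(max_displacement_px=8.0, shrink_scale=0.95, n_tears=3),
                HistologyStyle(noise_sd=0.05))
    raise ValueError(f"artifact level must be 1, 2 or 3, got {level}")


@dataclass
class SimulatedSection:
    image: np.ndarray
    truth_plane: PlaneParams | dict[str, PlaneParams]
    truth_labels: LabeledSlice
    truth_field: np.ndarray  # (H, W, 2) pull-back displacement, pixels
    artifact_level: int
    component_truth: ComponentReport | None
    seed: int
    pixel_size_um: float
    artifacts: list[str] = field(default_factory=list)


def random_smooth_field(
    shape: tuple[int, int], max_px: float, grid: int, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random pull-back displacement field capped at max_px."""
    field_ = rng.normal(size=(grid, grid, 2))
    out = np.stack(
        [sktransform.resize(field_[..., k], shape, order=3, mode="reflect",
                            preserve_range=True) for k in range(2)],
        axis=-1,
    )
    mag = np.sqrt((out ** 2).sum(-1)).max()
    if mag > 0:
        out *= max_px / mag
    return out


def warp_labels_by_field(labels: np.ndarray, field_: np.ndarray) -> np.ndarray:
    """Nearest-neighbor pull-back warp: out[p] = labels[p + field(p)]."""
    h, w = labels.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([rr + field_[..., 0], cc + field_[..., 1]])
    return ndimage.map_coordinates(labels, coords, order=0, mode="constant", cval=0)


def _component_truth(labels: np.ndarray, graph: StructureGraph,
                     x_mid_col: float) -> ComponentReport:
    """Ground-truth component report from subtree membership of the labels."""
    bs_ids = sorted(graph.subtree_ids(3))
    stem = np.isin(labels, bs_ids)
    cer = (labels != 0) & ~stem
    cols = np.arange(labels.shape[1])[None, :]
    report = ComponentReport(detached=True)

    def box_of(mask: np.ndarray) -> ComponentBox | None:
        if not mask.any():
            return None
        rows = np.flatnonzero(mask.any(axis=1))
        cs = np.flatnonzero(mask.any(axis=0))
        return ComponentBox(mask=mask, bbox=(int(rows[0]), int(rows[-1]) + 1,
                                             int(cs[0]), int(cs[-1]) + 1))

    report.left_cerebrum = box_of(cer & (cols < x_mid_col))
    report.right_cerebrum = box_of(cer & (cols >= x_mid_col))
    report.brainstem = box_of(stem)
    return report


def simulate_section(
    volume: LabeledVolume,
    graph: StructureGraph,
    plane: PlaneParams,
    deform_spec: DeformSpec | None = None,
    artifact_level: int = 1,
    seed: int = 0,
    pixel_um: float | None = None,
    style: HistologyStyle | None = None,
    out_shape: tuple[int, int] | None = None,
) -> SimulatedSection:
    """Simulate one histological section with full ground truth.

    The label slice is extracted at ``plane`` (per-component planes when a
    brainstem offset is requested), deformed by a known smooth field, then
    rendered; artifacts are added per level.  ``truth_labels`` is exactly
    the plane slice warped by ``truth_field``; tears and cerebrum deletion
    affect the *image* (lost tissue), recorded in ``component_truth`` and
    the artifact list.
    """
    if artifact_level not in (1, 2, 3):
        raise ValueError(f"artifact level must be 1, 2 or 3, got {artifact_level}")
    default_deform, default_style = artifact_defaults(artifact_level)
    deform = deform_spec if deform_spec is not None else default_deform
    style = style if style is not None else default_style
    pixel_um = pixel_um if pixel_um is not None else volume.frame.voxel_size_um[0]
    rng = np.random.default_rng(seed)
    artifacts = [f"smooth_deformation(max={deform.max_displacement_px}px)"]

    multiplane = abs(deform.brainstem_offset_um) > 0
    if multiplane:
        stem_plane = replace(plane, d_um=plane.d_um + deform.brainstem_offset_um)
        bs_ids = sorted(graph.subtree_ids(3))
        base = slice_oblique(volume, plane, out_pixel_um=pixel_um, out_shape=out_shape)
        x_um, y_um = slice_grid_um(plane, base.pixel_size_um, base.labels.shape)
        z_um = plane_geometry(stem_plane)(x_um, y_um)
        stem_labels = sample_volume_nearest(volume, x_um, y_um, z_um)
        labels0 = np.where(np.isin(base.labels, bs_ids), 0, base.labels)
        labels0 = np.where(np.isin(stem_labels, bs_ids), stem_labels, labels0)
        truth_plane: PlaneParams | dict[str, PlaneParams] = {
            "cerebrum": plane, "brainstem": stem_plane,
        }
        artifacts.append(f"brainstem_d_offset({deform.brainstem_offset_um:g}um)")
    else:
        base = slice_oblique(volume, plane, out_pixel_um=pixel_um, out_shape=out_shape)
        labels0 = base.labels
        truth_plane = plane

    h, w = labels0.shape
    field_ = random_smooth_field((h, w), deform.max_displacement_px, deform.grid, rng)
    if deform.shrink_scale != 1.0:
        s = deform.shrink_scale
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        field_ = field_ + np.stack(
            [(rr - (h - 1) / 2.0) * (1.0 / s - 1.0), (cc - (w - 1) / 2.0) * (1.0 / s - 1.0)],
            axis=-1,
        )
        artifacts.append(f"shrinkage(scale={s:g})")
    labels1 = warp_labels_by_field(labels0, field_)
    truth_labels = LabeledSlice(labels=labels1, pixel_size_um=pixel_um,
                                plane=truth_plane, provenance="simulate_section")

    image_labels = labels1.copy()
    component_truth: ComponentReport | None = None
    if deform.delete_cerebrum in ("left", "right"):
        bs_ids = sorted(graph.subtree_ids(3))
        cols = np.arange(w)[None, :]
        side = cols < w / 2.0 if deform.delete_cerebrum == "left" else cols >= w / 2.0
        # everything on that side except the brainstem is lost with the cerebrum
        image_labels[(image_labels != 0) & ~np.isin(image_labels, bs_ids) & side] = 0
        artifacts.append(f"delete_cerebrum({deform.delete_cerebrum})")
    elif deform.delete_cerebrum not in (None, "none"):
        raise ValueError(f"delete_cerebrum must be None, 'left' or 'right', "
                         f"got {deform.delete_cerebrum!r}")
    if multiplane or deform.delete_cerebrum:
        component_truth = _component_truth(image_labels, graph, w / 2.0)

    image = render_histology(
        LabeledSlice(labels=image_labels, pixel_size_um=pixel_um, plane=truth_plane),
        style=style, seed=seed + 1, graph=graph,
    )
    if deform.n_tears > 0:
        fg = image_labels != 0
        n_fg = int(fg.sum())
        if n_fg:
            budget = deform.tear_frac * n_fg
            radius = max(2, int(math.sqrt(budget / max(deform.n_tears, 1) / math.pi)))
            rs, cs = np.nonzero(fg)
            for _ in range(deform.n_tears):
                k = rng.integers(len(rs))
                rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
                blob = (rr - rs[k]) ** 2 + (cc - cs[k]) ** 2 <= radius ** 2
                image[blob] = 0.0
            artifacts.append(f"tears(n={deform.n_tears}, r={radius}px)")

    return SimulatedSection(
        image=image, truth_plane=truth_plane, truth_labels=truth_labels,
        truth_field=field_, artifact_level=artifact_level,
        component_truth=component_truth, seed=seed, pixel_size_um=pixel_um,
        artifacts=artifacts,
    )


def oracle_landmarks(
    section: SimulatedSection,
    m_ard,
    n: int = 10,
    seed: int = 0,
    margin_px: int = 8,
):
    """Ground-truth interior landmark pairs for refinement benchmarks.

    Samples ``n`` well-separated foreground points on the section; for each,
    the true atlas location is pushed through the inverse of the automatic
    field so the source landmark lives where the warped atlas actually shows
    that structure.  Returns (source LandmarkSet, destination LandmarkSet)
    ready for the hybrid refinement.
    """
    from sliceloc.registration import LandmarkSet

    rng = np.random.default_rng(seed)
    fg = ndimage.binary_erosion(section.truth_labels.labels != 0,
                                iterations=margin_px)
    rows, cols = np.nonzero(fg)
    if rows.size < n:
        raise ValueError("not enough interior foreground for oracle landmarks")
    # greedy farthest-point-ish sampling for spread
    order = rng.permutation(rows.size)
    chosen: list[int] = []
    min_sep = max(8.0, math.sqrt(fg.sum() / (4.0 * n)))
    for idx in order:
        p = np.array([rows[idx], cols[idx]], float)
        if all(np.hypot(*(p - np.array([rows[j], cols[j]], float))) >= min_sep
               for j in chosen):
            chosen.append(idx)
        if len(chosen) == n:
            break
    if len(chosen) < n:
        chosen = list(order[:n])
    dst = np.array([[rows[j], cols[j]] for j in chosen], float)
    # true atlas coordinate of each section point
    atlas = dst + np.array([section.truth_field[int(r), int(c)] for r, c in dst])
    # invert the automatic field pointwise: find q with q + u_ard(q) = atlas
    q = atlas.copy()
    for _ in range(10):
        dr = ndimage.map_coordinates(m_ard.field[..., 0], q.T, order=1, mode="nearest")
        dc = ndimage.map_coordinates(m_ard.field[..., 1], q.T, order=1, mode="nearest")
        q = atlas - np.column_stack([dr, dc])
    h, w = section.truth_labels.labels.shape
    q[:, 0] = np.clip(q[:, 0], 0, h - 1)
    q[:, 1] = np.clip(q[:, 1], 0, w - 1)
    return (LandmarkSet(points=q, origin=["manual"] * n),
            LandmarkSet(points=dst, origin=["manual"] * n))


# ---------------------------------------------------------------------------
# Simulated raters
# ---------------------------------------------------------------------------


@dataclass
class RaterLabels:
    """Independent expert labels for one section, in plate units."""

    ratings: list[float]

    def __post_init__(self) -> None:
        if any(not (1.0 <= r <= ARA_MAX) for r in self.ratings):
            raise ValueError(f"ratings must lie in [1, {ARA_MAX:g}], got {self.ratings}")


def simulate_raters(
    true_ap: float, sd: float, n_raters: int = 4, seed: int = 0
) -> RaterLabels:
    """Simulate expert plate labels: truth + iid Gaussian noise, clipped.

    ``true_ap`` and ``sd`` are in plate units (1 plate = 100 um).
    """
    if n_raters < 2:
        raise ValueError(f"need at least 2 raters, got {n_raters}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    rng = np.random.default_rng(seed)
    vals = np.clip(true_ap + rng.normal(0.0, sd, size=n_raters), 1.0, ARA_MAX)
    return RaterLabels(ratings=[float(v) for v in vals])
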