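"""Localization of a 2D section in the 3D atlas: recovering (alpha, beta, d).

The pipeline routes a section by its approximate anteroposterior position
(the single label, SL) into one of three branches:

* group A (olfactory bulb): too few structures for atlas matching -- the
  section is segmented directly into bulb layers;
* groups B / B': the section is split into four quadrants, each quadrant
  receives its own continuous plate label (Q label), and the slicing plane
  (alpha, beta, d) is solved from the Q labels by least squares;
* group C (posterior): sections detach into left/right cerebrum and
  brainstem, so components are detected first, each present cerebrum is
  split dorsally/ventrally, and per-component planes are fitted (the
  brainstem is sliced at its own AP position).

Learned per-quadrant predictors are admitted through the
:class:`SectionPredictor` interface; the package ships an oracle (reads the
simulator's ground-truth plane) and a deterministic brute-force search that
maximizes normalized mutual information between the section and simplified
atlas renderings over a coarse-to-fine grid of candidate planes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, transform

from sliceloc.atlas import (
    LabeledSlice,
    LabeledVolume,
    StructureGraph,
    slice_oblique,
)
from sliceloc.frames import (
    ARA_MAX,
    ARA_MIN,
    GroupLabel,
    PlaneParams,
    ap_to_ara_section,
    ara_section_to_ap,
    group_of_section,
    plane_geometry,
)


class LocalizationError(RuntimeError):
    """Raised by localization stages; the message names the failing stage."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class QLabels:
    """Per-quadrant continuous plate labels [Q_1..Q_5].

    Q5 is the brainstem quintant; for groups B/B' it is stored as 0 and
    flagged invalid.  Invalid entries mark missing components.
    """

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(5)
        self.valid = np.asarray(self.valid, dtype=bool).reshape(5)
        v = self.values[self.valid]
        if v.size and (np.any(v < ARA_MIN) or np.any(v > ARA_MAX)):
            raise ValueError(f"valid Q labels must lie in [{ARA_MIN:g}, {ARA_MAX:g}], got {v}")


@dataclass
class QuadrantCrop:
    """A quadrant/quintant crop with its physical center in the atlas frame."""

    image: np.ndarray
    center_um: tuple[float, float]
    index: int  # 1..5; Q5 = brainstem

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 5:
            raise ValueError(f"quadrant index must be in 1..5, got {self.index}")


@dataclass
class ComponentBox:
    """A detected tissue component: mask plus bounding box (r0, r1, c0, c1)."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]


@dataclass
class ComponentReport:
    """Presence and geometry of {left_cerebrum, right_cerebrum, brainstem}.

    ``detached`` is False when the section is a single blob spanning the
    midline (no detachment happened, typical of mis-routed group-B images).
    """

    left_cerebrum: ComponentBox | None = None
    right_cerebrum: ComponentBox | None = None
    brainstem: ComponentBox | None = None
    detached: bool = True

    def present(self) -> list[str]:
        return [k for k in ("left_cerebrum", "right_cerebrum", "brainstem")
                if getattr(self, k) is not None]

    def missing(self) -> list[str]:
        return [k for k in ("left_cerebrum", "right_cerebrum", "brainstem")
                if getattr(self, k) is None]


class SectionPredictor(Protocol):
    """Maps a section image or quadrant crop to a continuous plate number."""

    kind: str

    def predict(self, crop: "QuadrantCrop | np.ndarray") -> float: ...


@dataclass
class LocalizationResult:
    group: GroupLabel
    single_label: float
    qlabels: QLabels | None = None
    plane: PlaneParams | dict[str, PlaneParams] | None = None
    group_a_mask: np.ndarray | None = None
    component_report: ComponentReport | None = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Image preprocessing helpers
# ---------------------------------------------------------------------------


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Grayscale float image scaled to [0, 1] (RGB collapsed by mean)."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img)
    return img


def resize_max_side(image: np.ndarray, max_side: int) -> tuple[np.ndarray, float]:
    """Downscale so the longest side is ``max_side``; returns (image, scale).

    ``scale`` multiplies pixel size (scale >= 1; 1 when no resize happened).
    """
    h, w = image.shape[:2]
    longest = max(h, w)
    if longest <= max_side:
        return image, 1.0
    factor = longest / max_side
    out = transform.resize(
        image, (int(round(h / factor)), int(round(w / factor))),
        order=1, anti_aliasing=True, preserve_range=True,
    )
    return out, factor


def foreground_bbox(image: np.ndarray, threshold: float = 0.0) -> tuple[int, int, int, int]:
    """Bounding box (r0, r1, c0, c1), half-open, of pixels above threshold."""
    fg = normalize_image(image) > threshold
    if not fg.any():
        raise LocalizationError("foreground detection: section image is all background")
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def pixel_center_um(
    r: float, c: float, shape: tuple[int, int], pixel_um: float,
    center_xy_um: tuple[float, float],
) -> tuple[float, float]:
    """Physical (x, y) of pixel (r, c) on a canvas centered at center_xy_um."""
    h, w = shape
    x = center_xy_um[0] + (c - (w - 1) / 2.0) * pixel_um
    y = center_xy_um[1] + (r - (h - 1) / 2.0) * pixel_um
    return float(x), float(y)


# ---------------------------------------------------------------------------
# Quadrant / quintant splitting
# ---------------------------------------------------------------------------


def split_quadrants(
    image: np.ndarray,
    group: GroupLabel,
    components: ComponentReport | None = None,
    pixel_size_um: float = 1.0,
    center_xy_um: tuple[float, float] = (0.0, 0.0),
    foreground_threshold: float = 0.0,
) -> list[QuadrantCrop]:
    """Split a section into 4 quadrants (B/B') or 5 quintants (C).

    Numbering: Q1 dorsal-left, Q2 dorsal-right, Q3 ventral-left, Q4
    ventral-right, Q5 brainstem.  Groups B/B' split the foreground bounding
    box at its center; group C splits each *present* cerebrum into
    dorsal/ventral halves and adds the brainstem box.  Each crop carries
    the physical (x, y) of its geometric center.
    """
    if group == GroupLabel.A:
        raise LocalizationError("quadrant split: group A sections are segmented, not split")
    img = normalize_image(image)
    shape = img.shape

    def crop_of(box: tuple[int, int, int, int], index: int) -> QuadrantCrop:
        r0, r1, c0, c1 = box
        center = pixel_center_um((r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0,
                                 shape, pixel_size_um, center_xy_um)
        return QuadrantCrop(image=img[r0:r1, c0:c1], center_um=center, index=index)

    def quarter_boxes(r0, r1, c0, c1):
        rm, cm = (r0 + r1) // 2, (c0 + c1) // 2
        return {1: (r0, rm, c0, cm), 2: (r0, rm, cm, c1),
                3: (rm, r1, c0, cm), 4: (rm, r1, cm, c1)}

    if group in (GroupLabel.B, GroupLabel.BPRIME):
        box = foreground_bbox(img, foreground_threshold)
        return [crop_of(b, i) for i, b in sorted(quarter_boxes(*box).items())]

    # group C
    if components is None:
        raise LocalizationError("quadrant split: group C requires a component report")
    if components.brainstem is None:
        raise LocalizationError(
            "quadrant split: invalid posterior section -- the brain stem must be present"
        )
    crops: list[QuadrantCrop] = []
    for side, (qd, qv) in (("left_cerebrum", (1, 3)), ("right_cerebrum", (2, 4))):
        comp = getattr(components, side)
        if comp is None:
            continue
        r0, r1, c0, c1 = comp.bbox
        rm = (r0 + r1) // 2
        crops.append(crop_of((r0, rm, c0, c1), qd))
        crops.append(crop_of((rm, r1, c0, c1), qv))
    crops.append(crop_of(components.brainstem.bbox, 5))
    return sorted(crops, key=lambda c: c.index)


# ---------------------------------------------------------------------------
# Q-label prediction
# ---------------------------------------------------------------------------


def predict_qlabels(
    crops: Sequence[QuadrantCrop],
    predictor: SectionPredictor,
    group: GroupLabel = GroupLabel.B,
) -> QLabels:
    """Run the per-quadrant predictor; missing quadrants are flagged invalid."""
    values = np.zeros(5)
    valid = np.zeros(5, dtype=bool)
    for crop in crops:
        if group in (GroupLabel.B, GroupLabel.BPRIME) and crop.index == 5:
            continue
        out = float(predictor.predict(crop))
        if not (ARA_MIN <= out <= ARA_MAX):
            raise LocalizationError(
                f"Q-label prediction: predictor returned {out:g} outside "
                f"[{ARA_MIN:g}, {ARA_MAX:g}] for quadrant {crop.index}"
            )
        values[crop.index - 1] = out
        valid[crop.index - 1] = True
    if group in (GroupLabel.B, GroupLabel.BPRIME):
        values[4] = 0.0
        valid[4] = False
    if not valid.any():
        raise LocalizationError("Q-label prediction: no valid quadrants")
    return QLabels(values=values, valid=valid)


class PlaneOraclePredictor:
    """Ground-truth predictor: evaluates a known plane at the crop center.

    ``planes`` may be a single plane or a mapping with per-component planes
    ('cerebrum' for Q1-Q4, 'brainstem' for Q5).  For a full section image
    it returns the plate number of the plane's anchor AP position.
    """

    kind = "oracle"

    def __init__(self, planes: PlaneParams | Mapping[str, PlaneParams]):
        self.planes = planes

    def _plane_for(self, index: int) -> PlaneParams:
        if isinstance(self.planes, PlaneParams):
            return self.planes
        key = "brainstem" if index == 5 else "cerebrum"
        if key in self.planes:
            return self.planes[key]
        if index in (1, 3) and "left_cerebrum" in self.planes:
            return self.planes["left_cerebrum"]
        if index in (2, 4) and "right_cerebrum" in self.planes:
            return self.planes["right_cerebrum"]
        raise KeyError(f"no plane registered for quadrant {index}")

    def predict(self, crop: QuadrantCrop | np.ndarray) -> float:
        if isinstance(crop, QuadrantCrop):
            plane = self._plane_for(crop.index)
            z = float(plane_geometry(plane)(crop.center_um[0], crop.center_um[1]))
        else:
            plane = self._plane_for(1)
            z = plane.d_um
        return float(ap_to_ara_section(float(np.clip(z, 0.0, (ARA_MAX - 1) * 100.0))))


class ConstantPredictor:
    """Fixed-output predictor (useful as a stub and in contract tests)."""

    kind = "constant"

    def __init__(self, value: float):
        self.value = float(value)

    def predict(self, crop) -> float:
        return self.value


# ---------------------------------------------------------------------------
# Plane solving from Q labels
# ---------------------------------------------------------------------------


def solve_plane_from_qlabels(
    qlabels: QLabels,
    crops: Sequence[QuadrantCrop],
    center_xy_um: tuple[float, float] = (0.0, 0.0),
    force_alpha_zero: bool = False,
    use_quadrants: Sequence[int] | None = None,
) -> tuple[PlaneParams, float]:
    """Least-squares plane fit z_i = d + a (x_i - x_c) + b (y_i - y_c).

    Each valid Q label is converted to micrometers and regressed on the
    quadrant-center coordinates; alpha = atan(a), beta = atan(b).  With two
    valid quadrants only (one cerebrum) alpha is fixed to 0 and (beta, d)
    are fitted; a single quadrant fixes d only.  Returns (plane, RMS
    residual in micrometers).
    """
    centers = {c.index: c.center_um for c in crops}
    sel = []
    for i in range(1, 6):
        if not qlabels.valid[i - 1]:
            continue
        if use_quadrants is not None and i not in use_quadrants:
            continue
        if i not in centers:
            raise LocalizationError(f"plane solve: no crop provided for valid quadrant {i}")
        sel.append(i)
    if not sel:
        raise LocalizationError("plane solve: no valid quadrants to fit a plane")

    z = np.array([ara_section_to_ap(qlabels.values[i - 1]) for i in sel])
    x = np.array([centers[i][0] for i in sel]) - center_xy_um[0]
    y = np.array([centers[i][1] for i in sel]) - center_xy_um[1]

    n = len(sel)
    fit_alpha = (not force_alpha_zero) and n >= 3
    fit_beta = n >= 2
    cols = [np.ones(n)]
    if fit_alpha:
        cols.append(x)
    if fit_beta:
        cols.append(y)
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    d = float(coef[0])
    a = float(coef[1]) if fit_alpha else 0.0
    b = float(coef[1 + int(fit_alpha)]) if fit_beta else 0.0
    residual = float(np.sqrt(np.mean((A @ coef - z) ** 2)))
    plane = PlaneParams(
        alpha_deg=math.degrees(math.atan(a)),
        beta_deg=math.degrees(math.atan(b)),
        d_um=d,
        center_xy_um=center_xy_um,
    )
    return plane, residual


# ---------------------------------------------------------------------------
# Group-C component detection
# ---------------------------------------------------------------------------


def detect_group_c_components(
    image: np.ndarray,
    threshold: float | None = None,
    min_area_frac: float = 0.01,
    midline_tol: float = 0.25,
) -> ComponentReport:
    """Detect {left cerebrum, right cerebrum, brainstem} in a posterior section.

    Foreground = threshold (default: any positive intensity) followed by
    morphological cleanup; connected components above the area floor are
    classified by centroid geometry: the brainstem is the most ventral
    component near the midline, cerebra sort left/right of it.  A single
    component spanning the midline means no detachment occurred.
    """
    img = normalize_image(image)
    fg = img > (0.0 if threshold is None else threshold)
    if not fg.any():
        raise LocalizationError("component detection: empty section")
    fg = ndimage.binary_closing(fg, iterations=1)
    lab, n = ndimage.label(fg)
    if n == 0:
        raise LocalizationError("component detection: empty section")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    floor = min_area_frac * sizes.sum()
    keep = [i + 1 for i, s in enumerate(sizes) if s >= floor]
    if not keep:
        raise LocalizationError("component detection: no component above the area floor")

    comps: list[tuple[ComponentBox, tuple[float, float]]] = []
    for i in keep:
        mask = lab == i
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        bbox = (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
        centroid = ndimage.center_of_mass(mask)
        comps.append((ComponentBox(mask=mask, bbox=bbox), centroid))

    c0 = min(c.bbox[2] for c, _ in comps)
    c1 = max(c.bbox[3] for c, _ in comps)
    midline = (c0 + c1) / 2.0
    width = c1 - c0

    if len(comps) == 1:
        box, _ = comps[0]
        spans = box.bbox[2] < midline < box.bbox[3]
        if spans:
            # single blob across the midline: no detachment; report the two
            # halves as cerebra so downstream quadrant logic stays usable
            mid = int(round(midline))
            left = ComponentBox(mask=box.mask & (np.arange(box.mask.shape[1]) < mid)[None, :],
                                bbox=(box.bbox[0], box.bbox[1], box.bbox[2], mid))
            right = ComponentBox(mask=box.mask & (np.arange(box.mask.shape[1]) >= mid)[None, :],
                                 bbox=(box.bbox[0], box.bbox[1], mid, box.bbox[3]))
            return ComponentReport(left_cerebrum=left, right_cerebrum=right,
                                   brainstem=None, detached=False)

    report = ComponentReport(detached=True)
    # brainstem: most ventral centroid among components near the midline
    stem_candidates = [
        (cen[0], box, cen) for box, cen in comps
        if abs(cen[1] - midline) <= midline_tol * width
    ]
    remaining = list(comps)
    if stem_candidates and len(comps) > 1:
        _, stem_box, stem_cen = max(stem_candidates, key=lambda t: t[0])
        report.brainstem = stem_box
        remaining = [(b, c) for b, c in comps if b is not stem_box]
    for box, cen in remaining:
        side = "left_cerebrum" if cen[1] < midline else "right_cerebrum"
        prev = getattr(report, side)
        if prev is None or box.mask.sum() > prev.mask.sum():
            setattr(report, side, box)
    return report


# ---------------------------------------------------------------------------
# Brute-force plane search (deterministic stand-in for learned predictors)
# ---------------------------------------------------------------------------


@dataclass
class SearchGrid:
    """Coarse-to-fine grid over (alpha, beta, d) for the brute-force search."""

    alpha_max_deg: float = 10.0
    beta_max_deg: float = 10.0
    coarse_angle_step_deg: float = 2.5
    fine_angle_step_deg: float = 1.0
    fine_angle_window_deg: float = 3.0
    coarse_d_step_um: float = 500.0
    fine_d_step_um: float = 100.0
    d_range_um: tuple[float, float] | None = None
    render_px: int = 160
    refine_px: tuple[int, ...] = (160,)
    bins: int = 24
    n_coarse_candidates: int = 8


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def normalized_mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Studholme NMI = (H(A) + H(B)) / H(A, B), in [1, 2]."""
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins, range=[[0, 1], [0, 1]])
    joint /= joint.sum()
    hj = _entropy(joint.ravel())
    ha = _entropy(joint.sum(axis=1))
    hb = _entropy(joint.sum(axis=0))
    if hj == 0:
        return 2.0
    return (ha + hb) / hj


def _native_scalar(volume: LabeledVolume, graph: StructureGraph,
                   plane: PlaneParams,
                   fiber_ids: frozenset[int] | None = None) -> np.ndarray:
    """Simplified rendering on the volume's native full-extent canvas:
    background 0, generic foreground 1.0, fiber tracts 0.5."""
    slc = slice_oblique(volume, plane)
    if fiber_ids is None:
        fiber_ids = frozenset(
            i for i in slc.id_set() if i != 0 and graph.is_fiber_tract(i)
        )
    out = np.zeros(slc.labels.shape, dtype=float)
    out[slc.labels != 0] = 1.0
    if fiber_ids:
        out[np.isin(slc.labels, sorted(fiber_ids))] = 0.5
    return out


def render_scalar_atlas(
    volume: LabeledVolume,
    graph: StructureGraph,
    plane: PlaneParams,
    out_px: int,
    fiber_ids: frozenset[int] | None = None,
) -> np.ndarray:
    """Simplified atlas rendering as a scalar image, resized to out_px square.

    The slice is extracted on the volume's native full-extent canvas and
    then resized exactly like the section image, so the two are
    geometrically comparable.
    """
    out = _native_scalar(volume, graph, plane, fiber_ids)
    out = transform.resize(out, (out_px, out_px), order=1, anti_aliasing=True,
                           preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def brute_force_localize(
    image: np.ndarray,
    volume: LabeledVolume,
    graph: StructureGraph,
    grid: SearchGrid | None = None,
) -> tuple[PlaneParams, float]:
    """Exhaustive coarse-to-fine plane search maximizing NMI.

    The section is masked and resized to ``render_px`` squared; every grid
    candidate renders the simplified atlas at that plane and scores it by
    normalized mutual information.  Ties break deterministically toward the
    smallest d, then alpha, then beta.  Returns (best plane, best score).
    """
    grid = grid or SearchGrid()
    raw = normalize_image(image)
    if not (raw > 0).any():
        raise LocalizationError("brute-force localization: all-background image")
    img_at = {
        px: np.clip(transform.resize(raw, (px, px), order=1, anti_aliasing=True,
                                     preserve_range=True), 0.0, 1.0)
        for px in grid.refine_px
    }

    fiber_ids = frozenset(
        int(i) for i in np.unique(volume.labels) if i != 0 and graph.is_fiber_tract(int(i))
    )
    anchor = volume.frame.center_um()[:2]
    zlo, zhi = volume.frame.ap_range_um()
    dlo, dhi = grid.d_range_um if grid.d_range_um else (zlo, zhi)

    def score_at(alpha: float, beta: float, d: float) -> float:
        """NMI averaged over the render scales.  The candidate plane is
        sliced once on the native canvas and resized per scale; averaging
        decorrelates the resize and voxel-quantization noise that limits
        single-scale angle precision."""
        plane = PlaneParams(alpha, beta, d, anchor)
        native = _native_scalar(volume, graph, plane, fiber_ids)
        scores = []
        for px in grid.refine_px:
            rendered = np.clip(
                transform.resize(native, (px, px), order=1, anti_aliasing=True,
                                 preserve_range=True), 0.0, 1.0)
            scores.append(normalized_mutual_information(img_at[px], rendered,
                                                        bins=grid.bins))
        return float(np.mean(scores))

    score_multi = score_at

    def sweep(d_vals, a_vals, b_vals):
        """Score the whole grid; returns entries sorted best-first with the
        deterministic tie-break (higher score, then smaller d, alpha, beta)."""
        entries = []
        for d in d_vals:
            for a in a_vals:
                for b in b_vals:
                    entries.append((-score_at(a, b, d), d, a, b))
        entries.sort()
        return entries

    a_coarse = np.arange(-grid.alpha_max_deg, grid.alpha_max_deg + 1e-9,
                         grid.coarse_angle_step_deg)
    b_coarse = np.arange(-grid.beta_max_deg, grid.beta_max_deg + 1e-9,
                         grid.coarse_angle_step_deg)
    d_coarse = np.arange(dlo, dhi + 1e-9, grid.coarse_d_step_um)
    coarse = sweep(d_coarse, a_coarse, b_coarse)

    # refine around a shortlist of coarse candidates.  The NMI landscape has
    # near-tied basins both along AP and in the angles, so the shortlist is
    # the union of (a) the top entries that differ from each other in d or
    # in an angle by more than a coarse step, and (b) the best angle pair at
    # each of the strongest coarse d values.
    def distinct(c1, c2):
        return (abs(c1[1] - c2[1]) > grid.coarse_d_step_um
                or abs(c1[2] - c2[2]) > grid.coarse_angle_step_deg
                or abs(c1[3] - c2[3]) > grid.coarse_angle_step_deg)

    candidates: list[tuple] = []
    for entry in coarse:
        if all(distinct(entry, c) for c in candidates):
            candidates.append(entry)
        if len(candidates) >= grid.n_coarse_candidates:
            break
    best_per_d: dict[float, tuple] = {}
    for entry in coarse:
        if entry[1] not in best_per_d:
            best_per_d[entry[1]] = entry
    for entry in sorted(best_per_d.values())[: grid.n_coarse_candidates]:
        if all(distinct(entry, c) for c in candidates):
            candidates.append(entry)

    best = coarse[0]
    for _, d0, a0, b0 in candidates:
        d_fine = np.arange(max(dlo, d0 - grid.coarse_d_step_um),
                           min(dhi, d0 + grid.coarse_d_step_um) + 1e-9,
                           grid.fine_d_step_um)
        a_fine = np.arange(max(-grid.alpha_max_deg, a0 - grid.fine_angle_window_deg),
                           min(grid.alpha_max_deg, a0 + grid.fine_angle_window_deg) + 1e-9,
                           grid.fine_angle_step_deg)
        b_fine = np.arange(max(-grid.beta_max_deg, b0 - grid.fine_angle_window_deg),
                           min(grid.beta_max_deg, b0 + grid.fine_angle_window_deg) + 1e-9,
                           grid.fine_angle_step_deg)
        top = sweep(d_fine, a_fine, b_fine)[0]
        if top < best:
            best = top
    neg_s, d1, a1, b1 = best

    # sub-grid refinement: two rounds of per-axis parabolic peak fitting,
    # with the score marginalized over the neighboring grid values of the
    # nuisance coordinates (averaging suppresses the staining/deformation
    # noise that otherwise flips the argmax to an adjacent grid point)
    def clip_abd(a, b, d):
        return (float(np.clip(a, -grid.alpha_max_deg, grid.alpha_max_deg)),
                float(np.clip(b, -grid.beta_max_deg, grid.beta_max_deg)),
                float(np.clip(d, dlo, dhi)))

    def axis_refine(center, step, profile):
        xs = np.array([center - step, center, center + step])
        ys = np.array([profile(x) for x in xs])
        denom = ys[0] - 2 * ys[1] + ys[2]
        if denom >= -1e-12:
            return float(xs[int(np.argmax(ys))])
        delta = 0.5 * (ys[0] - ys[2]) / denom
        return center + float(np.clip(delta, -1.0, 1.0)) * step

    da, dd = grid.fine_angle_step_deg, grid.fine_d_step_um
    for _ in range(2):
        b1 = axis_refine(b1, da, lambda x: np.mean(
            [score_multi(*clip_abd(a1, x, d1 + k * dd)) for k in (-1, 0, 1)]))
        a1 = axis_refine(a1, da, lambda x: np.mean(
            [score_multi(*clip_abd(x, b1, d1 + k * dd)) for k in (-1, 0, 1)]))
        d1 = axis_refine(d1, dd, lambda x: np.mean(
            [score_multi(*clip_abd(a1 + k * da, b1, x)) for k in (-1, 0, 1)]))
    a1, b1, d1 = clip_abd(a1, b1, d1)
    return PlaneParams(a1, b1, d1, anchor), float(-neg_s)


class BruteForcePredictor:
    """SectionPredictor backed by the exhaustive NMI plane search.

    For a full section image the search runs once and the predicted plate
    number is read at the plane anchor; quadrant crops are answered by
    evaluating the cached plane at the crop center.
    """

    kind = "brute_force"

    def __init__(self, volume: LabeledVolume, graph: StructureGraph,
                 grid: SearchGrid | None = None):
        self.volume = volume
        self.graph = graph
        self.grid = grid
        self._plane: PlaneParams | None = None
        self._score: float | None = None

    def localize_plane(self, image: np.ndarray) -> tuple[PlaneParams, float]:
        self._plane, self._score = brute_force_localize(image, self.volume, self.graph, self.grid)
        return self._plane, self._score

    def predict(self, crop: QuadrantCrop | np.ndarray) -> float:
        if isinstance(crop, QuadrantCrop):
            if self._plane is None:
                raise LocalizationError(
                    "brute-force predictor: call localize_plane (or predict on the "
                    "full image) before predicting quadrants"
                )
            z = float(plane_geometry(self._plane)(crop.center_um[0], crop.center_um[1]))
        else:
            plane, _ = self.localize_plane(np.asarray(crop))
            z = plane.d_um
        z = float(np.clip(z, 0.0, (ARA_MAX - 1) * 100.0))
        return float(ap_to_ara_section(z))


# ---------------------------------------------------------------------------
# Group-A segmentation
# ---------------------------------------------------------------------------

#: Class codes emitted by group-A segmenters.
GROUP_A_CLASSES = {
    "background": 0,
    "MOBgl": 1,
    "MOBopl": 2,
    "MOBgr": 3,
    "AOB": 4,
    "fiber_tracts": 5,
}


def classify_group_a_id(structure_id: int, graph: StructureGraph) -> int:
    """Map a structure ID to a group-A class code via its ancestry."""
    if structure_id == 0:
        return 0
    if graph.is_fiber_tract(structure_id):
        return GROUP_A_CLASSES["fiber_tracts"]
    for node in graph.ancestors(structure_id):
        for name in ("MOBgl", "MOBopl", "MOBgr", "AOB"):
            if node.acronym == name:
                return GROUP_A_CLASSES[name]
    return 0


class OracleGroupASegmenter:
    """Reads the simulator's ground-truth label slice."""

    kind = "oracle"

    def __init__(self, truth_labels: LabeledSlice, graph: StructureGraph):
        self.truth = truth_labels
        self.graph = graph

    def segment(self, image: np.ndarray) -> np.ndarray:
        out = np.zeros(self.truth.labels.shape, dtype=np.int32)
        for i in np.unique(self.truth.labels):
            i = int(i)
            if i == 0:
                continue
            out[self.truth.labels == i] = classify_group_a_id(i, self.graph)
        return out


class NearestAtlasSegmenter:
    """Baseline segmenter: transfer classes from an (undeformed) atlas slice.

    Foreground pixels of the section take the class of the template pixel at
    the same location, or of the nearest labeled template pixel when the
    template is background there.
    """

    kind = "brute_force"

    def __init__(self, volume: LabeledVolume, graph: StructureGraph, plane: PlaneParams,
                 pixel_um: float | None = None):
        self.volume = volume
        self.graph = graph
        self.plane = plane
        self.pixel_um = pixel_um

    def segment(self, image: np.ndarray) -> np.ndarray:
        img = normalize_image(image)
        slc = slice_oblique(self.volume, self.plane, out_pixel_um=self.pixel_um,
                            out_shape=img.shape)
        template = np.zeros(img.shape, dtype=np.int32)
        for i in np.unique(slc.labels):
            i = int(i)
            if i:
                template[slc.labels == i] = classify_group_a_id(i, self.graph)
        fg = img > 0
        out = np.zeros_like(template)
        if template.any():
            _, (ri, ci) = ndimage.distance_transform_edt(template == 0, return_indices=True)
            out[fg] = template[ri[fg], ci[fg]]
        return out


def segment_group_a(image: np.ndarray, segmenter) -> np.ndarray:
    """Run a 5-class group-A segmenter and validate its contract."""
    raster = np.asarray(segmenter.segment(image))
    img = normalize_image(image)
    if raster.shape != img.shape:
        raise LocalizationError(
            f"group-A segmentation: raster shape {raster.shape} != image shape {img.shape}"
        )
    known = set(GROUP_A_CLASSES.values())
    emitted = set(np.unique(raster).tolist())
    if not emitted <= known:
        raise LocalizationError(
            f"group-A segmentation: predictor emitted unknown classes {sorted(emitted - known)}"
        )
    return raster


# ---------------------------------------------------------------------------
# End-to-end localization
# ---------------------------------------------------------------------------


def localize(
    image: np.ndarray,
    volume: LabeledVolume,
    graph: StructureGraph,
    sl_predictor: SectionPredictor | None = None,
    ql_predictor: SectionPredictor | None = None,
    segmenter=None,
    pixel_size_um: float | None = None,
    grid: SearchGrid | None = None,
) -> LocalizationResult:
    """Full localization pipeline with group routing.

    SL prediction decides the group; group A is segmented, groups B/B' are
    quadrant-split into a single plane fit, group C gets per-component
    planes (alpha fixed to 0; the brainstem is fitted d-only with beta
    inherited from the cerebrum average).  Defaults to brute-force
    predictors when none are supplied.
    """
    if pixel_size_um is None:
        pixel_size_um = volume.frame.voxel_size_um[0]
    anchor = volume.frame.center_um()[:2]
    img = normalize_image(image)

    default_bf: BruteForcePredictor | None = None
    if sl_predictor is None or ql_predictor is None:
        default_bf = BruteForcePredictor(volume, graph, grid)
    sl_predictor = sl_predictor or default_bf
    ql_predictor = ql_predictor or default_bf

    try:
        sl_value = float(sl_predictor.predict(img))
    except LocalizationError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-named propagation
        raise LocalizationError(f"single-label prediction: {exc}") from exc
    if not (ARA_MIN <= sl_value <= ARA_MAX):
        raise LocalizationError(
            f"single-label prediction: value {sl_value:g} outside [{ARA_MIN:g}, {ARA_MAX:g}]"
        )
    group = group_of_section(sl_value)
    result = LocalizationResult(group=group, single_label=sl_value)
    result.diagnostics["sl_value"] = sl_value

    if group == GroupLabel.A:
        if segmenter is None:
            plane = PlaneParams(0.0, 0.0, ara_section_to_ap(sl_value), anchor)
            segmenter = NearestAtlasSegmenter(volume, graph, plane, pixel_size_um)
        result.group_a_mask = segment_group_a(img, segmenter)
        return result

    if group in (GroupLabel.B, GroupLabel.BPRIME):
        crops = split_quadrants(img, group, pixel_size_um=pixel_size_um,
                                center_xy_um=anchor)
        qlabels = predict_qlabels(crops, ql_predictor, group)
        plane, residual = solve_plane_from_qlabels(qlabels, crops, center_xy_um=anchor)
        result.qlabels = qlabels
        result.plane = plane
        result.diagnostics["residual_um"] = residual
        result.diagnostics["ql_group"] = group_of_section(
            float(np.clip(qlabels.values[qlabels.valid].mean(), ARA_MIN, ARA_MAX))
        ).value
        return result

    # group C: component detection, quintant split, per-component planes
    report = detect_group_c_components(img)
    crops = split_quadrants(img, group, components=report,
                            pixel_size_um=pixel_size_um, center_xy_um=anchor)
    qlabels = predict_qlabels(crops, ql_predictor, group)
    result.qlabels = qlabels
    result.component_report = report

    planes: dict[str, PlaneParams] = {}
    residuals: dict[str, float] = {}
    betas: list[float] = []
    for side, quads in (("left_cerebrum", (1, 3)), ("right_cerebrum", (2, 4))):
        if getattr(report, side) is None:
            continue
        plane, res = solve_plane_from_qlabels(
            qlabels, crops, center_xy_um=anchor, force_alpha_zero=True,
            use_quadrants=quads,
        )
        planes[side] = plane
        residuals[side] = res
        betas.append(plane.beta_deg)
    stem_plane, stem_res = solve_plane_from_qlabels(
        qlabels, crops, center_xy_um=anchor, force_alpha_zero=True, use_quadrants=(5,),
    )
    beta_stem = float(np.mean(betas)) if betas else 0.0
    planes["brainstem"] = PlaneParams(0.0, beta_stem, stem_plane.d_um, anchor)
    residuals["brainstem"] = stem_res
    result.plane = planes
    result.diagnostics["residuals_um"] = residuals
    return result
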