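"""Hybrid 2D registration: automatic deformable stage + landmark refinement.

The automatic stage aligns the simplified atlas rendering to the section in
two steps: a centered similarity transform (translation, rotation,
isotropic scale) maximizing mutual information, followed by an iterative
dense deformable refinement with Gaussian-regularized updates on
intensity-remapped images (the remap makes the multimodal pair comparable
by a monomodal force).  The result is a dense pull-back displacement field
M_Ard.

The optional refinement takes paired landmarks (manual pairs plus 20
automatic outer-contour points per side), triangulates the section-side
points with Delaunay, and warps each triangle by the exact affine defined
by its three vertex pairs: M_LM.  Transforms compose as M_LM o M_Ard and
label rasters are always transferred with nearest-neighbor sampling so no
new structure IDs can appear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial import Delaunay, QhullError
from skimage import filters, measure, transform as sktransform

from sliceloc.atlas import LabeledSlice, StructureGraph, simplify_atlas_slice
from sliceloc.localization import normalize_image


class RegistrationError(RuntimeError):
    """Raised by registration stages; the message names the failing stage."""


# ---------------------------------------------------------------------------
# Basic image operations
# ---------------------------------------------------------------------------


def foreground_mask(image: np.ndarray) -> np.ndarray:
    """Binary tissue mask: Otsu threshold, largest component, holes filled."""
    img = normalize_image(image)
    if img.max() <= 0:
        raise RegistrationError("foreground mask: empty image")
    thresh = filters.threshold_otsu(img)
    fg = img > thresh
    if not fg.any():
        raise RegistrationError("foreground mask: empty foreground")
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        fg = lab == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(fg)


def tissue_mask(image: np.ndarray, threshold: float = 0.02) -> np.ndarray:
    """Any-tissue mask: normalized intensity above a small floor, largest
    component, holes filled.  Unlike the Otsu-based :func:`foreground_mask`
    this keeps dark structures (fiber tracts) that sit near the background
    level, so outer contours are not notched."""
    img = normalize_image(image)
    fg = img > threshold
    if not fg.any():
        raise RegistrationError("tissue mask: empty foreground")
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        fg = lab == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(fg)


def mutual_information(image_a: np.ndarray, image_b: np.ndarray, bins: int = 32) -> float:
    """Mutual information of the joint intensity histogram, in bits."""
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (pa @ pb)[nz])).sum())


# ---------------------------------------------------------------------------
# Displacement fields
# ---------------------------------------------------------------------------


@dataclass
class DisplacementField:
    """Dense pull-back displacement: warped(p) = source(p + field[p]).

    ``field`` has shape (H, W, 2) in (row, col) pixel units on the target
    canvas; the identity transform is the all-zero field.
    """

    field: np.ndarray

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        if self.field.ndim != 3 or self.field.shape[2] != 2:
            raise ValueError(f"field must have shape (H, W, 2), got {self.field.shape}")
        if not np.isfinite(self.field).all():
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.field.shape[:2]

    def coords(self) -> np.ndarray:
        """Absolute source coordinates, shape (2, H, W)."""
        h, w = self.shape
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        return np.stack([rr + self.field[..., 0], cc + self.field[..., 1]])

    def warp(self, image: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        return ndimage.map_coordinates(np.asarray(image, float), self.coords(),
                                       order=order, mode="constant", cval=cval)

    def warp_labels(self, labels: np.ndarray) -> np.ndarray:
        out = ndimage.map_coordinates(labels, self.coords(), order=0,
                                      mode="constant", cval=0)
        return out.astype(labels.dtype)

    def sample_at(self, coords: np.ndarray) -> np.ndarray:
        """Pull-back through this field at arbitrary (2, ...) coordinates."""
        dr = ndimage.map_coordinates(self.field[..., 0], coords, order=1,
                                     mode="nearest")
        dc = ndimage.map_coordinates(self.field[..., 1], coords, order=1,
                                     mode="nearest")
        return coords + np.stack([dr, dc])

    @classmethod
    def identity(cls, shape: tuple[int, int]) -> "DisplacementField":
        return cls(field=np.zeros(shape + (2,)))


def _similarity_pullback(points: np.ndarray, shape: tuple[int, int],
                         params: np.ndarray) -> np.ndarray:
    """Source coordinates of target-space ``points`` (2, ...) under a centered
    similarity transform.

    params = (t_row, t_col, theta_rad, log_scale); forward model:
    target point p = s R (q - c) + c + t for source point q.
    """
    h, w = shape
    tr, tc, theta, logs = params
    s = math.exp(logs)
    cr, ccol = (h - 1) / 2.0, (w - 1) / 2.0
    dr = (points[0] - cr - tr) / s
    dc = (points[1] - ccol - tc) / s
    cos, sin = math.cos(-theta), math.sin(-theta)
    return np.stack([cr + cos * dr - sin * dc, ccol + sin * dr + cos * dc])


def _similarity_coords(shape: tuple[int, int], params: np.ndarray) -> np.ndarray:
    """Dense pull-back coordinate grid of the centered similarity transform."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    return _similarity_pullback(np.stack([rr, cc]), shape, params)


def _coords_to_field(coords: np.ndarray) -> np.ndarray:
    h, w = coords.shape[1:]
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return np.stack([coords[0] - rr, coords[1] - cc], axis=-1)


@dataclass
class RegistrationConfig:
    """Automatic-stage settings.

    ``pyramid_levels`` downsampling factors (coarse to fine);
    ``iterations`` dense refinement iterations per level;
    ``update_sigma_px`` / ``field_sigma_px`` Gaussian regularization of the
    per-iteration update and of the accumulated field, in pixels.
    """

    pyramid_levels: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (30, 40, 60)
    update_sigma_px: float = 2.0
    field_sigma_px: float = 1.0
    mi_bins: int = 32
    step_px: float = 0.5
    working_max_side: int = 256
    mi_tolerance_bits: float = 0.02


def _remap_target(tgt: np.ndarray, src_warped: np.ndarray, bins: int = 32) -> np.ndarray:
    """Replace each target intensity bin by the mean warped-source intensity
    it currently overlaps.  The simplified atlas has very few intensity
    levels, so this projects the many-leveled section image into the atlas
    contrast space and turns the multimodal pair into a monomodal one for
    the demons force."""
    idx = np.clip((tgt * (bins - 1)).round().astype(int), 0, bins - 1)
    out = np.zeros_like(tgt)
    for b in np.unique(idx):
        sel = idx == b
        out[sel] = src_warped[sel].mean()
    return out


def auto_register(
    simplified_atlas: np.ndarray,
    section_image: np.ndarray,
    config: RegistrationConfig | None = None,
) -> tuple[DisplacementField, dict]:
    """Automatic deformable registration of the atlas rendering to the section.

    Multiresolution: a centered similarity transform maximizing mutual
    information seeds an iterative demons-style dense refinement with
    Gaussian-regularized updates.  Returns (field, history); the history
    carries the MI trace and a ``converged`` flag -- when the dense stage
    fails to beat the similarity stage (within tolerance) the similarity
    field is returned and the flag is False, never silently.
    """
    config = config or RegistrationConfig()
    src = normalize_image(simplified_atlas)
    tgt = normalize_image(section_image)
    if src.shape != tgt.shape:
        raise RegistrationError(
            f"auto registration: image shapes differ, {src.shape} vs {tgt.shape}"
        )
    if src.max() <= 0 or tgt.max() <= 0:
        raise RegistrationError("auto registration: empty source or target image")
    history: dict = {"mi": [], "stage": [], "converged": True}

    # --- stage 1: centered similarity transform by MI (coarse grid) --------
    factor = max(config.pyramid_levels)
    small_shape = (max(1, src.shape[0] // factor), max(1, src.shape[1] // factor))
    src_s = sktransform.resize(src, small_shape, order=1, anti_aliasing=True,
                               preserve_range=True)
    tgt_s = sktransform.resize(tgt, small_shape, order=1, anti_aliasing=True,
                               preserve_range=True)

    def neg_mi_small(params: np.ndarray) -> float:
        coords = _similarity_coords(small_shape, params)
        warped = ndimage.map_coordinates(src_s, coords, order=1, mode="constant")
        return -mutual_information(tgt_s, warped, bins=max(8, config.mi_bins // 2))

    best = optimize.minimize(
        neg_mi_small, np.zeros(4), method="Powell",
        options={"xtol": 1e-3, "ftol": 1e-4, "maxiter": 400},
    )
    params = best.x * np.array([factor, factor, 1.0, 1.0])

    sim_coords = _similarity_coords(src.shape, params)
    sim_field = _coords_to_field(sim_coords)
    src_sim = DisplacementField(sim_field).warp(src)
    mi_sim = mutual_information(tgt, src_sim, bins=config.mi_bins)
    history["mi"].append(mi_sim)
    history["stage"].append("similarity")

    # --- stage 2: dense demons-style refinement over the pyramid -----------
    # the dense field is the *residual* on top of the similarity-resampled
    # source, so the Gaussian regularization never has to smooth the global
    # pose ramp (which would corrupt it at the image borders)
    field = None
    for factor, iters in zip(config.pyramid_levels, config.iterations):
        shape_l = (max(2, src.shape[0] // factor), max(2, src.shape[1] // factor))
        src_l = sktransform.resize(src_sim, shape_l, order=1, anti_aliasing=True,
                                   preserve_range=True)
        tgt_l = sktransform.resize(tgt, shape_l, order=1, anti_aliasing=True,
                                   preserve_range=True)
        if field is None:
            field = np.zeros(shape_l + (2,))
        else:
            scale = shape_l[0] / field.shape[0]
            field = np.stack(
                [sktransform.resize(field[..., k], shape_l, order=1,
                                    preserve_range=True) * scale for k in range(2)],
                axis=-1,
            )
        rr, cc = np.meshgrid(np.arange(shape_l[0]), np.arange(shape_l[1]),
                             indexing="ij")
        for _ in range(iters):
            coords = np.stack([rr + field[..., 0], cc + field[..., 1]])
            warped = ndimage.map_coordinates(src_l, coords, order=1, mode="constant")
            tgt_m = _remap_target(tgt_l, warped)
            diff = tgt_m - warped
            gr, gc = np.gradient(warped)
            denom = gr**2 + gc**2 + diff**2 / (config.step_px**2 + 1e-12)
            denom[denom < 1e-9] = np.inf
            ur = diff * gr / denom
            uc = diff * gc / denom
            ur = ndimage.gaussian_filter(ur, config.update_sigma_px)
            uc = ndimage.gaussian_filter(uc, config.update_sigma_px)
            field[..., 0] += config.step_px * ur
            field[..., 1] += config.step_px * uc
            field[..., 0] = ndimage.gaussian_filter(field[..., 0], config.field_sigma_px)
            field[..., 1] = ndimage.gaussian_filter(field[..., 1], config.field_sigma_px)

    scale = src.shape[0] / field.shape[0]
    if scale != 1.0:
        field = np.stack(
            [sktransform.resize(field[..., k], src.shape, order=1,
                                preserve_range=True) * scale for k in range(2)],
            axis=-1,
        )
    # compose: pull back through the dense residual, then the similarity
    h, w = src.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    inter = np.stack([rr + field[..., 0], cc + field[..., 1]])
    total = _similarity_pullback(inter, src.shape, params)
    dense = DisplacementField(_coords_to_field(total))
    mi_dense = mutual_information(tgt, dense.warp(src), bins=config.mi_bins)
    history["mi"].append(mi_dense)
    history["stage"].append("dense")

    if mi_dense < mi_sim - config.mi_tolerance_bits:
        history["converged"] = False
        return DisplacementField(sim_field), history
    return dense, history


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    """Ordered (row, col) landmark coordinates with per-point origin.

    origin entries are 'manual' or 'automatic_contour'; source and target
    sets correspond by index.
    """

    points: np.ndarray
    origin: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not self.origin:
            self.origin = ["manual"] * len(self.points)
        if len(self.origin) != len(self.points):
            raise ValueError("origin list must match the number of points")
        if len(self.points) != len({tuple(p) for p in self.points.round(9).tolist()}):
            raise ValueError("duplicate landmark points")

    def __len__(self) -> int:
        return len(self.points)

    def extend(self, other: "LandmarkSet") -> "LandmarkSet":
        return LandmarkSet(points=np.vstack([self.points, other.points]),
                           origin=self.origin + other.origin)


def contour_landmarks(mask: np.ndarray, n: int = 20) -> LandmarkSet:
    """n points equally spaced by arc length along the outer contour.

    The walk starts at the topmost (then leftmost) contour point and runs
    clockwise in image coordinates; deterministic for a given mask.
    """
    mask = np.asarray(mask, bool)
    lab, ncomp = ndimage.label(mask)
    if ncomp != 1:
        raise RegistrationError(
            f"contour landmarks: mask must have exactly one component, found {ncomp}"
        )
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=lambda c: len(c))
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    seg = np.sqrt((np.diff(np.vstack([contour, contour[:1]]), axis=0) ** 2).sum(1))
    total = float(seg.sum())
    if total < n:
        raise RegistrationError(
            f"contour landmarks: contour length {total:.1f}px shorter than n={n}"
        )
    # canonical start: topmost, then leftmost vertex
    start = int(np.lexsort((contour[:, 1], contour[:, 0]))[0])
    contour = np.roll(contour, -start, axis=0)
    # canonical orientation: clockwise in image coords (y down) = positive
    # signed area in (row, col)
    r, c = contour[:, 0], contour[:, 1]
    area = 0.5 * float(np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r))
    if area < 0:
        contour = np.vstack([contour[:1], contour[1:][::-1]])
    seg = np.sqrt((np.diff(np.vstack([contour, contour[:1]]), axis=0) ** 2).sum(1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n) * cum[-1] / n
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(contour) - 1)
    frac = (targets - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    nxt = (idx + 1) % len(contour)
    pts = contour[idx] + frac[:, None] * (contour[nxt] - contour[idx])
    return LandmarkSet(points=pts, origin=["automatic_contour"] * n)


# ---------------------------------------------------------------------------
# Piecewise affine
# ---------------------------------------------------------------------------


def _affine_from_pairs(src3: np.ndarray, dst3: np.ndarray) -> np.ndarray:
    """Exact 2x3 affine mapping three source points to three destinations."""
    A = np.hstack([src3, np.ones((3, 1))])
    try:
        sol = np.linalg.solve(A, dst3)
    except np.linalg.LinAlgError as exc:
        raise RegistrationError(f"piecewise affine: degenerate triangle ({exc})") from exc
    return sol.T  # (2, 3): out = M @ [r, c, 1]


class PiecewiseAffineTransform:
    """Per-triangle exact affine warp over the Delaunay triangulation of the
    destination landmarks; points outside the hull map by identity.

    ``forward`` matrices map source -> destination per triangle, ``backward``
    the exact inverse (destination -> source), both solved from the three
    vertex pairs of each triangle.
    """

    def __init__(self, src_points: np.ndarray, dst_points: np.ndarray):
        self.src = np.asarray(src_points, float).reshape(-1, 2)
        self.dst = np.asarray(dst_points, float).reshape(-1, 2)
        if self.src.shape != self.dst.shape:
            raise ValueError("source and destination landmark counts differ")
        if len(self.src) < 3:
            raise ValueError("need at least 3 landmark pairs")
        try:
            self.tri = Delaunay(self.dst)
        except QhullError as exc:
            raise RegistrationError(
                f"piecewise affine: landmarks are degenerate/collinear ({exc})"
            ) from exc
        n_tri = len(self.tri.simplices)
        self.forward = np.empty((n_tri, 2, 3))
        self.backward = np.empty_like(self.forward)
        # grid-aligned contour landmarks can be exactly collinear, making
        # qhull emit zero-area slivers on the hull edge; those carry no
        # pixels and are mapped by identity instead of an ill-posed solve
        self.valid = np.ones(n_tri, dtype=bool)
        self.fwd_valid = np.ones(n_tri, dtype=bool)
        identity = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        for k, simplex in enumerate(self.tri.simplices):
            d3 = self.dst[simplex]
            s3 = self.src[simplex]
            area = abs(np.linalg.det(np.hstack([d3, np.ones((3, 1))]))) / 2.0
            if area < 1e-9:
                self.valid[k] = False
                self.fwd_valid[k] = False
                self.forward[k] = identity
                self.backward[k] = identity
                continue
            self.backward[k] = _affine_from_pairs(d3, s3)
            src_area = abs(np.linalg.det(np.hstack([s3, np.ones((3, 1))]))) / 2.0
            if src_area < 1e-9:
                # source triple collinear: the pull-back is still well posed,
                # but there is no forward affine for this triangle
                self.fwd_valid[k] = False
                self.forward[k] = identity
            else:
                self.forward[k] = _affine_from_pairs(s3, d3)
        if not self.valid.any():
            raise RegistrationError(
                "piecewise affine: all triangles are degenerate (collinear landmarks)"
            )

    def pullback_coords(self, shape: tuple[int, int]) -> np.ndarray:
        """Source coordinates for each pixel of a ``shape`` destination canvas."""
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        simplex = self.tri.find_simplex(pts)
        out = pts.copy()
        inside = simplex >= 0
        if inside.any():
            homo = np.column_stack([pts[inside], np.ones(int(inside.sum()))])
            mats = self.backward[simplex[inside]]
            out[inside] = np.einsum("nij,nj->ni", mats, homo)
        return out.T.reshape(2, *shape)

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        """Forward map (source -> destination); outside all triangles: identity."""
        pts = np.asarray(points, float).reshape(-1, 2)
        out = pts.copy()
        for k, simplex in enumerate(self.tri.simplices):
            if not (self.valid[k] and self.fwd_valid[k]):
                continue
            s3 = self.src[simplex]
            T = np.vstack([(s3[1] - s3[0]), (s3[2] - s3[0])]).T
            try:
                bary = np.linalg.solve(T, (pts - s3[0]).T).T
            except np.linalg.LinAlgError:
                continue
            w = np.column_stack([1 - bary.sum(1), bary])
            inside = (w >= -1e-9).all(axis=1)
            if inside.any():
                homo = np.column_stack([pts[inside], np.ones(int(inside.sum()))])
                out[inside] = homo @ self.forward[k].T
        return out

    def warp(self, image: np.ndarray, order: int = 1) -> np.ndarray:
        coords = self.pullback_coords(image.shape[:2])
        return ndimage.map_coordinates(np.asarray(image, float), coords,
                                       order=order, mode="constant")


def build_piecewise_affine(
    src_landmarks: LandmarkSet | np.ndarray,
    dst_landmarks: LandmarkSet | np.ndarray,
    domain_shape: tuple[int, int] | None = None,
) -> PiecewiseAffineTransform:
    """Triangulate the destination landmarks and solve per-triangle affines."""
    src = src_landmarks.points if isinstance(src_landmarks, LandmarkSet) else src_landmarks
    dst = dst_landmarks.points if isinstance(dst_landmarks, LandmarkSet) else dst_landmarks
    t = PiecewiseAffineTransform(src, dst)
    t.domain_shape = domain_shape
    return t


# ---------------------------------------------------------------------------
# Composition and the hybrid pipeline
# ---------------------------------------------------------------------------


@dataclass
class RegistrationResult:
    """Composed registration M_LM o M_Ard with provenance."""

    m_ard: DisplacementField
    m_lm: PiecewiseAffineTransform | None = None
    history: dict = field(default_factory=dict)
    config: RegistrationConfig | None = None
    warped_labels: np.ndarray | None = None
    warped_atlas: np.ndarray | None = None

    def total_coords(self, shape: tuple[int, int]) -> np.ndarray:
        """Pull-back coordinates of the full composition on a target canvas."""
        if self.m_lm is not None:
            inter = self.m_lm.pullback_coords(shape)
        else:
            rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                                 indexing="ij")
            inter = np.stack([rr, cc]).astype(float)
        return self.m_ard.sample_at(inter)


def apply_transform(
    raster: np.ndarray,
    result: RegistrationResult,
    interpolation: str = "nearest",
) -> np.ndarray:
    """Warp a raster through the composed registration.

    Integer label rasters must use nearest-neighbor interpolation; the warp
    can therefore never create structure IDs absent from the input.
    """
    raster = np.asarray(raster)
    is_labels = np.issubdtype(raster.dtype, np.integer)
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"interpolation must be 'nearest' or 'linear', got {interpolation!r}")
    if is_labels and interpolation == "linear":
        raise ValueError("linear interpolation would fabricate IDs on an integer label raster")
    coords = result.total_coords(raster.shape[:2])
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.map_coordinates(raster.astype(float), coords, order=order,
                                  mode="constant", cval=0)
    return out.astype(raster.dtype) if is_labels else out


def register_hybrid(
    atlas_slice: LabeledSlice,
    section_image: np.ndarray,
    graph: StructureGraph,
    manual_landmarks: tuple[LandmarkSet, LandmarkSet] | None = None,
    config: RegistrationConfig | None = None,
    n_contour: int = 20,
) -> RegistrationResult:
    """Full hybrid registration of an atlas slice onto a section image.

    The atlas is simplified (fiber tracts gray on green), auto-registered
    to the section, and -- when manual landmark pairs (source side on the
    auto-warped atlas, destination side on the section) are provided --
    refined by a piecewise-affine warp built from the manual pairs plus
    ``n_contour`` automatic outer-contour points per side.  Returns the
    composed result with the warped label raster attached.
    """
    config = config or RegistrationConfig()
    simplified = simplify_atlas_slice(atlas_slice, graph)
    try:
        m_ard, history = auto_register(simplified, section_image, config)
    except RegistrationError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise RegistrationError(f"auto registration: {exc}") from exc

    result = RegistrationResult(m_ard=m_ard, history=history, config=config)
    if manual_landmarks is not None:
        src_lm, dst_lm = manual_landmarks
        warped_atlas = m_ard.warp(normalize_image(simplified))
        try:
            src_contour = contour_landmarks(tissue_mask(warped_atlas), n_contour)
            dst_contour = contour_landmarks(tissue_mask(section_image), n_contour)
        except RegistrationError as exc:
            raise RegistrationError(f"landmark refinement: {exc}") from exc
        # pair contours by arc-length index after the cyclic shift that
        # minimizes total pair distance (the canonical start point can land
        # on different contour features of the two masks)
        n = len(src_contour)
        shifts = [
            float(np.linalg.norm(np.roll(src_contour.points, -k, axis=0)
                                 - dst_contour.points, axis=1).sum())
            for k in range(n)
        ]
        k_best = int(np.argmin(shifts))
        src_contour = LandmarkSet(
            points=np.roll(src_contour.points, -k_best, axis=0),
            origin=src_contour.origin,
        )
        src_all = src_lm.extend(src_contour)
        dst_all = dst_lm.extend(dst_contour)
        result.m_lm = build_piecewise_affine(src_all, dst_all,
                                             domain_shape=section_image.shape[:2])
        result.history["n_landmarks"] = len(src_all)

    result.warped_labels = apply_transform(atlas_slice.labels, result, "nearest")
    result.warped_atlas = apply_transform(normalize_image(simplified), result, "linear")
    return result


def invert_field(field: DisplacementField, iterations: int = 10) -> DisplacementField:
    """Fixed-point approximate inverse of a pull-back displacement field."""
    h, w = field.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    inv = np.zeros_like(field.field)
    for _ in range(iterations):
        coords = np.stack([rr + inv[..., 0], cc + inv[..., 1]])
        dr = ndimage.map_coordinates(field.field[..., 0], coords, order=1, mode="nearest")
        dc = ndimage.map_coordinates(field.field[..., 1], coords, order=1, mode="nearest")
        inv[..., 0] = -dr
        inv[..., 1] = -dc
    return DisplacementField(inv)
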