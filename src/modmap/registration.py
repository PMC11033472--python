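"""Serial-section alignment via landmark-fitted projective transforms.

Tangential sections are cut and mounted independently, so each deeper
section is related to the layer-1 (L1) reference frame by a small projective
distortion.  Blood vessels pierce the stack nearly perpendicularly and serve
as landmark correspondences; a homography is fitted to them per section by
least squares (normalized direct linear transform) and used to transport the
L1 patch/interpatch map down the stack.

All transforms act on physical (x_um, y_um) coordinates — sections may
differ in pixel size.  Intensity images are resampled bilinearly via inverse
mapping; label images are transported nearest-neighbour so class labels
never blend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from .image import ModmapError, ModuleMap, ParameterError, PlanarImage


class UnderdeterminedError(ModmapError):
    """Fewer than 4 landmark pairs: the projective fit has 8 dof."""


class DegenerateConfigurationError(ModmapError):
    """Landmark configuration is (near-)degenerate; the fit is unstable."""


@dataclass
class LandmarkSet:
    """Point correspondences between the reference frame and one section.

    ``reference_xy_um`` and ``section_xy_um`` are (n, 2) arrays of matched
    coordinates; row i of one corresponds to row i of the other.
    """

    reference_xy_um: np.ndarray
    section_xy_um: np.ndarray
    section_index: int = 1

    def __post_init__(self) -> None:
        self.reference_xy_um = np.atleast_2d(np.asarray(self.reference_xy_um, float))
        self.section_xy_um = np.atleast_2d(np.asarray(self.section_xy_um, float))
        if self.reference_xy_um.shape != self.section_xy_um.shape:
            raise ParameterError("landmark tables must have matching shapes")
        if self.reference_xy_um.shape[1] != 2:
            raise ParameterError("landmarks must be (n, 2) xy coordinates")

    def __len__(self) -> int:
        return len(self.reference_xy_um)


@dataclass
class PlanarProjectiveTransform:
    """Invertible 3x3 homography acting on um coordinates.

    The matrix is normalized so the lower-right element equals 1.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ParameterError("homography matrix must be 3x3")
        if abs(m[2, 2]) < 1e-15 or not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(
            m
        ) > 1e12:
            raise DegenerateConfigurationError(
                "homography matrix is singular or badly conditioned"
            )
        self.matrix = m / m[2, 2]

    @classmethod
    def identity(cls) -> "PlanarProjectiveTransform":
        return cls(np.eye(3))

    def apply(self, points_xy_um: np.ndarray) -> np.ndarray:
        """Map (n, 2) um coordinates through the homography."""
        pts = np.atleast_2d(np.asarray(points_xy_um, float))
        hom = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return hom[:, :2] / hom[:, 2:3]

    def inverse(self) -> "PlanarProjectiveTransform":
        return PlanarProjectiveTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "PlanarProjectiveTransform") -> "PlanarProjectiveTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return PlanarProjectiveTransform(self.matrix @ other.matrix)


def estimate_homography_matrix(
    src_xy: np.ndarray, dst_xy: np.ndarray
) -> np.ndarray | None:
    """Normalized-DLT least-squares homography; None when degenerate."""
    if hasattr(ProjectiveTransform, "from_estimate"):
        tform = ProjectiveTransform.from_estimate(src_xy, dst_xy)
        if not tform:
            return None
    else:  # scikit-image < 0.26
        tform = ProjectiveTransform()
        if not tform.estimate(src_xy, dst_xy):
            return None
    if not np.all(np.isfinite(tform.params)):
        return None
    return tform.params


@dataclass
class FitResult:
    transform: PlanarProjectiveTransform
    residual_rms_um: float
    n_landmarks: int


def fit_projective(landmarks: LandmarkSet) -> FitResult:
    """Least-squares homography from reference to section coordinates.

    Uses the normalized direct linear transform (coordinates conditioned to
    zero mean and unit RMS before solving); exact for four landmarks in
    general position, least squares beyond.
    """
    if len(landmarks) < 4:
        raise UnderdeterminedError(
            f"projective fit needs >= 4 landmark pairs, got {len(landmarks)}"
        )
    params = estimate_homography_matrix(
        landmarks.reference_xy_um, landmarks.section_xy_um
    )
    if params is None:
        raise DegenerateConfigurationError(
            "landmark configuration is degenerate (collinear or coincident points)"
        )
    transform = PlanarProjectiveTransform(params)
    resid = transform.apply(landmarks.reference_xy_um) - landmarks.section_xy_um
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1)))) if len(landmarks) else 0.0
    return FitResult(transform, rms, len(landmarks))


def transform_points(
    transform: PlanarProjectiveTransform, points_xy_um: np.ndarray
) -> np.ndarray:
    """Map um points exactly through the homography."""
    return transform.apply(points_xy_um)


def _pixel_matrix(
    transform: PlanarProjectiveTransform, src_pixel_um: float, dst_pixel_um: float
) -> np.ndarray:
    """Homography conjugated into pixel (x=col, y=row) coordinates."""
    s_src = np.diag([src_pixel_um, src_pixel_um, 1.0])
    s_dst = np.diag([1.0 / dst_pixel_um, 1.0 / dst_pixel_um, 1.0])
    return s_dst @ transform.matrix @ s_src


def transform_image(
    transform: PlanarProjectiveTransform,
    image: PlanarImage,
    out_shape: tuple[int, int] | None = None,
    out_pixel_size_um: float | None = None,
    order: int = 1,
) -> PlanarImage:
    """Resample an image into the frame ``transform`` maps it onto.

    Inverse mapping with bilinear interpolation (``order=1``) for intensity;
    pass ``order=0`` for label images.  Pixels mapping outside the source
    frame become background (0) and are dropped from the output mask; the
    mask itself is transported nearest-neighbour.
    """
    out_shape = out_shape or image.shape
    out_px = out_pixel_size_um or image.pixel_size_um
    fwd_px = _pixel_matrix(transform, image.pixel_size_um, out_px)
    inv = ProjectiveTransform(matrix=np.linalg.inv(fwd_px))
    pixels = warp(
        image.pixels, inv, output_shape=out_shape, order=order, cval=0.0,
        preserve_range=True,
    )
    mask = warp(
        image.mask.astype(float), inv, output_shape=out_shape, order=0, cval=0.0,
        preserve_range=True,
    ) > 0.5
    return PlanarImage(np.clip(pixels, 0.0, None), out_px, mask)


DEFAULT_LAYER_TABLE: dict[str, tuple[int, int]] = {
    "L1": (1, 2),
    "L2-4": (3, 7),
    "L5": (8, 12),
    "L6": (13, 16),
}


@dataclass
class LayerAssignment:
    """Map from serial-section index to cortical layer label.

    The default follows the 40 um tangential sectioning scheme in which L1
    occupies sections 1-2, L2-4 sections 3-7, L5 sections 8-12 and L6
    sections 13-16 (laminar borders identified with PV and Ctip2 staining).
    Indices outside the table map to "unknown".
    """

    table: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_TABLE)
    )

    def __post_init__(self) -> None:
        spans = sorted(self.table.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if a1 >= b0:
                raise ParameterError("layer index ranges must not overlap")
        if any(a0 > a1 for a0, a1 in self.table.values()):
            raise ParameterError("layer index ranges must be non-empty")

    def assign(self, section_index: int) -> str:
        for layer, (lo, hi) in self.table.items():
            if lo <= section_index <= hi:
                return layer
        return "unknown"


def assign_layer(
    section_index: int, layer_assignment: LayerAssignment | None = None
) -> str:
    """Layer label for a section index (total function; unknown beyond table)."""
    return (layer_assignment or LayerAssignment()).assign(section_index)


def propagate_modules(
    module_map_l1: ModuleMap,
    transforms: dict[int, PlanarProjectiveTransform],
    section_indices: list[int] | None = None,
    out_shape: tuple[int, int] | None = None,
) -> dict[int, ModuleMap]:
    """Transport the L1 module labels into each section's frame.

    ``transforms[k]`` must map reference (L1) coordinates to section-k
    coordinates; labels are carried by the inverse map with
    nearest-neighbour sampling so they never blend.
    """
    wanted = section_indices if section_indices is not None else sorted(transforms)
    missing = [k for k in wanted if k not in transforms]
    if missing:
        raise ModmapError(f"missing transforms for section(s) {missing}")
    label_img = PlanarImage(
        module_map_l1.quantile_label.astype(float),
        module_map_l1.pixel_size_um,
        module_map_l1.quantile_label > 0,
    )
    out: dict[int, ModuleMap] = {}
    for k in wanted:
        moved = transform_image(
            transforms[k], label_img, out_shape=out_shape, order=0
        )
        labels = moved.pixels.astype(np.int16)
        labels[~moved.mask] = 0
        out[k] = ModuleMap(
            labels,
            n_quantiles=module_map_l1.n_quantiles,
            top_k=module_map_l1.top_k,
            bottom_k=module_map_l1.bottom_k,
            pixel_size_um=moved.pixel_size_um,
        )
    return out
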