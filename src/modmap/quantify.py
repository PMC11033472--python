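"""Module-conditioned density statistics.

Everything downstream of segmentation and alignment lives here: ROI optical
density per intensity quantile, radial density profiles around the
injection centre with core exclusion, point densities per module class,
patch/interpatch ratios, anisotropy aspect ratios from second moments, and
the two-sample Kolmogorov-Smirnov comparison of patch vs interpatch
samples.

Densities are physical: signal sums or point counts divided by class area
in um^2 (points are reported per mm^2).  Radial profiles are normalized by
a single shared constant — the joint maximum over both class curves — so
the two curves remain comparable on one axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .image import InjectionSite, ModmapError, ModuleMap, ParameterError, PlanarImage

MODULE_CLASSES = ("patch", "interpatch")


class EmptySampleError(ModmapError):
    """A statistical comparison received an empty sample."""


# ---------------------------------------------------------------------------
# injection centre


def detect_injection_center(
    image: PlanarImage, saturation_quantile: float = 0.999
) -> InjectionSite:
    """Locate the injection core as the centroid of saturated pixels.

    The centre is the intensity-weighted centroid of masked pixels at or
    above the given intensity quantile.  The core radius is an analysis
    parameter, not estimated here.
    """
    vals = image.pixels[image.mask]
    if vals.size == 0:
        raise ParameterError("image mask is empty")
    # threshold = k-th largest masked value with k = floor(n * (1 - q)), so
    # the super-threshold set has the requested tail fraction even when the
    # background is heavily tied (e.g. a flat field plus a saturated spot)
    k = max(1, int(np.floor(vals.size * (1.0 - saturation_quantile))))
    thr = np.partition(vals, -k)[-k]
    sel = image.mask & (image.pixels >= thr)
    weights = image.pixels[sel]
    if sel.sum() == 0 or weights.sum() <= 0:
        raise ParameterError("no pixels at or above the saturation quantile")
    x_um, y_um = image.coords_um()
    cx = float(np.average(x_um[sel], weights=weights))
    cy = float(np.average(y_um[sel], weights=weights))
    return InjectionSite(
        center_xy_um=(cx, cy), saturation_quantile=saturation_quantile
    )


# ---------------------------------------------------------------------------
# ROIs


@dataclass
class RoiSpec:
    """Axis-aligned rectangular region of interest in um coordinates."""

    x_um: float
    y_um: float
    width_um: float = 550.0
    height_um: float = 400.0
    name: str = ""

    def pixel_slice(self, pixel_size_um: float, shape: tuple[int, int]) -> tuple[slice, slice]:
        s = pixel_size_um
        r0 = int(np.ceil(self.y_um / s - 0.5))
        c0 = int(np.ceil(self.x_um / s - 0.5))
        r1 = int(np.floor((self.y_um + self.height_um) / s - 0.5)) + 1
        c1 = int(np.floor((self.x_um + self.width_um) / s - 0.5)) + 1
        if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
            raise ParameterError(f"ROI {self.name or (self.x_um, self.y_um)} exceeds the image frame")
        return slice(r0, r1), slice(c0, c1)


def ring_rois(
    injection: InjectionSite,
    n_rois: int = 3,
    ring_radius_um: float = 700.0,
    width_um: float = 550.0,
    height_um: float = 400.0,
    phase_deg: float = 90.0,
) -> list[RoiSpec]:
    """Place ROIs at equal angles on a ring around the injection centre.

    Emulates the manual choice of quantification fields "where the
    projection density was strong enough": outside the saturated core,
    inside the halo.
    """
    cx, cy = injection.center_xy_um
    rois = []
    for i in range(n_rois):
        ang = np.deg2rad(phase_deg + 360.0 * i / n_rois)
        rois.append(
            RoiSpec(
                x_um=cx + ring_radius_um * np.cos(ang) - width_um / 2,
                y_um=cy + ring_radius_um * np.sin(ang) - height_um / 2,
                width_um=width_um,
                height_um=height_um,
                name=f"roi{i + 1}",
            )
        )
    return rois


def roi_quantile_density(
    signal: PlanarImage,
    module_map: ModuleMap,
    rois: list[RoiSpec],
) -> pd.DataFrame:
    """Mean optical density per intensity quantile within each ROI.

    Returns tidy rows (roi, quantile, mean_intensity, pixel_count); a
    quantile absent from an ROI yields no row (missing, not zero).  The
    per-quantile aggregate across ROIs is available via
    :func:`aggregate_quantile_density`.
    """
    if signal.shape != module_map.shape:
        raise ParameterError("signal and module map shapes differ")
    rows = []
    for i, roi in enumerate(rois):
        rs, cs = roi.pixel_slice(signal.pixel_size_um, signal.shape)
        sig = signal.pixels[rs, cs]
        lab = module_map.quantile_label[rs, cs]
        valid = signal.mask[rs, cs] & (lab > 0)
        for q in range(1, module_map.n_quantiles + 1):
            sel = valid & (lab == q)
            n = int(sel.sum())
            if n == 0:
                continue
            rows.append(
                {
                    "roi": roi.name or f"roi{i + 1}",
                    "quantile": q,
                    "mean_intensity": float(sig[sel].mean()),
                    "pixel_count": n,
                }
            )
    return pd.DataFrame(rows, columns=["roi", "quantile", "mean_intensity", "pixel_count"])


def aggregate_quantile_density(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM of per-ROI quantile means, across ROIs."""
    g = table.groupby("quantile")["mean_intensity"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_intensity", "sem": "sem_intensity", "count": "n_rois"})


def roi_class_means(
    signal: PlanarImage, module_map: ModuleMap, rois: list[RoiSpec]
) -> pd.DataFrame:
    """Per-ROI mean optical density in the patch and interpatch classes.

    These are the ROI-level sampling units entering the KS comparison.
    ROIs missing one class entirely yield NaN for that class.
    """
    if signal.shape != module_map.shape:
        raise ParameterError("signal and module map shapes differ")
    rows = []
    for i, roi in enumerate(rois):
        rs, cs = roi.pixel_slice(signal.pixel_size_um, signal.shape)
        sig = signal.pixels[rs, cs]
        valid = signal.mask[rs, cs]
        rec = {"roi": roi.name or f"roi{i + 1}"}
        for cls in MODULE_CLASSES:
            sel = valid & module_map.class_mask(cls)[rs, cs]
            rec[cls] = float(sig[sel].mean()) if sel.any() else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# radial profiles


@dataclass
class RadialProfile:
    """Module-conditioned density vs distance from the injection centre."""

    bin_edges_um: np.ndarray                  # (n_bins + 1,)
    density: dict[str, np.ndarray]            # raw density per class, NaN = missing
    normalized: dict[str, np.ndarray]         # density / joint maximum
    sem: dict[str, np.ndarray] | None         # across replicates, if supplied
    normalization_constant: float
    exclusion_radius_um: float

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    def smoothed(self, cls: str, window: int = 3) -> np.ndarray:
        """Moving-average display curve; statistics use the raw bins."""
        v = self.normalized[cls]
        kernel = np.ones(window) / window
        filled = np.where(np.isfinite(v), v, 0.0)
        wts = np.convolve(np.isfinite(v).astype(float), kernel, mode="same")
        sm = np.convolve(filled, kernel, mode="same")
        with np.errstate(invalid="ignore"):
            return np.where(wts > 0, sm / wts, np.nan)


def _radial_bins(
    exclusion_radius_um: float, max_radius_um: float, bin_width_um: float
) -> np.ndarray:
    if exclusion_radius_um < 0:
        raise ParameterError("exclusion radius must be >= 0")
    n = max(1, int(np.floor((max_radius_um - exclusion_radius_um) / bin_width_um)))
    return exclusion_radius_um + bin_width_um * np.arange(n + 1)


def radial_density_profile(
    module_map: ModuleMap,
    injection: InjectionSite,
    signal: PlanarImage | None = None,
    points: pd.DataFrame | None = None,
    bin_width_um: float = 50.0,
    exclusion_radius_um: float | None = None,
    max_radius_um: float | None = None,
    replicate_profiles: list["RadialProfile"] | None = None,
) -> RadialProfile:
    """Class-conditioned radial density around the injection centre.

    For each annulus (uniform ``bin_width_um`` bins starting at the core
    exclusion radius) and each class c in {patch, interpatch}:
    ``density = (signal sum | point count in annulus ∩ c) / area(annulus ∩ c)``.
    Both curves are divided by one shared constant, the joint maximum, so
    the global peak equals 1.  Annuli where a class has zero area are NaN
    (missing, not zero).
    """
    if (signal is None) == (points is None):
        raise ParameterError("provide exactly one of signal or points")
    s = module_map.pixel_size_um
    h, w = module_map.shape
    cx, cy = injection.center_xy_um
    if not (0 <= cx <= (w - 1) * s and 0 <= cy <= (h - 1) * s):
        raise ParameterError("injection centre lies outside the analysis frame")
    excl = (
        exclusion_radius_um
        if exclusion_radius_um is not None
        else injection.core_exclusion_radius_um
    )
    y, x = np.mgrid[0:h, 0:w]
    r_pix = np.hypot(x * s - cx, y * s - cy)
    if max_radius_um is None:
        max_radius_um = min(cx, cy, (w - 1) * s - cx, (h - 1) * s - cy)
    edges = _radial_bins(excl, max_radius_um, bin_width_um)
    nb = len(edges) - 1
    pix_area = s * s

    density: dict[str, np.ndarray] = {}
    for cls in MODULE_CLASSES:
        cmask = module_map.class_mask(cls)
        dens = np.full(nb, np.nan)
        for b in range(nb):
            ann = (r_pix >= edges[b]) & (r_pix < edges[b + 1]) & cmask
            area = ann.sum() * pix_area
            if area == 0:
                continue
            if signal is not None:
                ok = ann & signal.mask
                area = ok.sum() * pix_area
                if area == 0:
                    continue
                dens[b] = signal.pixels[ok].sum() / area
            else:
                px = points["x_um"].to_numpy()
                py = points["y_um"].to_numpy()
                rr = np.hypot(px - cx, py - cy)
                inb = (rr >= edges[b]) & (rr < edges[b + 1])
                col = np.clip(np.rint(px[inb] / s).astype(int), 0, w - 1)
                row = np.clip(np.rint(py[inb] / s).astype(int), 0, h - 1)
                dens[b] = cmask[row, col].sum() / area
        density[cls] = dens

    joint = np.concatenate([density[c] for c in MODULE_CLASSES])
    peak = np.nanmax(joint) if np.isfinite(joint).any() else np.nan
    if not np.isfinite(peak) or peak == 0:
        peak = 1.0
    normalized = {c: density[c] / peak for c in MODULE_CLASSES}
    sem = None
    if replicate_profiles:
        sem = {}
        for c in MODULE_CLASSES:
            stackv = np.vstack([p.normalized[c] for p in replicate_profiles])
            with np.errstate(invalid="ignore"):
                sem[c] = np.nanstd(stackv, axis=0, ddof=1) / np.sqrt(
                    np.sum(np.isfinite(stackv), axis=0).clip(1)
                )
    return RadialProfile(
        bin_edges_um=edges,
        density=density,
        normalized=normalized,
        sem=sem,
        normalization_constant=float(peak),
        exclusion_radius_um=excl,
    )


def estimate_interpatch_preference(profile: RadialProfile) -> float:
    """Planted-preference estimate: area-stable mean of per-bin ratios.

    Averages interpatch/patch density over all annuli where both classes
    are present; with a multiplicative module effect and distance-matched
    annuli the per-bin ratio is an unbiased estimate of the preference
    factor rho.
    """
    ip = profile.density["interpatch"]
    pa = profile.density["patch"]
    ok = np.isfinite(ip) & np.isfinite(pa) & (pa > 0)
    if not ok.any():
        raise ParameterError("no annulus contains both classes")
    return float(np.mean(ip[ok] / pa[ok]))


# ---------------------------------------------------------------------------
# point densities


def assign_point_modules(
    points: pd.DataFrame, module_map: ModuleMap
) -> pd.DataFrame:
    """Attach the module class under each point (L1-frame coordinates)."""
    s = module_map.pixel_size_um
    h, w = module_map.shape
    col = np.rint(points["x_um"].to_numpy() / s).astype(int)
    row = np.rint(points["y_um"].to_numpy() / s).astype(int)
    inside = (col >= 0) & (col < w) & (row >= 0) & (row < h)
    module = np.full(len(points), "background", dtype=object)
    cc = np.clip(col, 0, w - 1)
    rr = np.clip(row, 0, h - 1)
    for cls in ("patch", "interpatch", "middle"):
        sel = inside & module_map.class_mask(cls)[rr, cc]
        module[sel] = cls
    out = points.copy()
    out["module"] = module
    return out


def point_module_density(
    points: pd.DataFrame,
    module_map: ModuleMap,
    rois: list[RoiSpec],
) -> pd.DataFrame:
    """Point density (per mm^2) per module class per ROI, with the ratio.

    Returns one row per ROI with patch/interpatch densities (count divided
    by that class's area inside the ROI) and the patch/interpatch density
    ratio, which is NaN when the interpatch class is absent or empty.
    Pass points already registered to the L1 frame.
    """
    labeled = assign_point_modules(points, module_map)
    s = module_map.pixel_size_um
    px_mm2 = (s / 1000.0) ** 2
    x = labeled["x_um"].to_numpy()
    y = labeled["y_um"].to_numpy()
    rows = []
    for i, roi in enumerate(rois):
        rs, cs = roi.pixel_slice(s, module_map.shape)
        in_roi = (
            (x >= roi.x_um)
            & (x < roi.x_um + roi.width_um)
            & (y >= roi.y_um)
            & (y < roi.y_um + roi.height_um)
        )
        rec: dict[str, object] = {"roi": roi.name or f"roi{i + 1}"}
        for cls in MODULE_CLASSES:
            area_mm2 = module_map.class_mask(cls)[rs, cs].sum() * px_mm2
            n = int((in_roi & (labeled["module"].to_numpy() == cls)).sum())
            rec[f"{cls}_area_mm2"] = area_mm2
            rec[f"{cls}_density_per_mm2"] = (n / area_mm2) if area_mm2 > 0 else np.nan
        ipd = rec["interpatch_density_per_mm2"]
        # single-class ROIs have valid densities but an undefined ratio
        rec["patch_interpatch_ratio"] = (
            rec["patch_density_per_mm2"] / ipd
            if np.isfinite(ipd) and ipd > 0
            else np.nan
        )
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics


@dataclass
class ComparisonResult:
    ks_statistic: float
    p_value: float
    n_patch: int
    n_interpatch: int
    alpha: float = 0.05
    method: str = "exact"

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def ks_compare(
    sample_patch: np.ndarray,
    sample_interpatch: np.ndarray,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sample Kolmogorov-Smirnov comparison of patch vs interpatch.

    The statistic is the sup-difference of the two empirical CDFs.  The
    p-value is exact when both samples have at most 25 observations and
    asymptotic otherwise.
    """
    a = np.asarray(sample_patch, float)
    b = np.asarray(sample_interpatch, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise EmptySampleError("both samples must be non-empty")
    method = "exact" if max(a.size, b.size) <= 25 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return ComparisonResult(
        ks_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_patch=int(a.size),
        n_interpatch=int(b.size),
        alpha=alpha,
        method=method,
    )


# ---------------------------------------------------------------------------
# anisotropy


@dataclass
class AnisotropyResult:
    aspect_ratio: float
    major_axis_angle_deg: float
    n_support: int


def _moments_aspect(
    x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> AnisotropyResult:
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    dx = x - mx
    dy = y - my
    cxx = (w * dx * dx).sum() / wsum
    cyy = (w * dy * dy).sum() / wsum
    cxy = (w * dx * dy).sum() / wsum
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        raise ParameterError("degenerate (collinear) support; aspect ratio undefined")
    major = evecs[:, 1]
    angle = float(np.degrees(np.arctan2(major[1], major[0]))) % 180.0
    return AnisotropyResult(
        aspect_ratio=float(np.sqrt(evals[1] / evals[0])),
        major_axis_angle_deg=angle,
        n_support=int(len(x)),
    )


def anisotropy_aspect_ratio(
    signal: PlanarImage | None = None,
    points: pd.DataFrame | None = None,
    intensity_quantile_threshold: float = 0.9,
    exclude_mask: np.ndarray | None = None,
) -> AnisotropyResult:
    """Aspect ratio of a labeled field from second central moments.

    For an image: intensity-weighted second central moments of the masked
    pixels at or above the stated intensity quantile (optionally excluding
    e.g. the saturated injection core); for points: unweighted moments.
    Aspect ratio = sqrt(lambda_major / lambda_minor); invariant to rotation
    (within pixel discretization) and to uniform intensity scaling.

    The default threshold keeps only the top decile of intensities: the
    labeled projection field proper.  At looser thresholds the moment pool
    is dominated by far-field background whose spatial spread is isotropic,
    which dilutes the ratio toward 1 (characterized by simulation on scenes
    with planted axis ratios).
    """
    if (signal is None) == (points is None):
        raise ParameterError("provide exactly one of signal or points")
    if signal is not None:
        sel = signal.mask.copy()
        if exclude_mask is not None:
            sel &= ~exclude_mask
        vals = signal.pixels[sel]
        if vals.size < 3:
            raise ParameterError("need at least 3 masked pixels")
        thr = np.quantile(vals, intensity_quantile_threshold)
        sel &= signal.pixels >= thr
        if sel.sum() < 3:
            raise ParameterError("fewer than 3 pixels above the intensity threshold")
        x_um, y_um = signal.coords_um()
        return _moments_aspect(x_um[sel], y_um[sel], signal.pixels[sel])
    if len(points) < 3:
        raise ParameterError("need at least 3 points")
    return _moments_aspect(
        points["x_um"].to_numpy(float),
        points["y_um"].to_numpy(float),
        np.ones(len(points)),
    )
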