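"""Patch / interpatch delineation from a fluorescence image.

The procedure mirrors the standard flatmount workflow for M2-receptor
modules in mouse V1: (1) local normalization — each pixel is divided by the
mean intensity of a surrounding 100 um-radius disc, which removes staining
gradients and acts as a high-pass filter; (2) smoothing with a 30 um-radius
circular averaging filter; (3) partition of the masked pixels into six
equal-count intensity quantiles (sextiles).  The top two sextiles are the
high-M2 patches, the bottom two the low-M2 interpatches.

Both disc filters are mask-aware normalized convolutions: the mean is taken
over the disc intersected with the analysis mask, so tissue edges are not
biased by padding.  A pixel belongs to a disc iff its centre lies within the
radius (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .image import ModmapError, ModuleMap, ParameterError, PlanarImage


class LocalMeanZeroError(ModmapError):
    """The local disc mean vanished inside the mask; reports flagged pixels."""

    def __init__(self, flagged_rowcol: np.ndarray):
        self.flagged_rowcol = flagged_rowcol
        head = ", ".join(f"({r},{c})" for r, c in flagged_rowcol[:5])
        more = "" if len(flagged_rowcol) <= 5 else f" and {len(flagged_rowcol) - 5} more"
        super().__init__(
            f"local disc mean is zero at {len(flagged_rowcol)} masked pixel(s): "
            f"{head}{more}"
        )


class DegeneratePartitionError(ModmapError):
    """Too few distinct intensities to form the requested quantiles."""


@dataclass
class SegmentationParams:
    """Delineation parameters (radii in um)."""

    norm_radius_um: float = 100.0
    blur_radius_um: float = 30.0
    n_quantiles: int = 6
    top_k: int = 2
    bottom_k: int = 2

    def __post_init__(self) -> None:
        if self.norm_radius_um <= 0 or self.blur_radius_um <= 0:
            raise ParameterError("filter radii must be > 0")
        if self.top_k + self.bottom_k > self.n_quantiles:
            raise ParameterError("top_k + bottom_k must not exceed n_quantiles")


def disc_kernel(radius_px: float) -> np.ndarray:
    """Binary disc footprint: pixel centres within ``radius_px`` (inclusive)."""
    if radius_px < 1.0:
        raise ParameterError(
            f"disc radius {radius_px:.3f} px is below 1 pixel; "
            "increase the radius or the image resolution"
        )
    r = int(np.floor(radius_px))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    # tiny tolerance so exact-integer radii include their boundary pixels
    return (dy * dy + dx * dx <= radius_px * radius_px * (1 + 1e-12)).astype(np.float64)


def _masked_disc_mean(image: PlanarImage, radius_um: float) -> np.ndarray:
    """Mean over disc ∩ mask at every pixel (normalized convolution)."""
    kernel = disc_kernel(radius_um / image.pixel_size_um)
    m = image.mask.astype(np.float64)
    num = fftconvolve(image.pixels * m, kernel, mode="same")
    den = fftconvolve(m, kernel, mode="same")
    out = np.zeros_like(num)
    ok = den > 0.5  # at least one in-mask pixel in the disc
    out[ok] = num[ok] / den[ok]
    return out


def normalize_local(image: PlanarImage, norm_radius_um: float = 100.0) -> PlanarImage:
    """Divide each pixel by the mean intensity of its surrounding disc.

    Scale-invariant by construction: ``normalize_local(k * I) ==
    normalize_local(I)`` for any k > 0.
    """
    local_mean = _masked_disc_mean(image, norm_radius_um)
    bad = image.mask & (local_mean <= 0)
    if bad.any():
        raise LocalMeanZeroError(np.argwhere(bad))
    out = np.zeros_like(image.pixels)
    out[image.mask] = image.pixels[image.mask] / local_mean[image.mask]
    return image.with_pixels(out)


def blur_circular(image: PlanarImage, blur_radius_um: float = 30.0) -> PlanarImage:
    """Circular averaging filter: disc-mean of the image at every pixel."""
    blurred = _masked_disc_mean(image, blur_radius_um)
    out = np.zeros_like(blurred)
    out[image.mask] = np.clip(blurred[image.mask], 0.0, None)
    return image.with_pixels(out)


def quantile_partition(
    image: PlanarImage,
    n_quantiles: int = 6,
    top_k: int = 2,
    bottom_k: int = 2,
) -> ModuleMap:
    """Partition masked pixels into equal-count intensity quantiles.

    Pixels are ranked by intensity; boundary values sit at ranks
    ``i * N / n_quantiles``.  Ties at a boundary all go to the lower
    quantile, which keeps the partition deterministic across platforms.
    """
    vals = image.pixels[image.mask]
    spread = vals.max() - vals.min() if vals.size else 0.0
    if np.unique(vals).size < n_quantiles or spread <= 1e-9 * max(
        abs(vals.max()), 1e-300
    ):
        raise DegeneratePartitionError(
            f"need at least {n_quantiles} distinct masked intensities "
            "spanning a non-degenerate range"
        )
    n = vals.size
    order = np.sort(vals, kind="stable")
    # boundary value of quantile i = value at rank i*N/n (1-based, floor)
    ranks = (np.arange(1, n_quantiles) * n) // n_quantiles
    boundaries = order[ranks - 1]
    labels = np.zeros(image.shape, dtype=np.int16)
    # label = 1 + number of boundaries strictly below the value
    labels[image.mask] = 1 + np.searchsorted(boundaries, vals, side="left").astype(
        np.int16
    )
    return ModuleMap(
        labels,
        n_quantiles=n_quantiles,
        top_k=top_k,
        bottom_k=bottom_k,
        pixel_size_um=image.pixel_size_um,
    )


def delineate_modules(
    image: PlanarImage, params: SegmentationParams | None = None
) -> ModuleMap:
    """Full delineation: local normalization → circular blur → sextiles."""
    p = params or SegmentationParams()
    normalized = normalize_local(image, p.norm_radius_um)
    smoothed = blur_circular(normalized, p.blur_radius_um)
    return quantile_partition(smoothed, p.n_quantiles, p.top_k, p.bottom_k)
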