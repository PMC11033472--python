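"""Core planar-image containers used throughout the pipeline.

All images live on a square pixel grid calibrated in micrometres.  The
coordinate convention is fixed package-wide: the origin sits at the centre
of the upper-left pixel, ``x`` runs along columns and ``y`` along rows, so a
point ``(x_um, y_um)`` corresponds to pixel ``(row, col) = (y/s, x/s)`` with
``s`` the pixel size in um.  Physical units are mandatory at every module
boundary; pixel indices never cross one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ModmapError(Exception):
    """Base class for all package errors."""


class ParameterError(ModmapError):
    """A parameter is outside its valid range (e.g. unresolvable radius)."""


@dataclass
class PlanarImage:
    """One fluorescence channel of a tangential section.

    Parameters
    ----------
    pixels : 2-D float array
        Non-negative intensities in arbitrary fluorescence units.
    pixel_size_um : float
        Physical size of one pixel (um / pixel), strictly positive.
    mask : 2-D bool array, optional
        Analysis region (valid tissue).  Defaults to the full frame.
    """

    pixels: np.ndarray
    pixel_size_um: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ParameterError(
                f"expected a single-channel 2-D image, got shape {self.pixels.shape}"
            )
        if not self.pixel_size_um > 0:
            raise ParameterError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ParameterError(
                    f"mask shape {self.mask.shape} != image shape {self.pixels.shape}"
                )
        vals = self.pixels[self.mask]
        if vals.size and (not np.all(np.isfinite(vals)) or vals.min() < 0):
            raise ParameterError("masked pixel values must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "PlanarImage":
        """Return a copy carrying new pixel values, same grid and mask."""
        return PlanarImage(pixels, self.pixel_size_um, self.mask.copy())

    def coords_um(self) -> tuple[np.ndarray, np.ndarray]:
        """(x_um, y_um) coordinate grids of pixel centres."""
        h, w = self.shape
        s = self.pixel_size_um
        y, x = np.mgrid[0:h, 0:w]
        return x * s, y * s


@dataclass
class ModuleMap:
    """Per-pixel intensity-quantile labels with derived patch/interpatch masks.

    ``quantile_label`` holds integers ``1..n_quantiles`` inside the analysis
    mask and 0 for background.  The top ``top_k`` quantiles form the patch
    mask (high-intensity modules), the bottom ``bottom_k`` the interpatch
    mask; anything in between is "middle" and excluded from two-class
    comparisons.
    """

    quantile_label: np.ndarray
    n_quantiles: int = 6
    top_k: int = 2
    bottom_k: int = 2
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.quantile_label = np.asarray(self.quantile_label, dtype=np.int16)
        if self.top_k + self.bottom_k > self.n_quantiles:
            raise ParameterError("top_k + bottom_k must not exceed n_quantiles")
        lab = self.quantile_label
        if lab.size and (lab.min() < 0 or lab.max() > self.n_quantiles):
            raise ParameterError("labels must lie in {0..n_quantiles}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.quantile_label.shape

    @property
    def mask(self) -> np.ndarray:
        return self.quantile_label > 0

    @property
    def patch_mask(self) -> np.ndarray:
        return self.quantile_label > self.n_quantiles - self.top_k

    @property
    def interpatch_mask(self) -> np.ndarray:
        lab = self.quantile_label
        return (lab >= 1) & (lab <= self.bottom_k)

    @property
    def middle_mask(self) -> np.ndarray:
        return self.mask & ~self.patch_mask & ~self.interpatch_mask

    def class_mask(self, name: str) -> np.ndarray:
        try:
            return {
                "patch": self.patch_mask,
                "interpatch": self.interpatch_mask,
                "middle": self.middle_mask,
            }[name]
        except KeyError:
            raise ParameterError(f"unknown module class {name!r}") from None


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


@dataclass
class InjectionSite:
    """Location and analysis geometry of a tracer injection.

    ``core_radius_um`` is the physical saturated-core radius used by the
    synthetic generator; ``core_exclusion_radius_um`` is the analysis-specific
    radius discounted around the centre (250 um for anterograde axon
    profiles, 300 um for retrograde point profiles).
    """

    center_xy_um: tuple[float, float]
    core_radius_um: float = 150.0
    core_exclusion_radius_um: float = 250.0
    saturation_quantile: float = 0.999

    def __post_init__(self) -> None:
        if not self.core_radius_um >= 0:
            raise ParameterError("core_radius_um must be >= 0")
        if not self.core_exclusion_radius_um >= 0:
            raise ParameterError("core_exclusion_radius_um must be >= 0")
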