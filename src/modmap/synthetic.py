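"""Synthetic flatmount scenes with known modular ground truth.

Real flatmount material for this analysis is not publicly deposited, so the
pipeline is validated on generated scenes that reproduce the statistical
structure the analysis assumes:

* a quasi-periodic patch/interpatch intensity field (band-pass-filtered
  Gaussian noise with a dominant spatial period of ~120 um, giving 4-8
  modules per ~260 x 360 um point image);
* a tracer injection with a saturated core disc and a surrounding halo;
* an anisotropic, distance-decaying axon density field whose preference for
  interpatches is a planted, tunable factor ``rho`` (ratio of interpatch to
  patch density at matched distance; ``rho = 1`` means no preference);
* inhomogeneous Poisson point sets (cell bodies, apical dendrites) sampled
  from module-biased densities;
* serial sections related to the reference frame by small projective
  distortions sharing exact landmark correspondences.

Every generator is a pure function of its parameters and seed; RNG streams
are split per sub-generator so, e.g., changing the landmark count does not
perturb the axon field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image import InjectionSite, ModuleMap, ParameterError, PlanarImage
from .registration import LandmarkSet, PlanarProjectiveTransform, transform_image
from .segmentation import quantile_partition

# Wavelength of the peak response of a difference-of-Gaussians band-pass with
# sigma2 = 2*sigma1 is pi*sqrt(6/ln 4)*sigma1 ~= 6.536*sigma1.
_DOG_PEAK_FACTOR = float(np.pi * np.sqrt(6.0 / np.log(4.0)))


@dataclass
class SceneParams:
    """Study conditions of one synthetic flatmount scene.

    Defaults emulate the tissue scale of the mouse V1 preparation: a
    2560 x 2560 um field at 5 um/pixel with a 120 um module period,
    a 46 nL-scale injection (300 um-wide saturated core) at the field
    centre, exponential axon-density decay over 500 um, anisotropy 1.4
    (long axis = elevation, here y), and multiplicative log-normal
    intensity speckle with sigma = 0.2.
    """

    field_size_um: tuple[float, float] = (2560.0, 2560.0)
    pixel_size_um: float = 5.0
    module_spacing_um: float = 120.0
    interpatch_preference_rho: float = 4.0
    anisotropy_a: float = 1.4
    decay_length_um: float = 500.0
    noise_sigma: float = 0.2
    core_radius_um: float = 150.0
    m2_contrast: float = 0.35
    expected_cells: int = 4000
    cell_interpatch_rho: float = 1.6
    expected_dendrites: int = 1000
    dendrite_interpatch_rho: float = 3.0


@dataclass
class SyntheticScene:
    seed: int
    params: SceneParams
    m2_field: np.ndarray               # latent continuous M2 surface (z-scored)
    m2_image: PlanarImage              # observed M2 channel (non-negative)
    gt_module_map: ModuleMap           # sextile partition of the latent field
    injection: InjectionSite
    axon_field: PlanarImage
    cell_points: pd.DataFrame          # x_um, y_um, section_index, kind, layer
    dendrite_points: pd.DataFrame

    @property
    def pixel_size_um(self) -> float:
        return self.params.pixel_size_um

    @property
    def field_size_um(self) -> tuple[float, float]:
        return self.params.field_size_um


def _grid_shape(field_size_um: tuple[float, float], pixel_size_um: float) -> tuple[int, int]:
    w_um, h_um = field_size_um
    return (int(round(h_um / pixel_size_um)), int(round(w_um / pixel_size_um)))


def generate_module_field(
    seed: int | np.random.SeedSequence,
    field_size_um: tuple[float, float] = (2560.0, 2560.0),
    pixel_size_um: float = 5.0,
    module_spacing_um: float = 120.0,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, ModuleMap]:
    """Latent quasi-periodic module field and its ground-truth sextile map.

    White Gaussian noise is band-pass filtered with a difference of
    Gaussians (sigma2 = 2*sigma1) whose peak response sits at
    ``module_spacing_um``, then z-scored within the mask.  The ground-truth
    module map is the sextile partition of the resulting field.
    """
    if module_spacing_um <= 2 * pixel_size_um:
        raise ParameterError(
            f"module spacing {module_spacing_um} um is not resolvable at "
            f"{pixel_size_um} um/pixel"
        )
    shape = _grid_shape(field_size_um, pixel_size_um)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    elif mask.shape != shape:
        raise ParameterError(f"mask shape {mask.shape} != field shape {shape}")
    if not mask.any():
        raise ParameterError("analysis mask is empty")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    sigma1 = module_spacing_um / _DOG_PEAK_FACTOR / pixel_size_um
    fld = gaussian_filter(noise, sigma1) - gaussian_filter(noise, 2.0 * sigma1)
    mu, sd = fld[mask].mean(), fld[mask].std()
    fld = (fld - mu) / sd
    fld[~mask] = 0.0
    ranks = PlanarImage(fld - fld.min(), pixel_size_um, mask)
    gt = quantile_partition(ranks, n_quantiles=6, top_k=2, bottom_k=2)
    return fld, gt


def _elliptical_distance(
    shape: tuple[int, int],
    pixel_size_um: float,
    center_xy_um: tuple[float, float],
    anisotropy_a: float,
) -> np.ndarray:
    """Elliptical distance from the centre; long axis along y (elevation)."""
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    u = x * pixel_size_um - center_xy_um[0]
    v = y * pixel_size_um - center_xy_um[1]
    return np.hypot(u, v / anisotropy_a)


def generate_axon_field(
    gt_module_map: ModuleMap,
    injection: InjectionSite,
    rho: float,
    anisotropy_a: float = 1.0,
    decay_length_um: float = 500.0,
    seed: int | np.random.SeedSequence = 0,
    noise_sigma: float = 0.0,
) -> PlanarImage:
    """Planted axon-projection density field.

    ``field = exp(-d_aniso / decay) * (1 + (rho - 1) * [interpatch])``
    times unit-mean log-normal speckle, with the saturated injection core
    overwriting a disc of ``injection.core_radius_um``.
    """
    if rho < 0:
        raise ParameterError("interpatch preference rho must be >= 0")
    if anisotropy_a < 1:
        raise ParameterError("anisotropy_a must be >= 1 (long/short axis ratio)")
    if decay_length_um <= 0:
        raise ParameterError("decay_length_um must be > 0")
    shape = gt_module_map.shape
    s = gt_module_map.pixel_size_um
    cx, cy = injection.center_xy_um
    h, w = shape
    if not (0 <= cx <= (w - 1) * s and 0 <= cy <= (h - 1) * s):
        raise ParameterError(
            f"injection centre {injection.center_xy_um} lies outside the field"
        )
    d = _elliptical_distance(shape, s, injection.center_xy_um, anisotropy_a)
    fld = np.exp(-d / decay_length_um)
    fld *= 1.0 + (rho - 1.0) * gt_module_map.interpatch_mask
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(shape)
        fld *= np.exp(noise_sigma * z - 0.5 * noise_sigma**2)
    if injection.core_radius_um > 0:
        y, x = np.mgrid[0:h, 0:w]
        core = np.hypot(x * s - cx, y * s - cy) <= injection.core_radius_um
        fld[core] = 2.0 * max(rho, 1.0)  # saturated, structureless core
    fld[~gt_module_map.mask] = 0.0
    return PlanarImage(fld, s, gt_module_map.mask)


def sample_points(
    density_field: PlanarImage,
    expected_n: float,
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Inhomogeneous Poisson point sample by thinning against the maximum.

    The density field (piecewise constant over pixels) is rescaled so its
    integral equals ``expected_n``; candidate points are drawn uniformly
    over the field at the maximum rate and thinned by the local relative
    density, which yields an exact inhomogeneous Poisson sample with
    continuous um coordinates and realized count ~ Poisson(expected_n).
    """
    if expected_n <= 0:
        raise ParameterError("expected_n must be > 0")
    lam = np.where(density_field.mask, density_field.pixels, 0.0)
    total = lam.sum()
    if total <= 0:
        raise ParameterError("density field is identically zero inside the mask")
    s = density_field.pixel_size_um
    h, w = density_field.shape
    area = (w * s) * (h * s)
    # per-um^2 rate with integral expected_n
    rate = lam * (expected_n / (total * s * s))
    rate_max = rate.max()
    rng = np.random.default_rng(seed)
    n_cand = rng.poisson(rate_max * area)
    if n_cand == 0:
        return pd.DataFrame({"x_um": [], "y_um": []}, dtype=float)
    x = rng.uniform(-0.5 * s, (w - 0.5) * s, n_cand)
    y = rng.uniform(-0.5 * s, (h - 0.5) * s, n_cand)
    col = np.clip(np.rint(x / s).astype(int), 0, w - 1)
    row = np.clip(np.rint(y / s).astype(int), 0, h - 1)
    keep = rng.uniform(0.0, 1.0, n_cand) < rate[row, col] / rate_max
    return pd.DataFrame({"x_um": x[keep], "y_um": y[keep]})


def _point_table(
    density: PlanarImage,
    expected_n: float,
    kind: str,
    section_weights: dict[int, float],
    layer_of: dict[int, str],
    seed: np.random.SeedSequence,
) -> pd.DataFrame:
    pts_seed, sect_seed = seed.spawn(2)
    pts = sample_points(density, expected_n, pts_seed)
    rng = np.random.default_rng(sect_seed)
    sections = np.array(sorted(section_weights))
    wts = np.array([section_weights[k] for k in sections], float)
    wts /= wts.sum()
    idx = rng.choice(sections, size=len(pts), p=wts)
    pts["section_index"] = idx
    pts["kind"] = kind
    pts["layer"] = [layer_of[k] for k in idx]
    return pts


def generate_scene(
    seed: int, params: SceneParams | None = None
) -> SyntheticScene:
    """Build a complete ground-truth scene from one integer seed."""
    p = params or SceneParams()
    ss = np.random.SeedSequence(seed)
    field_ss, axon_ss, cell_ss, dend_ss = ss.spawn(4)

    m2_field, gt = generate_module_field(
        field_ss, p.field_size_um, p.pixel_size_um, p.module_spacing_um
    )
    # observed M2 channel: positive affine rendering of the latent field
    m2_image = PlanarImage(
        np.clip(1.0 + p.m2_contrast * m2_field, 0.0, None),
        p.pixel_size_um,
        gt.mask,
    )
    w_um, h_um = p.field_size_um
    injection = InjectionSite(
        center_xy_um=(w_um / 2.0, h_um / 2.0), core_radius_um=p.core_radius_um
    )
    axon_field = generate_axon_field(
        gt,
        injection,
        p.interpatch_preference_rho,
        p.anisotropy_a,
        p.decay_length_um,
        axon_ss,
        p.noise_sigma,
    )

    from .registration import LayerAssignment  # local to avoid cycle at import

    layers = LayerAssignment()
    layer_of = {k: layers.assign(k) for k in range(1, 17)}
    cell_density = generate_axon_field(
        gt,
        replace(injection, core_radius_um=0.0),
        p.cell_interpatch_rho,
        p.anisotropy_a,
        p.decay_length_um,
        cell_ss,
        0.0,
    )
    # retrogradely labeled somata sit in L2-6 (sections 3-16), weighted to L2/3
    cell_sections = {k: (3.0 if k <= 7 else (2.0 if k <= 12 else 1.0)) for k in range(3, 17)}
    cell_points = _point_table(
        cell_density, p.expected_cells, "cell_body", cell_sections, layer_of, cell_ss.spawn(1)[0]
    )
    dend_density = generate_axon_field(
        gt,
        replace(injection, core_radius_um=0.0),
        p.dendrite_interpatch_rho,
        p.anisotropy_a,
        p.decay_length_um,
        dend_ss,
        0.0,
    )
    dendrite_points = _point_table(
        dend_density, p.expected_dendrites, "apical_dendrite",
        {1: 1.0, 2: 1.0}, layer_of, dend_ss.spawn(1)[0]
    )
    return SyntheticScene(
        seed=seed,
        params=p,
        m2_field=m2_field,
        m2_image=m2_image,
        gt_module_map=gt,
        injection=injection,
        axon_field=axon_field,
        cell_points=cell_points,
        dendrite_points=dendrite_points,
    )


@dataclass
class SerialStack:
    """Per-section images, landmark pairs and the generating transforms."""

    section_images: dict[int, PlanarImage]
    landmarks: dict[int, LandmarkSet]
    true_transforms: dict[int, PlanarProjectiveTransform]


def _random_homography(
    field_size_um: tuple[float, float],
    distortion_scale_um: float,
    rng: np.random.Generator,
) -> PlanarProjectiveTransform:
    """Small projective perturbation of the identity.

    Built by displacing the four field corners by Gaussian offsets of the
    given scale and fitting the (exact) four-point homography.
    """
    if distortion_scale_um == 0:
        return PlanarProjectiveTransform.identity()
    w, h = field_size_um
    corners = np.array([[0.0, 0.0], [w, 0.0], [0.0, h], [w, h]])
    moved = corners + rng.normal(0.0, distortion_scale_um, corners.shape)
    from .registration import estimate_homography_matrix

    return PlanarProjectiveTransform(estimate_homography_matrix(corners, moved))


def generate_serial_stack(
    scene: SyntheticScene,
    n_sections: int = 4,
    landmark_count: int = 8,
    distortion_scale_um: float = 5.0,
    seed: int | np.random.SeedSequence = 0,
    deep_amplitude: float = 0.5,
) -> SerialStack:
    """Serial sections distorted by known homographies, with shared landmarks.

    Section k carries a known transform ``T_k`` (reference -> section
    frame).  Sections 1-2 (L1) show the modular axon field; deeper sections
    show a non-modular (rho = 1) field at reduced amplitude, matching the
    weaker, unclustered deep-layer projections.  Landmark tables are exact
    correspondences under ``T_k``, emulating blood-vessel landmarks.
    """
    if n_sections < 1:
        raise ParameterError("n_sections must be >= 1")
    if landmark_count < 4:
        raise ParameterError(
            "landmark_count must be >= 4 (projective fit is underdetermined)"
        )
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    geom_ss, deep_ss = ss.spawn(2)
    rng = np.random.default_rng(geom_ss)
    deep_field = generate_axon_field(
        scene.gt_module_map,
        scene.injection,
        1.0,
        scene.params.anisotropy_a,
        scene.params.decay_length_um,
        deep_ss,
        scene.params.noise_sigma,
    )
    w, h = scene.field_size_um
    images: dict[int, PlanarImage] = {}
    marks: dict[int, LandmarkSet] = {}
    truths: dict[int, PlanarProjectiveTransform] = {}
    for k in range(1, n_sections + 1):
        t_k = _random_homography(scene.field_size_um, distortion_scale_um, rng)
        base = scene.axon_field if k <= 2 else deep_field
        img = transform_image(t_k, base, order=1)
        if k > 2:
            img = img.with_pixels(img.pixels * deep_amplitude)
        ref = np.column_stack(
            [rng.uniform(0.1 * w, 0.9 * w, landmark_count),
             rng.uniform(0.1 * h, 0.9 * h, landmark_count)]
        )
        marks[k] = LandmarkSet(ref, t_k.apply(ref), section_index=k)
        truths[k] = t_k
        images[k] = img
    return SerialStack(images, marks, truths)
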