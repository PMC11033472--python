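"""End-to-end orchestration: segment → align → propagate → quantify → compare.

Two entry points:

* :func:`analyze_scene` / :func:`run_study` operate on in-memory synthetic
  scenes and are what the validation studies (calibration, power, parameter
  recovery) run;
* :func:`run_directory_pipeline` chains the file-based stages the CLI
  exposes on a run directory produced by ``modmap simulate`` (or by
  arranging real data in the same layout).

Statistical design: the KS comparison uses ROI-level mean optical densities
as sampling units — one patch sample and one interpatch sample, pooled over
ROIs and subjects.  Patch and interpatch values are taken from disjoint
ROIs so the two samples are independent, as the two-sample KS test assumes;
within an ROI the two class means would share acquisition noise and local
normalization discs and be positively correlated.  The axon signal is
passed through the same local-mean normalization used for delineation
("high-pass") before densities are measured, which removes the injection's
radial decay so ROIs at different distances are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .image import InjectionSite, ModmapError, ModuleMap, PlanarImage, dice_coefficient
from .io import QuantificationParams, write_json
from .quantify import (
    ComparisonResult,
    RadialProfile,
    RoiSpec,
    anisotropy_aspect_ratio,
    detect_injection_center,
    estimate_interpatch_preference,
    ks_compare,
    point_module_density,
    radial_density_profile,
    ring_rois,
    roi_class_means,
    roi_quantile_density,
)
from .segmentation import SegmentationParams, blur_circular, delineate_modules, normalize_local
from .synthetic import SceneParams, SyntheticScene, generate_scene


class StageDependencyError(ModmapError):
    """A pipeline stage is missing the artifacts of an earlier stage."""


#: Desk-scale study conditions for the large simulation studies
#: (calibration and power need thousands of scenes): a quarter-size field
#: at half resolution, with ROIs and ring radius scaled to match.
REDUCED_SCENE = SceneParams(
    field_size_um=(1280.0, 1280.0),
    pixel_size_um=10.0,
    core_radius_um=80.0,
)

REDUCED_QUANT = QuantificationParams(
    roi_width_um=275.0,
    roi_height_um=200.0,
    roi_ring_radius_um=400.0,
    axon_exclusion_radius_um=150.0,
    point_exclusion_radius_um=150.0,
)


def filtered_signal(
    signal: PlanarImage, seg: SegmentationParams | None = None
) -> PlanarImage:
    """High-pass (local-mean division) and blur the density signal."""
    p = seg or SegmentationParams()
    return blur_circular(normalize_local(signal, p.norm_radius_um), p.blur_radius_um)


def class_rois(
    injection: InjectionSite,
    quant: QuantificationParams,
    phase_deg: float = 90.0,
    assignment_seed: int | None = None,
) -> dict[str, list[RoiSpec]]:
    """Disjoint ROI sets for the patch and interpatch samples.

    ``2 * rois_per_class`` ROIs are placed on a ring around the injection
    centre.  When ``assignment_seed`` is given, which ROIs feed the patch
    sample and which the interpatch sample is randomized (deterministically
    per seed); otherwise they alternate.  Randomized assignment matters for
    calibration: the decay field is anisotropic, so ROI position carries a
    small deterministic bias, and a fixed alternating assignment would feed
    the identical bias multiset to both samples, coupling them.
    """
    all_rois = ring_rois(
        injection,
        n_rois=2 * quant.rois_per_class,
        ring_radius_um=quant.roi_ring_radius_um,
        width_um=quant.roi_width_um,
        height_um=quant.roi_height_um,
        phase_deg=phase_deg,
    )
    idx = np.arange(len(all_rois))
    if assignment_seed is not None:
        idx = np.random.default_rng(assignment_seed).permutation(idx)
    return {
        "patch": [all_rois[i] for i in idx[0::2]],
        "interpatch": [all_rois[i] for i in idx[1::2]],
    }


@dataclass
class SceneReport:
    """Per-scene (per-subject) analysis products."""

    module_map: ModuleMap
    injection: InjectionSite
    patch_sample: np.ndarray            # per-ROI patch mean optical densities
    interpatch_sample: np.ndarray
    profile: RadialProfile
    rho_hat: float
    quantile_table: pd.DataFrame
    dice_vs_truth: float | None = None


def analyze_scene(
    scene: SyntheticScene,
    seg: SegmentationParams | None = None,
    quant: QuantificationParams | None = None,
    module_map: ModuleMap | None = None,
) -> SceneReport:
    """Run segmentation and quantification on one scene.

    ``module_map`` may be supplied to quantify against a precomputed (e.g.
    ground-truth) map; by default the M2 image is delineated from scratch.
    """
    seg = seg or SegmentationParams()
    quant = quant or QuantificationParams()
    if module_map is None:
        module_map = delineate_modules(scene.m2_image, seg)
    injection = detect_injection_center(
        scene.axon_field, scene.injection.saturation_quantile
    )
    injection = replace(
        injection,
        core_radius_um=scene.injection.core_radius_um,
        core_exclusion_radius_um=quant.axon_exclusion_radius_um,
    )
    signal = (
        filtered_signal(scene.axon_field, seg) if quant.filter_signal
        else scene.axon_field
    )
    rois = class_rois(injection, quant, assignment_seed=scene.seed)
    patch_means = roi_class_means(signal, module_map, rois["patch"])["patch"]
    inter_means = roi_class_means(signal, module_map, rois["interpatch"])["interpatch"]
    profile = radial_density_profile(
        module_map,
        injection,
        signal=scene.axon_field,
        bin_width_um=quant.bin_width_um,
        exclusion_radius_um=quant.axon_exclusion_radius_um,
    )
    qtable = roi_quantile_density(
        signal, module_map, rois["patch"] + rois["interpatch"]
    )
    return SceneReport(
        module_map=module_map,
        injection=injection,
        patch_sample=patch_means.to_numpy(float),
        interpatch_sample=inter_means.to_numpy(float),
        profile=profile,
        rho_hat=estimate_interpatch_preference(profile),
        quantile_table=qtable,
        dice_vs_truth=dice_coefficient(
            module_map.patch_mask, scene.gt_module_map.patch_mask
        ),
    )


@dataclass
class StudyDesign:
    """A simulated multi-subject study (defaults follow the tissue study:
    4 subjects, 3 ROIs per class each, alpha = 0.05)."""

    scene: SceneParams = field(default_factory=SceneParams)
    n_subjects: int = 4
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    quant: QuantificationParams = field(default_factory=QuantificationParams)
    use_ground_truth_map: bool = False


@dataclass
class StudyResult:
    comparison: ComparisonResult
    patch_sample: np.ndarray
    interpatch_sample: np.ndarray
    rho_hats: list[float]
    dice: list[float]


def run_study(seed: int, design: StudyDesign | None = None) -> StudyResult:
    """Simulate one multi-subject study and pool the KS comparison.

    Subject scenes are generated from seeds split off the study seed; each
    contributes its per-ROI class means to the pooled patch and interpatch
    samples.
    """
    d = design or StudyDesign()
    subject_seeds = np.random.SeedSequence(seed).generate_state(d.n_subjects) % (2**31)
    patch, inter, rho_hats, dice = [], [], [], []
    for s in subject_seeds:
        scene = generate_scene(int(s), d.scene)
        report = analyze_scene(
            scene,
            d.seg,
            d.quant,
            module_map=scene.gt_module_map if d.use_ground_truth_map else None,
        )
        patch.append(report.patch_sample)
        inter.append(report.interpatch_sample)
        rho_hats.append(report.rho_hat)
        dice.append(report.dice_vs_truth)
    patch_all = np.concatenate(patch)
    inter_all = np.concatenate(inter)
    return StudyResult(
        comparison=ks_compare(patch_all, inter_all, d.quant.alpha),
        patch_sample=patch_all,
        interpatch_sample=inter_all,
        rho_hats=rho_hats,
        dice=dice,
    )


# ---------------------------------------------------------------------------
# file-based chain (CLI stages operate on a run directory)


def run_directory_pipeline(run_dir: str | Path, config=None) -> dict:
    """Chain segment → align → propagate → quantify on a run directory.

    The directory must contain ``modmap simulate`` outputs (m2.tif,
    section_*.tif, landmarks.csv, points.csv, scene.yaml).  Results land in
    ``segment/``, ``align/`` and ``quantify/`` subdirectories; the returned
    dict summarizes the quantification.  Raises
    :class:`StageDependencyError` when inputs are missing.
    """
    from .cli import align_directory, quantify_directory, segment_directory

    run_dir = Path(run_dir)
    if not (run_dir / "m2.tif").exists():
        raise StageDependencyError(
            f"{run_dir} does not contain simulate artifacts (m2.tif missing)"
        )
    segment_directory(run_dir)
    align_directory(run_dir)
    report = quantify_directory(run_dir)
    write_json(run_dir / "quantify" / "report.json", report)
    return report
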