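"""File interchange: grayscale TIFF, CSV point/landmark tables, YAML config.

All interchange coordinates are physical micrometres; pixel indices never
cross a file boundary.  Pixel size comes from the config when given, else
from the TIFF resolution tags; on conflict the config wins and a warning is
logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .image import ModmapError, ParameterError, PlanarImage
from .registration import DEFAULT_LAYER_TABLE, LandmarkSet
from .segmentation import SegmentationParams

logger = logging.getLogger("modmap")

POINT_COLUMNS = ["x_um", "y_um", "section_index", "kind"]
LANDMARK_COLUMNS = ["section_index", "x_ref_um", "y_ref_um", "x_sec_um", "y_sec_um"]


class FileFormatError(ModmapError):
    """An interchange file violates its declared schema."""


# ---------------------------------------------------------------------------
# images


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    px_per_unit = num / den
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))
    if unit_um is None:
        return None
    return unit_um / px_per_unit


def read_image(
    path: str | Path,
    pixel_size_um: float | None = None,
    mask_path: str | Path | None = None,
) -> PlanarImage:
    """Read a single-channel grayscale TIFF as a :class:`PlanarImage`.

    ``pixel_size_um`` (config) takes precedence over the file's resolution
    tags; a mismatch is logged as a warning.  A companion mask TIFF
    (nonzero = valid) is optional; the default mask is the full frame.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        tag_px = _pixel_size_from_tags(tif)
    if data.ndim != 2:
        raise FileFormatError(
            f"{path}: expected a single-channel grayscale image, got shape "
            f"{data.shape}; multi-channel/RGB input is not supported"
        )
    if pixel_size_um is not None:
        if tag_px is not None and not np.isclose(tag_px, pixel_size_um, rtol=1e-3):
            logger.warning(
                "%s: resolution tag says %.4g um/px but config says %.4g um/px; "
                "using the config value",
                path, tag_px, pixel_size_um,
            )
        px = pixel_size_um
    elif tag_px is not None:
        px = tag_px
    else:
        raise FileFormatError(
            f"{path}: no resolution tags and no pixel size supplied"
        )
    mask = None
    if mask_path is not None:
        mask = tifffile.imread(str(mask_path)) > 0
    return PlanarImage(np.asarray(data, dtype=np.float64), px, mask)


def write_image(
    path: str | Path, image: PlanarImage, dtype: str = "float32"
) -> None:
    """Write a grayscale TIFF with resolution tags in pixels/cm."""
    data = image.pixels
    if dtype in ("uint8", "uint16"):
        info = np.iinfo(dtype)
        if data.max() > info.max or np.any(data != np.round(data)):
            raise ParameterError(
                f"cannot losslessly store values in {dtype}; scale or use float32"
            )
        data = data.astype(dtype)
    else:
        data = data.astype(np.float32)
    px_per_cm = 10000.0 / image.pixel_size_um
    tifffile.imwrite(
        str(path),
        data,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def write_labels(path: str | Path, labels: np.ndarray, pixel_size_um: float) -> None:
    """Write a label image (0 = background) as uint8 TIFF."""
    img = PlanarImage(labels.astype(np.float64), pixel_size_um)
    write_image(path, img, dtype="uint8")


# ---------------------------------------------------------------------------
# tables


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing required column(s) {missing}")
    for col in required:
        if col in ("kind",):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = list(df.index[bad][:5])
            raise FileFormatError(
                f"{path}: non-numeric value(s) in column {col!r} at row(s) {rows}"
            )
        df[col] = coerced
    return df


def read_points(path: str | Path) -> pd.DataFrame:
    """Read a labeled point table (x_um, y_um, section_index, kind, ...).

    Unknown columns are preserved as opaque annotations.
    """
    df = _read_table(path, POINT_COLUMNS)
    df["section_index"] = df["section_index"].astype(int)
    return df


def write_points(path: str | Path, points: pd.DataFrame) -> None:
    missing = [c for c in POINT_COLUMNS if c not in points.columns]
    if missing:
        raise FileFormatError(f"points table missing column(s) {missing}")
    ordered = POINT_COLUMNS + [c for c in points.columns if c not in POINT_COLUMNS]
    points[ordered].to_csv(path, index=False)


def read_landmarks(path: str | Path) -> dict[int, LandmarkSet]:
    """Read landmark correspondences, one :class:`LandmarkSet` per section."""
    df = _read_table(path, LANDMARK_COLUMNS)
    out: dict[int, LandmarkSet] = {}
    for k, grp in df.groupby("section_index"):
        out[int(k)] = LandmarkSet(
            grp[["x_ref_um", "y_ref_um"]].to_numpy(float),
            grp[["x_sec_um", "y_sec_um"]].to_numpy(float),
            section_index=int(k),
        )
    return out


def write_landmarks(path: str | Path, landmarks: dict[int, LandmarkSet]) -> None:
    rows = []
    for k in sorted(landmarks):
        lm = landmarks[k]
        for (xr, yr), (xs, ys) in zip(lm.reference_xy_um, lm.section_xy_um):
            rows.append(
                {"section_index": k, "x_ref_um": xr, "y_ref_um": yr,
                 "x_sec_um": xs, "y_sec_um": ys}
            )
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# config

SCHEMA_VERSION = 1


@dataclass
class QuantificationParams:
    """Analysis radii, binning and test level (all lengths in um)."""

    bin_width_um: float = 50.0
    axon_exclusion_radius_um: float = 250.0
    point_exclusion_radius_um: float = 300.0
    alpha: float = 0.05
    roi_width_um: float = 550.0
    roi_height_um: float = 400.0
    rois_per_class: int = 3
    roi_ring_radius_um: float = 700.0
    filter_signal: bool = True
    anisotropy_threshold_quantile: float = 0.9


@dataclass
class RunConfig:
    """Validated run configuration for the file-based pipeline."""

    run_dir: str
    seed: int = 0
    pixel_size_um: float | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    quantification: QuantificationParams = field(default_factory=QuantificationParams)
    layer_table: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_TABLE)
    )
    schema_version: int = SCHEMA_VERSION


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if raw.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise FileFormatError(
            f"{path}: unsupported schema_version {raw.get('schema_version')}"
        )
    kwargs = dict(raw)
    kwargs.pop("schema_version", None)
    if "segmentation" in kwargs:
        kwargs["segmentation"] = SegmentationParams(**kwargs["segmentation"])
    if "quantification" in kwargs:
        kwargs["quantification"] = QuantificationParams(**kwargs["quantification"])
    if "layer_table" in kwargs:
        kwargs["layer_table"] = {
            k: tuple(v) for k, v in kwargs["layer_table"].items()
        }
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise FileFormatError(f"{path}: {exc}") from None


def save_config(path: str | Path, config: RunConfig) -> None:
    data = asdict(config)
    data["layer_table"] = {k: list(v) for k, v in data["layer_table"].items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# provenance


def write_json(path: str | Path, payload: dict) -> None:
    """Deterministic JSON (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(run_dir: str | Path, seed: int, extra: dict | None = None) -> Path:
    """Record config hash, seeds and tool version for exact re-creation."""
    from . import __version__

    run_dir = Path(run_dir)
    files = sorted(
        p for p in run_dir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    payload = {
        "tool": "modmap",
        "version": __version__,
        "seed": seed,
        "files": {str(p.relative_to(run_dir)): file_sha256(p) for p in files},
    }
    if extra:
        payload.update(extra)
    out = run_dir / "manifest.json"
    write_json(out, payload)
    return out
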