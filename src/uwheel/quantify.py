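"""Fluorescence-scan quantification of targeting efficiency.

Pipeline: threshold both 16-bit scans to strip background (pixels below
the cutoff, default 3600, are zeroed), optionally calibrate beads per
intensity count from a manual-count image, then divide the post-targeting
intensity inside the target ROI by the total pre-targeting intensity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import CalibrationError, ScanFormatError, UWheelError

__all__ = [
    "DEFAULT_CUTOFF",
    "FluorescenceScan",
    "RoiSet",
    "QuantifyResult",
    "read_scan",
    "write_scan",
    "threshold_scan",
    "beads_per_count",
    "targeting_efficiency_from_scans",
]

#: Default background threshold (16-bit counts).
DEFAULT_CUTOFF = 3600


@dataclass
class FluorescenceScan:
    """A single-plane 16-bit grayscale raster."""

    pixels: np.ndarray
    pixel_size: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.pixels = _check_raster(self.pixels)

    @property
    def total_intensity(self) -> float:
        return float(self.pixels.sum(dtype=np.float64))


def _check_raster(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ScanFormatError("scan must be a single 2-D plane")
    if arr.dtype != np.uint16:
        raise ScanFormatError(
            f"scan must be 16-bit unsigned (uint16), got {arr.dtype}"
        )
    return arr


def read_scan(path: str | Path, label: str | None = None) -> FluorescenceScan:
    """Read a 16-bit grayscale TIFF."""
    return FluorescenceScan(pixels=tifffile.imread(str(path)), label=label)


def write_scan(scan: FluorescenceScan, path: str | Path) -> None:
    tifffile.imwrite(str(path), scan.pixels)


def threshold_scan(
    scan: FluorescenceScan | np.ndarray, cutoff: int = DEFAULT_CUTOFF
) -> FluorescenceScan:
    """Zero every pixel with intensity strictly below ``cutoff``.

    Pixels at or above the cutoff pass through unchanged; the operation
    is idempotent.
    """
    pixels = scan.pixels if isinstance(scan, FluorescenceScan) else scan
    pixels = _check_raster(pixels)
    out = np.where(pixels < cutoff, np.uint16(0), pixels)
    meta = scan if isinstance(scan, FluorescenceScan) else None
    return FluorescenceScan(
        pixels=out,
        pixel_size=meta.pixel_size if meta else None,
        label=meta.label if meta else None,
    )


def beads_per_count(
    calibration: FluorescenceScan | np.ndarray,
    manual_bead_count: int,
    cutoff: int = DEFAULT_CUTOFF,
) -> float:
    """Beads per intensity unit from a manually counted calibration image."""
    if manual_bead_count <= 0:
        raise CalibrationError("manual bead count must be > 0")
    total = threshold_scan(calibration, cutoff).total_intensity
    if total <= 0:
        raise CalibrationError("no post-threshold signal in calibration image")
    return manual_bead_count / total


@dataclass
class RoiSet:
    """Named boolean masks, one per branch, matching the scan shape."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = set()
        for name, mask in self.masks.items():
            mask = np.asarray(mask)
            if mask.dtype != bool:
                raise ScanFormatError(f"ROI '{name}' mask must be boolean")
            self.masks[name] = mask
            shapes.add(mask.shape)
        if len(shapes) > 1:
            raise ScanFormatError("ROI masks have mismatched shapes")

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)

    # -------- run-length JSON round trip (text-friendly on disk) --------
    def to_json(self, path: str | Path) -> None:
        payload = {}
        for name, mask in self.masks.items():
            runs = []
            for row in range(mask.shape[0]):
                line = np.concatenate(([False], mask[row], [False]))
                edges = np.flatnonzero(np.diff(line.astype(np.int8)))
                for start, stop in zip(edges[::2], edges[1::2]):
                    runs.append([row, int(start), int(stop)])
            payload[name] = {"shape": list(mask.shape), "runs": runs}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiSet":
        payload = json.loads(Path(path).read_text())
        masks = {}
        for name, spec in payload.items():
            mask = np.zeros(tuple(spec["shape"]), dtype=bool)
            for row, start, stop in spec["runs"]:
                mask[row, start:stop] = True
            masks[name] = mask
        return cls(masks=masks)

    @classmethod
    def from_mask_dir(cls, directory: str | Path) -> "RoiSet":
        """Load binary TIFF masks named ``<branch>.tif`` from a directory."""
        masks = {}
        for p in sorted(Path(directory).glob("*.tif*")):
            masks[p.stem] = tifffile.imread(str(p)) > 0
        if not masks:
            raise ScanFormatError(f"no TIFF masks found in {directory}")
        return cls(masks=masks)


@dataclass(frozen=True)
class QuantifyResult:
    """Targeting efficiency plus the per-branch breakdown."""

    efficiency: float
    per_branch: dict[str, float]
    pre_total: float
    post_total: float

    @property
    def efficiency_clamped(self) -> float:
        """Report-friendly value clamped to [0, 1]; raw value preserved."""
        return min(max(self.efficiency, 0.0), 1.0)


def targeting_efficiency_from_scans(
    pre: FluorescenceScan,
    post: FluorescenceScan,
    rois: RoiSet,
    target: str,
    cutoff: int = DEFAULT_CUTOFF,
) -> QuantifyResult:
    """Target-ROI post intensity divided by total pre intensity.

    Both scans are thresholded first.  Per-branch fractions use the same
    pre-scan denominator, so over a full partition of the signal they sum
    to (post total)/(pre total).
    """
    if pre.pixels.shape != post.pixels.shape:
        raise ScanFormatError("pre and post scans must have identical shapes")
    if target not in rois:
        raise UWheelError(f"target ROI '{target}' not present in ROI set")
    pre_t = threshold_scan(pre, cutoff)
    post_t = threshold_scan(post, cutoff)
    for name, mask in rois.masks.items():
        if mask.shape != pre.pixels.shape:
            raise ScanFormatError(f"ROI '{name}' shape does not match scans")
    pre_total = pre_t.total_intensity
    if pre_total <= 0:
        raise CalibrationError(
            "undefined efficiency: pre-targeting scan has no signal"
        )
    post64 = post_t.pixels.astype(np.float64)
    per_branch = {
        name: float(post64[mask].sum()) / pre_total
        for name, mask in rois.masks.items()
    }
    return QuantifyResult(
        efficiency=per_branch[target],
        per_branch=per_branch,
        pre_total=pre_total,
        post_total=post_t.total_intensity,
    )
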