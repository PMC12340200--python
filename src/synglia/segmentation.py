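"""Per-channel 3D segmentation of intensity stacks into binary masks."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .image_io import ImageStack, canonical_channel_name

__all__ = [
    "SegmentationConfig",
    "BinaryMask",
    "DegenerateChannelError",
    "segment_channel",
    "segment_stack",
    "qc_negative_control",
    "QCReport",
    "export_mask",
]


class DegenerateChannelError(ValueError):
    """Raised when a data-driven threshold is requested on a flat channel."""


@dataclass(frozen=True)
class SegmentationConfig:
    """How to binarize a channel.

    ``method`` is one of ``otsu`` (parameter-free default), ``fixed``
    (absolute intensity threshold) or ``percentile`` (per-stack intensity
    percentile).  Connected components smaller than ``min_object_voxels``
    under the configured 3D connectivity are removed afterwards; the
    default applies no size filter.
    """

    method: str = "otsu"
    fixed_threshold: float | None = None
    percentile: float | None = None
    min_object_voxels: int = 0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "fixed", "percentile"):
            raise ValueError(f"unknown segmentation method {self.method!r}")
        if self.method == "fixed" and self.fixed_threshold is None:
            raise ValueError("method 'fixed' requires fixed_threshold")
        if self.method == "percentile":
            if self.percentile is None or not 0 < self.percentile < 100:
                raise ValueError("percentile must be in (0, 100)")
        if self.min_object_voxels < 0:
            raise ValueError("min_object_voxels must be >= 0")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


@dataclass
class BinaryMask:
    """A channel's segmentation result plus an audit record of how it was
    produced."""

    mask: np.ndarray
    channel_name: str
    method_record: dict

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")


def resolve_threshold(data: np.ndarray, config: SegmentationConfig) -> float:
    if config.method == "fixed":
        return float(config.fixed_threshold)
    if np.ptp(data) == 0:
        raise DegenerateChannelError(
            f"channel is constant (value {float(data.flat[0])}); a "
            f"data-driven {config.method!r} threshold is undefined"
        )
    if config.method == "otsu":
        return float(threshold_otsu(np.asarray(data, dtype=float)))
    return float(np.percentile(data, config.percentile))


def _remove_small(mask: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    if config.min_object_voxels <= 0 or not mask.any():
        return mask
    # skimage connectivity: 1 = faces only (6-neighbour), 3 = full (26).
    # max_size removes components of size <= value, so subtract one to drop
    # only components strictly smaller than min_object_voxels.
    conn = 1 if config.connectivity == 6 else 3
    return remove_small_objects(
        mask, max_size=config.min_object_voxels - 1, connectivity=conn
    )


def segment_channel(
    stack: ImageStack, channel: str, config: SegmentationConfig | None = None
) -> BinaryMask:
    """Threshold one channel (strictly above the resolved threshold) and
    drop connected components smaller than ``min_object_voxels``."""
    config = config or SegmentationConfig()
    data = stack.channel(channel)
    threshold = resolve_threshold(data, config)
    mask = data > threshold
    mask = _remove_small(mask, config)
    return BinaryMask(
        mask=mask,
        channel_name=canonical_channel_name(channel),
        method_record={
            "method": config.method,
            "threshold": threshold,
            "min_object_voxels": config.min_object_voxels,
            "connectivity": config.connectivity,
        },
    )


def segment_stack(
    stack: ImageStack,
    config: SegmentationConfig | Mapping[str, SegmentationConfig] | None = None,
) -> dict[str, BinaryMask]:
    """Segment every channel; ``config`` may be shared or per-channel."""
    masks = {}
    for name in stack.channel_names:
        if isinstance(config, Mapping):
            cfg = config.get(name, SegmentationConfig())
        else:
            cfg = config
        masks[name] = segment_channel(stack, name, cfg)
    return masks


@dataclass
class QCReport:
    """Outcome of a no-primary negative-control check."""

    passed: bool
    max_burden_pct: float
    channel_burden_pct: dict[str, float]
    failing_channels: list[str]

    def __str__(self) -> str:  # plain-text audit report
        lines = [
            f"negative-control QC: {'PASS' if self.passed else 'FAIL'} "
            f"(limit {self.max_burden_pct}% per channel)"
        ]
        for c, b in self.channel_burden_pct.items():
            flag = "  <-- exceeds limit" if c in self.failing_channels else ""
            lines.append(f"  {c}: {b:.4f}%{flag}")
        return "\n".join(lines)


def qc_negative_control(
    stack: ImageStack,
    config: SegmentationConfig | Mapping[str, SegmentationConfig],
    max_burden_pct: float,
) -> QCReport:
    """Check a no-primary control stack for non-specific staining.

    The control is segmented with the supplied configuration (typically
    fixed thresholds carried over from a matched stained stack) and fails
    if any channel's burden exceeds ``max_burden_pct``.
    """
    burdens = {}
    for name in stack.channel_names:
        cfg = (config.get(name, SegmentationConfig())
               if isinstance(config, Mapping) else config)
        bm = segment_channel(stack, name, cfg)
        burdens[name] = 100.0 * bm.mask.sum() / bm.mask.size
    failing = [c for c, b in burdens.items() if b > max_burden_pct]
    return QCReport(
        passed=not failing,
        max_burden_pct=float(max_burden_pct),
        channel_burden_pct=burdens,
        failing_channels=failing,
    )


def export_mask(path: str | Path, mask: BinaryMask) -> Path:
    """Write a mask as 8-bit TIFF (0/255) with a plain-text sidecar
    recording the segmentation method."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (mask.mask.astype(np.uint8) * 255))
    sidecar = path.with_suffix(path.suffix + ".method.txt")
    lines = [f"channel\t{mask.channel_name}"]
    lines += [f"{k}\t{v}" for k, v in mask.method_record.items()]
    sidecar.write_text("\n".join(lines) + "\n")
    return path
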