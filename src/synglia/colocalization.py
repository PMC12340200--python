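"""Voxel-level burden, colocalization and engulfment-enrichment metrics.

All headline quantities are percentages of the total stack volume computed
on binary masks (voxel co-occupancy), not intensity correlations.  The
engulfment enrichment uses conditional denominators: the fraction of
amyloid-positive synaptic voxels inside glia over the same fraction for
amyloid-negative synaptic voxels.  Undefined ratios (zero denominators)
propagate as missing values, never as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .image_io import STUDY_CHANNELS, ImageStack
from .segmentation import BinaryMask, SegmentationConfig, segment_stack

__all__ = [
    "burden",
    "pairwise_coloc",
    "triple_coloc",
    "engulfment_enrichment",
    "EngulfmentResult",
    "RoiMeasurement",
    "measure_stack",
    "measurements_to_frame",
    "write_measurements",
]

GLIAL_CHANNELS = ("IBA1", "GFAP")


def _as_bool(mask: BinaryMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.mask
    return np.asarray(mask, dtype=bool)


def _check_shapes(*masks: np.ndarray) -> None:
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes differ: {sorted(shapes)}")


def burden(mask: BinaryMask | np.ndarray) -> float:
    """Percent of stack voxels positive for the channel."""
    m = _as_bool(mask)
    if m.size == 0:
        raise ValueError("empty mask array")
    return 100.0 * np.count_nonzero(m) / m.size


def pairwise_coloc(
    mask_a: BinaryMask | np.ndarray, mask_b: BinaryMask | np.ndarray
) -> float:
    """Percent of stack voxels positive in both channels (symmetric)."""
    a, b = _as_bool(mask_a), _as_bool(mask_b)
    _check_shapes(a, b)
    return 100.0 * np.count_nonzero(a & b) / a.size


def triple_coloc(
    mask_a: BinaryMask | np.ndarray,
    mask_b: BinaryMask | np.ndarray,
    mask_c: BinaryMask | np.ndarray,
) -> float:
    """Percent of stack voxels positive in all three channels."""
    a, b, c = _as_bool(mask_a), _as_bool(mask_b), _as_bool(mask_c)
    _check_shapes(a, b, c)
    return 100.0 * np.count_nonzero(a & b & c) / a.size


@dataclass
class EngulfmentResult:
    """Conditional synapse-in-glia fractions for one glial channel.

    Fractions are in [0, 1]; any component whose denominator is zero is
    ``None`` and listed in ``undefined``.
    """

    frac_ab_pos_syn_in_glia: float | None
    frac_ab_neg_syn_in_glia: float | None
    enrichment_ratio: float | None
    undefined: list[str] = field(default_factory=list)


def engulfment_enrichment(
    syn_mask: BinaryMask | np.ndarray,
    ab_mask: BinaryMask | np.ndarray,
    glia_mask: BinaryMask | np.ndarray,
) -> EngulfmentResult:
    """How much more likely amyloid-positive synaptic voxels are to sit
    inside glia than amyloid-negative ones."""
    syn, ab, glia = _as_bool(syn_mask), _as_bool(ab_mask), _as_bool(glia_mask)
    _check_shapes(syn, ab, glia)
    n_pos = int(np.count_nonzero(syn & ab))
    n_neg = int(np.count_nonzero(syn & ~ab))
    undefined = []
    frac_pos = frac_neg = ratio = None
    if n_pos > 0:
        frac_pos = np.count_nonzero(syn & ab & glia) / n_pos
    else:
        undefined.append("frac_ab_pos_syn_in_glia")
    if n_neg > 0:
        frac_neg = np.count_nonzero(syn & ~ab & glia) / n_neg
    else:
        undefined.append("frac_ab_neg_syn_in_glia")
    if frac_pos is not None and frac_neg is not None and frac_neg > 0:
        ratio = frac_pos / frac_neg
    else:
        undefined.append("enrichment_ratio")
    return EngulfmentResult(
        frac_ab_pos_syn_in_glia=frac_pos,
        frac_ab_neg_syn_in_glia=frac_neg,
        enrichment_ratio=ratio,
        undefined=undefined,
    )


@dataclass
class RoiMeasurement:
    """Every quantity extracted from one stack, plus its nesting keys."""

    case_id: str
    roi_pair_id: str
    stack_id: str
    plaque_status: str
    burden_pct: dict[str, float]
    pairwise_pct: dict[tuple[str, str], float]
    pairwise_pct_of_first: dict[tuple[str, str], float]
    triple_pct: dict[tuple[str, str, str], float]
    engulfment: dict[str, EngulfmentResult]

    def to_row(self) -> dict:
        """Flatten into one tidy table row with documented column names."""
        row: dict = {
            "case_id": self.case_id,
            "roi_pair_id": self.roi_pair_id,
            "stack_id": self.stack_id,
            "plaque_status": self.plaque_status,
        }
        for c, v in self.burden_pct.items():
            row[f"burden_{c}"] = v
        for (a, b), v in self.pairwise_pct.items():
            row[f"pair_{a}_{b}"] = v
        for (a, b), v in self.pairwise_pct_of_first.items():
            row[f"pairof_{a}_{b}"] = v
        for (a, b, c), v in self.triple_pct.items():
            row[f"triple_{a}_{b}_{c}"] = v
        for g, e in self.engulfment.items():
            row[f"engulf_{g}_frac_ab_pos"] = (
                math.nan if e.frac_ab_pos_syn_in_glia is None
                else e.frac_ab_pos_syn_in_glia
            )
            row[f"engulf_{g}_frac_ab_neg"] = (
                math.nan if e.frac_ab_neg_syn_in_glia is None
                else e.frac_ab_neg_syn_in_glia
            )
            row[f"engulf_{g}_ratio"] = (
                math.nan if e.enrichment_ratio is None else e.enrichment_ratio
            )
        return row


def measure_masks(
    masks: Mapping[str, BinaryMask | np.ndarray],
    case_id: str = "",
    roi_pair_id: str = "",
    stack_id: str = "",
    plaque_status: str = "",
) -> RoiMeasurement:
    """Compute all measurement fields from pre-segmented study masks."""
    arr = {c: _as_bool(masks[c]) for c in STUDY_CHANNELS}
    names = list(STUDY_CHANNELS)
    burden_pct = {c: burden(arr[c]) for c in names}
    pairwise, pair_of_first = {}, {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = pairwise_coloc(arr[a], arr[b])
            n_a = np.count_nonzero(arr[a])
            pair_of_first[(a, b)] = (
                100.0 * np.count_nonzero(arr[a] & arr[b]) / n_a
                if n_a else math.nan
            )
    triple = {}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            for k in range(j + 1, len(names)):
                b, c = names[j], names[k]
                triple[(a, b, c)] = triple_coloc(arr[a], arr[b], arr[c])
    engulf = {
        g: engulfment_enrichment(arr["Synapsin1"], arr["Abeta4G8"], arr[g])
        for g in GLIAL_CHANNELS
    }
    return RoiMeasurement(
        case_id=case_id,
        roi_pair_id=roi_pair_id,
        stack_id=stack_id,
        plaque_status=plaque_status,
        burden_pct=burden_pct,
        pairwise_pct=pairwise,
        pairwise_pct_of_first=pair_of_first,
        triple_pct=triple,
        engulfment=engulf,
    )


def measure_stack(
    stack: ImageStack,
    config: SegmentationConfig | Mapping[str, SegmentationConfig] | None = None,
    case_id: str = "",
    roi_pair_id: str = "",
    stack_id: str = "",
    plaque_status: str = "",
) -> RoiMeasurement:
    """Segment all four study channels of a stack and measure everything."""
    stack.validate_study_channels()
    masks = segment_stack(stack, config)
    return measure_masks(
        masks,
        case_id=case_id,
        roi_pair_id=roi_pair_id,
        stack_id=stack_id,
        plaque_status=plaque_status,
    )


def measurements_to_frame(
    measurements: Sequence[RoiMeasurement],
) -> pd.DataFrame:
    return pd.DataFrame([m.to_row() for m in measurements])


def write_measurements(
    path: str | Path, measurements: Sequence[RoiMeasurement]
) -> Path:
    """Write one tidy tab-separated row per stack (the stats input format)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    measurements_to_frame(measurements).to_csv(path, sep="\t", index=False)
    return path
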