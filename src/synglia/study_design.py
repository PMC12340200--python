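"""Sampling logic: plaque detection, paired/random ROI plans, top-k
selection, and cohort demographics."""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.measure import label, regionprops

from .image_io import GROUPS, CaseRecord
from .segmentation import BinaryMask

__all__ = [
    "PlaqueCall",
    "detect_plaque",
    "build_roi_plan",
    "select_top_k_by_ab",
    "Demographics",
    "demographics",
    "fisher_exact_rxc",
]


@dataclass
class PlaqueCall:
    """Plaque-detection outcome for one stack."""

    positive: bool
    regions: pd.DataFrame  # label, n_voxels, volume_um3, esd_um, centroid


def detect_plaque(
    ab_mask: BinaryMask | np.ndarray,
    voxel_size_um: tuple[float, float, float],
    min_diameter_um: float = 10.0,
) -> PlaqueCall:
    """Find amyloid components large enough to count as plaques.

    A connected component qualifies when its equivalent spherical diameter
    (diameter of the sphere with the same volume) reaches
    ``min_diameter_um``.  The default separates diffuse deposits from
    punctate synaptic amyloid; no size criterion is claimed from the
    original acquisition protocol.
    """
    mask = ab_mask.mask if isinstance(ab_mask, BinaryMask) else np.asarray(
        ab_mask, dtype=bool
    )
    if voxel_size_um is None or len(voxel_size_um) != 3:
        raise ValueError("voxel_size_um (z, y, x) is required")
    voxel_volume = float(np.prod(voxel_size_um))
    rows = []
    if mask.any():
        labels = label(mask, connectivity=3)
        for rp in regionprops(labels):
            vol = rp.num_pixels * voxel_volume
            esd = (6.0 * vol / np.pi) ** (1.0 / 3.0)
            if esd >= min_diameter_um:
                rows.append(
                    {
                        "label": rp.label,
                        "n_voxels": rp.num_pixels,
                        "volume_um3": vol,
                        "esd_um": esd,
                        "centroid_z": rp.centroid[0],
                        "centroid_y": rp.centroid[1],
                        "centroid_x": rp.centroid[2],
                    }
                )
    regions = pd.DataFrame(
        rows,
        columns=["label", "n_voxels", "volume_um3", "esd_um",
                 "centroid_z", "centroid_y", "centroid_x"],
    )
    return PlaqueCall(positive=len(rows) > 0, regions=regions)


def build_roi_plan(
    manifest: pd.DataFrame,
    plaque_calls: Mapping[str, bool],
    n_random: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each stack a sampling role.

    Cases with at least one plaque-positive stack get a paired plan: every
    plaque-positive stack is coupled with the non-positive stack sharing
    its ``roi_pair_id``.  Plaque-free cases contribute ``n_random`` stacks
    chosen reproducibly from their candidates; a shortfall keeps all
    candidates and is recorded in the ``note`` column.
    """
    required = {"case_id", "stack_id"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    uncalled = [s for s in manifest["stack_id"] if s not in plaque_calls]
    if uncalled:
        raise ValueError(f"no plaque call for stacks {uncalled[:5]}")
    rng = np.random.default_rng(seed)
    rows = []
    for case_id, sub in manifest.groupby("case_id", sort=True):
        if len(sub) == 0:
            raise ValueError(f"case {case_id} has zero stacks")
        pos = sub[sub["stack_id"].map(plaque_calls)]
        if len(pos):
            if "roi_pair_id" not in sub.columns:
                raise ValueError(
                    f"case {case_id} is plaque-positive but the manifest has "
                    "no roi_pair_id column to pair plaque/adjacent stacks"
                )
            for _, prow in pos.iterrows():
                partners = sub[
                    (sub["roi_pair_id"] == prow["roi_pair_id"])
                    & (sub["stack_id"] != prow["stack_id"])
                ]
                rows.append(
                    {
                        "case_id": case_id,
                        "stack_id": prow["stack_id"],
                        "roi_pair_id": prow["roi_pair_id"],
                        "plaque_status": "plaque",
                        "selection_rule": "paired",
                        "note": "",
                    }
                )
                if len(partners) == 0:
                    rows[-1]["note"] = "unpaired plaque stack"
                    continue
                partner = partners.sort_values("stack_id").iloc[0]
                rows.append(
                    {
                        "case_id": case_id,
                        "stack_id": partner["stack_id"],
                        "roi_pair_id": partner["roi_pair_id"],
                        "plaque_status": "no_plaque",
                        "selection_rule": "paired",
                        "note": "",
                    }
                )
        else:
            candidates = sorted(sub["stack_id"])
            note = ""
            if len(candidates) > n_random:
                chosen = sorted(
                    rng.choice(candidates, size=n_random, replace=False)
                )
            else:
                chosen = candidates
                if len(candidates) < n_random:
                    note = (
                        f"only {len(candidates)} of the requested "
                        f"{n_random} stacks available"
                    )
            roi_map = (
                sub.set_index("stack_id")["roi_pair_id"]
                if "roi_pair_id" in sub.columns else {}
            )
            for sid in chosen:
                rows.append(
                    {
                        "case_id": case_id,
                        "stack_id": sid,
                        "roi_pair_id": roi_map.get(sid, ""),
                        "plaque_status": "random",
                        "selection_rule": "random",
                        "note": note,
                    }
                )
    return pd.DataFrame(rows)


def select_top_k_by_ab(
    measurements: pd.DataFrame,
    k: int = 10,
    burden_column: str = "burden_Abeta4G8",
    case_column: str = "case_id",
) -> pd.DataFrame:
    """Per case, keep the ``k`` stacks with the highest amyloid burden.

    Ties break by lexicographic ``stack_id``; cases with fewer than ``k``
    rows are kept whole.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    parts = []
    for _, sub in measurements.groupby(case_column, sort=True):
        ordered = sub.sort_values(
            [burden_column, "stack_id"], ascending=[False, True]
        )
        parts.append(ordered.head(k))
    return pd.concat(parts, ignore_index=True)


def fisher_exact_rxc(table: np.ndarray) -> float:
    """Exact conditional test of independence for a small 2 x c table.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more likely than the observed table
    (Fisher-Freeman-Halton).
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("only 2 x c tables are supported")
    col_totals = table.sum(axis=0)
    n_first = int(table[0].sum())
    n = int(table.sum())
    denom = comb(n, n_first)

    def prob(first_row: tuple[int, ...]) -> float:
        p = 1.0
        for f, ct in zip(first_row, col_totals):
            p *= comb(int(ct), int(f))
        return p / denom

    obs_p = prob(tuple(table[0]))
    cutoff = obs_p * (1.0 + 1e-9)

    total = 0.0

    def recurse(col: int, remaining: int, row: list[int]) -> None:
        nonlocal total
        if col == len(col_totals) - 1:
            if remaining <= col_totals[col]:
                p = prob(tuple(row + [remaining]))
                if p <= cutoff:
                    total += p
            return
        for f in range(0, min(int(col_totals[col]), remaining) + 1):
            recurse(col + 1, remaining - f, row + [f])

    recurse(0, n_first, [])
    return min(total, 1.0)


@dataclass
class Demographics:
    """Cohort stratification plus age- and sex-matching tests."""

    group_counts: dict[str, int]
    sex_counts: dict[str, int]
    sex_percent: dict[str, float]
    group_age_mean: dict[str, float]
    wilcoxon_w: float | None
    wilcoxon_p: float | None
    fisher_p: float | None
    notes: list[str] = field(default_factory=list)

    def report(self) -> str:
        lines = ["cohort demographics", "-------------------"]
        for g in GROUPS:
            n = self.group_counts.get(g, 0)
            age = self.group_age_mean.get(g)
            age_s = f", mean age {age:.1f} y" if age is not None else ""
            lines.append(f"{g}: n = {n}{age_s}")
        lines.append(
            "sex: "
            + ", ".join(
                f"{s} = {self.sex_counts.get(s, 0)}"
                f" ({self.sex_percent.get(s, 0.0):.0f}%)"
                for s in ("F", "M", "Unknown")
            )
        )
        if self.wilcoxon_p is not None:
            lines.append(
                f"age match (CDS vs Aged, Wilcoxon rank sum): "
                f"W = {self.wilcoxon_w:.1f}, p = {self.wilcoxon_p:.3f}"
            )
        if self.fisher_p is not None:
            lines.append(
                f"sex match (Fisher's exact, Unknown excluded): "
                f"p = {self.fisher_p:.3f}"
            )
        lines.extend(f"note: {n}" for n in self.notes)
        return "\n".join(lines)


def demographics(records: Sequence[CaseRecord]) -> Demographics:
    """Summaries and matching tests for a parsed case table.

    The age-match test is a two-sided Wilcoxon rank-sum (Mann-Whitney,
    mid-rank ties) of CDS versus Aged ages; the sex-match test is Fisher's
    exact on the sex-by-group table excluding the Unknown-sex case.
    """
    if not records:
        raise ValueError("at least one case record is required")
    group_counts = {g: sum(r.group == g for r in records) for g in GROUPS}
    sex_counts = {
        s: sum(r.sex == s for r in records) for s in ("F", "M", "Unknown")
    }
    total = len(records)
    sex_percent = {s: 100.0 * c / total for s, c in sex_counts.items()}
    group_age_mean = {
        g: float(np.mean([r.age_years for r in records if r.group == g]))
        for g in GROUPS
        if group_counts[g] > 0
    }
    notes = []
    wilcoxon_w = wilcoxon_p = None
    ages_cds = [r.age_years for r in records if r.group == "CDS"]
    ages_aged = [r.age_years for r in records if r.group == "Aged"]
    if ages_cds and ages_aged:
        res = sps.mannwhitneyu(
            ages_cds, ages_aged, alternative="two-sided", method="auto"
        )
        wilcoxon_w = float(res.statistic)
        wilcoxon_p = float(res.pvalue)
        if len(set(ages_cds + ages_aged)) < len(ages_cds + ages_aged):
            notes.append(
                "tied ages present; Wilcoxon p uses the normal "
                "approximation with mid-ranks"
            )
    else:
        notes.append("age-match test skipped: CDS or Aged group absent")
    fisher_p = None
    known = [r for r in records if r.sex != "Unknown"]
    groups_present = [g for g in GROUPS if any(r.group == g for r in known)]
    if len(groups_present) >= 2 and len({r.sex for r in known}) == 2:
        table = np.array(
            [
                [sum(r.group == g and r.sex == "F" for r in known)
                 for g in groups_present],
                [sum(r.group == g and r.sex == "M" for r in known)
                 for g in groups_present],
            ]
        )
        fisher_p = fisher_exact_rxc(table)
        if sex_counts["Unknown"]:
            notes.append(
                f"{sex_counts['Unknown']} case(s) of unknown sex excluded "
                "from the sex-match test"
            )
    else:
        notes.append("sex-match test skipped: needs >=2 groups and both sexes")
    return Demographics(
        group_counts=group_counts,
        sex_counts=sex_counts,
        sex_percent=sex_percent,
        group_age_mean=group_age_mean,
        wilcoxon_w=wilcoxon_w,
        wilcoxon_p=wilcoxon_p,
        fisher_p=fisher_p,
        notes=notes,
    )
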