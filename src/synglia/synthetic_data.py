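"""Synthetic 4-channel 3D stacks and nested cohorts with known ground truth.

Scenes contain punctate synaptic staining, an optional diffuse amyloid
deposit, branched glial arbors, and configurable synapse-into-glia
relocation ("engulfment").  Ground-truth percentages are computed by exact
voxel counting on the pre-blur binary geometry, then the stack is blurred
with a Gaussian PSF and corrupted with Poisson and Gaussian noise.

The default geometry is desk-scale (16 x 128 x 128 voxels); the study's
full 184.7 um field of view is available by configuration.  Voxel
dimensions are conventions, not values taken from any acquisition.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import STUDY_CHANNELS, CaseRecord, ImageStack, write_stack

__all__ = [
    "GliaParams",
    "NearPlaqueMultipliers",
    "SceneParams",
    "GroundTruth",
    "GroupEffects",
    "CohortSpec",
    "CohortStack",
    "generate_scene",
    "generate_cohort",
    "save_cohort",
    "stack_hash",
]

_PAIRS = [
    (a, b) for i, a in enumerate(STUDY_CHANNELS) for b in STUDY_CHANNELS[i + 1:]
]
_TRIPLES = [
    (STUDY_CHANNELS[i], STUDY_CHANNELS[j], STUDY_CHANNELS[k])
    for i in range(4)
    for j in range(i + 1, 4)
    for k in range(j + 1, 4)
]

GLIAL_CHANNELS = ("IBA1", "GFAP")
_ENGULF_LABEL = {"IBA1": "microglia", "GFAP": "astrocyte"}


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid SceneParams.{name}: {msg}")


@dataclass(frozen=True)
class GliaParams:
    """Geometry of one glial channel: spherical somata with capsule branches."""

    n_somas: int = 3
    soma_radius_um: float = 2.5
    n_branches: int = 6
    branch_length_um: float = 8.0
    branch_radius_um: float = 0.6

    def validate(self, name: str) -> None:
        _require(self.n_somas >= 0, name, "n_somas must be >= 0")
        _require(self.soma_radius_um > 0, name, "soma_radius_um must be > 0")
        _require(self.n_branches >= 0, name, "n_branches must be >= 0")
        _require(self.branch_length_um > 0, name, "branch_length_um must be > 0")
        _require(self.branch_radius_um > 0, name, "branch_radius_um must be > 0")


@dataclass(frozen=True)
class NearPlaqueMultipliers:
    """Multipliers applied within ``plaque_radius_um + plaque_halo_um``."""

    glia_density: float = 1.0
    engulfment_fraction: float = 1.0
    ab_in_synapse_fraction: float = 1.0

    def validate(self) -> None:
        for f in ("glia_density", "engulfment_fraction", "ab_in_synapse_fraction"):
            _require(getattr(self, f) >= 0, f"near_plaque_multipliers.{f}",
                     "must be >= 0")


def _default_glia() -> dict[str, GliaParams]:
    return {"IBA1": GliaParams(), "GFAP": GliaParams(n_somas=3, n_branches=8)}


@dataclass(frozen=True)
class SceneParams:
    """Full parameterization of one synthetic stack."""

    shape_vox: tuple[int, int, int] = (16, 128, 128)
    voxel_size_um: tuple[float, float, float] = (0.5, 0.3, 0.3)
    synapse_density_per_um3: float = 0.12
    synapse_radius_um: float = 0.5
    ab_in_synapse_fraction: float = 0.2
    plaque_present: bool = False
    plaque_center_um: tuple[float, float, float] | None = None
    plaque_radius_um: float = 8.0
    plaque_halo_um: float = 5.0
    glia: Mapping[str, GliaParams] = field(default_factory=_default_glia)
    engulfment_fraction: float = 0.1
    engulfment_ab_bias: float = 1.0
    near_plaque_multipliers: NearPlaqueMultipliers = field(
        default_factory=NearPlaqueMultipliers
    )
    psf_sigma_um: tuple[float, float, float] = (0.3, 0.15, 0.15)
    photon_scale: float = 80.0
    read_noise_sd: float = 0.02
    background_level: float = 0.05

    def __post_init__(self) -> None:
        _require(len(self.shape_vox) == 3 and all(s >= 1 for s in self.shape_vox),
                 "shape_vox", "must be 3 positive integers")
        _require(all(v > 0 for v in self.voxel_size_um), "voxel_size_um",
                 "must be strictly positive")
        _require(self.synapse_density_per_um3 >= 0, "synapse_density_per_um3",
                 "must be >= 0")
        _require(self.synapse_radius_um > 0, "synapse_radius_um", "must be > 0")
        _require(0 <= self.ab_in_synapse_fraction <= 1, "ab_in_synapse_fraction",
                 "must be in [0, 1]")
        _require(0 <= self.engulfment_fraction <= 1, "engulfment_fraction",
                 "must be in [0, 1]")
        _require(self.engulfment_ab_bias >= 0, "engulfment_ab_bias",
                 "must be >= 0")
        _require(self.plaque_radius_um > 0, "plaque_radius_um", "must be > 0")
        _require(self.plaque_halo_um >= 0, "plaque_halo_um", "must be >= 0")
        _require(all(s >= 0 for s in self.psf_sigma_um), "psf_sigma_um",
                 "must be >= 0")
        _require(self.photon_scale > 0, "photon_scale", "must be > 0")
        _require(self.read_noise_sd >= 0, "read_noise_sd", "must be >= 0")
        _require(self.background_level >= 0, "background_level", "must be >= 0")
        for name in self.glia:
            _require(name in GLIAL_CHANNELS, "glia",
                     f"unknown glial channel {name!r}")
            self.glia[name].validate(f"glia[{name!r}]")
        self.near_plaque_multipliers.validate()
        if self.plaque_present and self.plaque_center_um is not None:
            ext = self.extent_um
            _require(
                all(0 <= c <= e for c, e in zip(self.plaque_center_um, ext)),
                "plaque_center_um",
                f"must lie inside the stack extent {ext}",
            )

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(
            s * v for s, v in zip(self.shape_vox, self.voxel_size_um)
        )

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.extent_um))

    def resolved_plaque_center(self) -> np.ndarray:
        if self.plaque_center_um is not None:
            return np.asarray(self.plaque_center_um, dtype=float)
        return np.asarray(self.extent_um, dtype=float) / 2.0


@dataclass
class GroundTruth:
    """Exact pre-blur geometry and voxel-count percentages for one scene."""

    masks: dict[str, np.ndarray]
    true_burden_pct: dict[str, float]
    true_pairwise_pct: dict[tuple[str, str], float]
    true_triple_pct: dict[tuple[str, str, str], float]
    punctum_table: pd.DataFrame
    plaque_mask: np.ndarray


def _voxel_centers_um(shape: tuple[int, ...], voxel: tuple[float, ...]):
    """Per-axis voxel-centre coordinates in micrometres."""
    return [
        (np.arange(n) + 0.5) * v for n, v in zip(shape, voxel)
    ]


def _rasterize_spheres(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    centers_um: np.ndarray,
    radius_um: float | np.ndarray,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Stamp spheres onto a boolean grid; a voxel is set when its centre
    lies within the sphere."""
    if out is None:
        out = np.zeros(shape, dtype=bool)
    if len(centers_um) == 0:
        return out
    radii = np.broadcast_to(np.asarray(radius_um, dtype=float),
                            (len(centers_um),))
    vz, vy, vx = voxel
    for (cz, cy, cx), r in zip(np.asarray(centers_um, dtype=float), radii):
        lo = [
            max(0, int(np.floor((c - r) / v - 0.5)))
            for c, v in zip((cz, cy, cx), voxel)
        ]
        hi = [
            min(n, int(np.ceil((c + r) / v + 0.5)) + 1)
            for c, v, n in zip((cz, cy, cx), voxel, shape)
        ]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        zz = (np.arange(lo[0], hi[0]) + 0.5) * vz - cz
        yy = (np.arange(lo[1], hi[1]) + 0.5) * vy - cy
        xx = (np.arange(lo[2], hi[2]) + 0.5) * vx - cx
        d2 = (
            zz[:, None, None] ** 2 + yy[None, :, None] ** 2
            + xx[None, None, :] ** 2
        )
        out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r
    return out


def _rasterize_capsule(
    shape, voxel, p0_um: np.ndarray, p1_um: np.ndarray, radius_um: float,
    out: np.ndarray,
) -> np.ndarray:
    """Approximate a cylinder by stamping spheres along its axis."""
    step = min(voxel) / 2.0
    length = float(np.linalg.norm(p1_um - p0_um))
    n = max(2, int(np.ceil(length / step)) + 1)
    ts = np.linspace(0.0, 1.0, n)
    centers = p0_um[None, :] + ts[:, None] * (p1_um - p0_um)[None, :]
    return _rasterize_spheres(shape, voxel, centers, radius_um, out=out)


def _render_glia(
    params: SceneParams, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Place glial somata (uniform; near-plaque surplus inside the halo)
    and radiating branches, returning one boolean volume per channel."""
    shape, voxel = params.shape_vox, params.voxel_size_um
    extent = np.asarray(params.extent_um)
    halo_r = params.plaque_radius_um + params.plaque_halo_um
    center = params.resolved_plaque_center()
    masks: dict[str, np.ndarray] = {}
    for name in GLIAL_CHANNELS:
        gp = params.glia.get(name)
        mask = np.zeros(shape, dtype=bool)
        if gp is None or gp.n_somas == 0:
            masks[name] = mask
            continue
        somas = rng.uniform(0.0, 1.0, size=(gp.n_somas, 3)) * extent
        if params.plaque_present:
            mult = params.near_plaque_multipliers.glia_density
            n_extra = int(round(gp.n_somas * max(mult - 1.0, 0.0)))
            extra = []
            while len(extra) < n_extra:
                p = center + rng.uniform(-halo_r, halo_r, size=3)
                if (np.linalg.norm(p - center) <= halo_r
                        and np.all(p >= 0) and np.all(p <= extent)):
                    extra.append(p)
            if extra:
                somas = np.vstack([somas, np.asarray(extra)])
        _rasterize_spheres(shape, voxel, somas, gp.soma_radius_um, out=mask)
        for soma in somas:
            for _ in range(gp.n_branches):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                _rasterize_capsule(
                    shape, voxel, soma, soma + d * gp.branch_length_um,
                    gp.branch_radius_um, out=mask,
                )
        masks[name] = mask
    return masks


def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    """Efraimidis-Spirakis reservoir keys: take the k largest u**(1/w)."""
    w = np.asarray(weights, dtype=float)
    keys = np.full(len(w), -np.inf)
    pos = w > 0
    u = rng.uniform(size=int(pos.sum()))
    keys[pos] = np.log(u) / w[pos]
    k = min(k, int(pos.sum()))
    if k == 0:
        return np.empty(0, dtype=int)
    return np.argsort(keys)[::-1][:k]


def _exact_percentages(masks: dict[str, np.ndarray]):
    total = float(np.prod(next(iter(masks.values())).shape))
    burden = {c: 100.0 * m.sum() / total for c, m in masks.items()}
    pairwise = {
        (a, b): 100.0 * np.count_nonzero(masks[a] & masks[b]) / total
        for a, b in _PAIRS
    }
    triple = {
        (a, b, c): 100.0
        * np.count_nonzero(masks[a] & masks[b] & masks[c]) / total
        for a, b, c in _TRIPLES
    }
    return burden, pairwise, triple


def generate_scene(
    params: SceneParams, seed: int
) -> tuple[ImageStack, GroundTruth]:
    """Render one 4-channel stack and its exact ground truth.

    Rendering order: place geometry, relocate engulfed puncta into glia,
    compute ground truth on the binary geometry, blur with the PSF, then
    apply Poisson noise, Gaussian read noise and a constant background.
    Identical ``(params, seed)`` yield bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shape, voxel = params.shape_vox, params.voxel_size_um
    extent = np.asarray(params.extent_um)
    plaque_center = params.resolved_plaque_center()
    halo_r = params.plaque_radius_um + params.plaque_halo_um

    # --- plaque density field (Gaussian falloff; 0.5 at the nominal radius)
    plaque_density = np.zeros(shape, dtype=float)
    if params.plaque_present:
        zz, yy, xx = np.meshgrid(
            *_voxel_centers_um(shape, voxel), indexing="ij"
        )
        r2 = (
            (zz - plaque_center[0]) ** 2
            + (yy - plaque_center[1]) ** 2
            + (xx - plaque_center[2]) ** 2
        )
        plaque_density = np.exp(
            -np.log(2.0) * r2 / params.plaque_radius_um**2
        )
    plaque_mask = plaque_density > 0.5

    # --- synaptic puncta
    n_syn = rng.poisson(params.synapse_density_per_um3 * params.volume_um3)
    centers = rng.uniform(0.0, 1.0, size=(n_syn, 3)) * extent
    near = np.zeros(n_syn, dtype=bool)
    if params.plaque_present and n_syn:
        near = np.linalg.norm(centers - plaque_center, axis=1) <= halo_r
    p_ab = np.full(n_syn, params.ab_in_synapse_fraction)
    if params.plaque_present:
        p_ab[near] = np.clip(
            p_ab[near] * params.near_plaque_multipliers.ab_in_synapse_fraction,
            0.0, 1.0,
        )
    ab_positive = rng.uniform(size=n_syn) < p_ab

    # --- glial geometry
    glia_masks = _render_glia(params, rng)

    # --- engulfment: weighted selection, then relocation into glia
    p_eng = np.full(n_syn, params.engulfment_fraction)
    if params.plaque_present:
        p_eng[near] = np.clip(
            p_eng[near] * params.near_plaque_multipliers.engulfment_fraction,
            0.0, 1.0,
        )
    engulfed_by = np.array(["none"] * n_syn, dtype=object)
    host_channels = [c for c in GLIAL_CHANNELS if glia_masks[c].any()]
    k = int(round(p_eng.sum()))
    if k > 0 and host_channels and n_syn > 0:
        weights = p_eng * np.where(ab_positive, params.engulfment_ab_bias, 1.0)
        chosen = _weighted_sample_without_replacement(rng, weights, k)
        glia_voxels = {
            c: np.argwhere(glia_masks[c]) for c in host_channels
        }
        hosts = rng.integers(0, len(host_channels), size=len(chosen))
        for idx, h in zip(chosen, hosts):
            chan = host_channels[h]
            vox = glia_voxels[chan][rng.integers(0, len(glia_voxels[chan]))]
            centers[idx] = (vox + rng.uniform(0.0, 1.0, size=3)) * np.asarray(
                voxel
            )
            engulfed_by[idx] = _ENGULF_LABEL[chan]

    syn_mask = _rasterize_spheres(
        shape, voxel, centers, params.synapse_radius_um
    )
    ab_core_mask = _rasterize_spheres(
        shape, voxel, centers[ab_positive], params.synapse_radius_um
    )
    ab_mask = ab_core_mask | plaque_mask

    masks = {
        "GFAP": glia_masks["GFAP"],
        "Abeta4G8": ab_mask,
        "Synapsin1": syn_mask,
        "IBA1": glia_masks["IBA1"],
    }
    burden, pairwise, triple = _exact_percentages(masks)
    punctum_table = pd.DataFrame(
        {
            "z_um": centers[:, 0] if n_syn else np.empty(0),
            "y_um": centers[:, 1] if n_syn else np.empty(0),
            "x_um": centers[:, 2] if n_syn else np.empty(0),
            "radius_um": np.full(n_syn, params.synapse_radius_um),
            "ab_positive": ab_positive,
            "engulfed_by": engulfed_by,
        }
    )
    truth = GroundTruth(
        masks={c: m.copy() for c, m in masks.items()},
        true_burden_pct=burden,
        true_pairwise_pct=pairwise,
        true_triple_pct=triple,
        punctum_table=punctum_table,
        plaque_mask=plaque_mask,
    )

    # --- render intensities: binary geometry (Abeta keeps the diffuse falloff)
    channels = np.stack(
        [
            masks["GFAP"].astype(float),
            np.maximum(plaque_density, ab_core_mask.astype(float)),
            masks["Synapsin1"].astype(float),
            masks["IBA1"].astype(float),
        ]
    )
    sigma_vox = tuple(
        s / v for s, v in zip(params.psf_sigma_um, params.voxel_size_um)
    )
    if any(s > 0 for s in sigma_vox):
        for c in range(channels.shape[0]):
            channels[c] = ndimage.gaussian_filter(channels[c], sigma=sigma_vox)
    noisy = channels
    if params.photon_scale > 0 and np.isfinite(params.photon_scale):
        noisy = rng.poisson(params.photon_scale * channels) / params.photon_scale
    if params.read_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, params.read_noise_sd, size=noisy.shape)
    noisy = np.clip(noisy + params.background_level, 0.0, None)

    stack = ImageStack(
        voxels=noisy.astype(np.float32),
        channel_names=STUDY_CHANNELS,
        voxel_size_um=params.voxel_size_um,
        provenance=f"synthetic:seed={seed}",
    )
    return stack, truth


def noiseless(params: SceneParams) -> SceneParams:
    """Copy of ``params`` with PSF, noise and background switched off.

    ``photon_scale`` is kept positive but infinite photon statistics are
    emulated by bypassing the Poisson draw (sigma and read noise zero, and
    ``photon_scale=inf`` sentinel is not used: instead noise is disabled by
    exact intensities).
    """
    return replace(
        params,
        psf_sigma_um=(0.0, 0.0, 0.0),
        photon_scale=np.inf,
        read_noise_sd=0.0,
        background_level=0.0,
    )


def stack_hash(stack: ImageStack) -> str:
    """SHA-256 of the voxel buffer; used for determinism checks."""
    return hashlib.sha256(
        np.ascontiguousarray(stack.voxels).tobytes()
    ).hexdigest()


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupEffects:
    """Per-group multipliers applied to the base scene parameters."""

    ab_in_synapse_fraction: float = 1.0
    glia_density: float = 1.0
    engulfment_fraction: float = 1.0
    plaque_prevalence: float = 0.0

    def validate(self, group: str) -> None:
        for f in ("ab_in_synapse_fraction", "glia_density",
                  "engulfment_fraction"):
            if getattr(self, f) < 0:
                raise ValueError(
                    f"CohortSpec effect {group}.{f} must be >= 0"
                )
        if not 0 <= self.plaque_prevalence <= 1:
            raise ValueError(
                f"CohortSpec effect {group}.plaque_prevalence must be in [0,1]"
            )


def _default_effects() -> dict[str, GroupEffects]:
    return {
        "Young": GroupEffects(),
        "Aged": GroupEffects(ab_in_synapse_fraction=2.0, glia_density=1.3,
                             engulfment_fraction=1.5, plaque_prevalence=0.6),
        "CDS": GroupEffects(ab_in_synapse_fraction=2.5, glia_density=1.5,
                            engulfment_fraction=2.0, plaque_prevalence=0.7),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Sizes, nesting and per-group effects of a simulated cohort."""

    n_young: int = 7
    n_aged: int = 10
    n_cds: int = 8
    stacks_per_case: int = 4
    base_params: SceneParams = field(default_factory=SceneParams)
    effects: Mapping[str, GroupEffects] = field(default_factory=_default_effects)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, n in (("n_young", self.n_young), ("n_aged", self.n_aged),
                        ("n_cds", self.n_cds)):
            if n < 1:
                raise ValueError(f"CohortSpec.{name} must be >= 1")
        if self.stacks_per_case < 1:
            raise ValueError("CohortSpec.stacks_per_case must be >= 1")
        if self.stacks_per_case % 2:
            raise ValueError(
                "CohortSpec.stacks_per_case must be even so plaque-bearing "
                "cases can be organized into plaque/adjacent pairs"
            )
        for g, eff in self.effects.items():
            eff.validate(g)

    @property
    def group_sizes(self) -> dict[str, int]:
        return {"Young": self.n_young, "Aged": self.n_aged, "CDS": self.n_cds}


@dataclass
class CohortStack:
    """One generated stack together with its nesting keys and truth."""

    case_id: str
    group: str
    stack_id: str
    roi_pair_id: str
    plaque_status: str  # plaque | no_plaque | random
    seed: int
    stack: ImageStack
    truth: GroundTruth


_AGE_RANGES = {"Young": (2.0, 7.0), "Aged": (14.0, 25.0), "CDS": (10.0, 19.0)}


def _case_params(base: SceneParams, eff: GroupEffects) -> SceneParams:
    glia = {
        name: replace(
            gp, n_somas=int(round(gp.n_somas * eff.glia_density))
        )
        for name, gp in base.glia.items()
    }
    return replace(
        base,
        ab_in_synapse_fraction=min(
            1.0, base.ab_in_synapse_fraction * eff.ab_in_synapse_fraction
        ),
        engulfment_fraction=min(
            1.0, base.engulfment_fraction * eff.engulfment_fraction
        ),
        glia=glia,
    )


def _child_seed(master: int, *path: int) -> int:
    """Deterministic per-stack seed: SeedSequence(master, *path) entropy."""
    ss = np.random.SeedSequence(entropy=(master,) + path)
    return int(ss.generate_state(1, dtype=np.uint64)[0] & 0x7FFFFFFF)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[CaseRecord], list[CohortStack], pd.DataFrame]:
    """Generate a nested cohort: stacks within ROI pairs within cases.

    Plaque-bearing cases (drawn per group from ``plaque_prevalence``)
    receive ``stacks_per_case / 2`` paired (plaque, adjacent no-plaque)
    stacks; plaque-free cases receive ``stacks_per_case`` random stacks.
    The master seed spawns per-case and per-stack child seeds through
    ``numpy.random.SeedSequence`` so every stack is independent and the
    whole cohort is reproducible.
    """
    records: list[CaseRecord] = []
    stacks: list[CohortStack] = []
    rows = []
    case_index = 0
    for group in ("Young", "Aged", "CDS"):
        eff = spec.effects.get(group, GroupEffects())
        for _ in range(spec.group_sizes[group]):
            case_index += 1
            case_id = f"SIM{case_index:03d}"
            crng = np.random.default_rng(
                np.random.SeedSequence(entropy=(spec.seed, case_index))
            )
            lo, hi = _AGE_RANGES[group]
            age = round(float(crng.uniform(lo, hi)), 1)
            sex = "F" if crng.uniform() < 0.6 else "M"
            has_plaques = bool(crng.uniform() < eff.plaque_prevalence)
            params = _case_params(spec.base_params, eff)
            records.append(
                CaseRecord(
                    case_id=case_id,
                    group=group,
                    age_years=age,
                    sex=sex,
                    ab_score="mild" if has_plaques else "none",
                    tau_score="none",
                )
            )
            for j in range(spec.stacks_per_case):
                seed_j = _child_seed(spec.seed, case_index, j)
                if has_plaques:
                    pair = j // 2
                    status = "plaque" if j % 2 == 0 else "no_plaque"
                    sp = replace(params, plaque_present=(status == "plaque"))
                else:
                    pair = j
                    status = "random"
                    sp = replace(params, plaque_present=False)
                stack, truth = generate_scene(sp, seed_j)
                stack_id = f"{case_id}_s{j:02d}"
                roi_pair_id = f"{case_id}_p{pair:02d}"
                stacks.append(
                    CohortStack(
                        case_id=case_id, group=group, stack_id=stack_id,
                        roi_pair_id=roi_pair_id, plaque_status=status,
                        seed=seed_j, stack=stack, truth=truth,
                    )
                )
                rows.append(
                    {
                        "case_id": case_id,
                        "group": group,
                        "stack_id": stack_id,
                        "roi_pair_id": roi_pair_id,
                        "plaque_status": status,
                        "seed": seed_j,
                    }
                )
    manifest = pd.DataFrame(rows)
    return records, stacks, manifest


def truth_table(stacks: list[CohortStack]) -> pd.DataFrame:
    """Tidy per-stack ground-truth percentages for a generated cohort."""
    rows = []
    for cs in stacks:
        row = {
            "case_id": cs.case_id,
            "group": cs.group,
            "stack_id": cs.stack_id,
            "roi_pair_id": cs.roi_pair_id,
            "plaque_status": cs.plaque_status,
        }
        for c, v in cs.truth.true_burden_pct.items():
            row[f"true_burden_{c}"] = v
        for (a, b), v in cs.truth.true_pairwise_pct.items():
            row[f"true_pair_{a}_{b}"] = v
        for (a, b, c), v in cs.truth.true_triple_pct.items():
            row[f"true_triple_{a}_{b}_{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def save_cohort(
    out_dir: str | Path,
    records: list[CaseRecord],
    stacks: list[CohortStack],
    manifest: pd.DataFrame,
    write_puncta: bool = False,
) -> Path:
    """Write a cohort to disk: OME-TIFF stacks plus TSV tables."""
    from .image_io import format_case_table

    out_dir = Path(out_dir)
    stack_dir = out_dir / "stacks"
    stack_dir.mkdir(parents=True, exist_ok=True)
    for cs in stacks:
        write_stack(stack_dir / f"{cs.stack_id}.ome.tif", cs.stack)
        if write_puncta:
            cs.truth.punctum_table.to_csv(
                stack_dir / f"{cs.stack_id}.puncta.tsv", sep="\t", index=False
            )
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    truth_table(stacks).to_csv(
        out_dir / "ground_truth.tsv", sep="\t", index=False
    )
    format_case_table(records, out_dir / "cases.tsv")
    return out_dir
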