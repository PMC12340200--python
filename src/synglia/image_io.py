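"""Reading and writing multi-channel 3D stacks and case metadata tables.

The internal stack representation is a 4D float array ordered
``(channel, z, y, x)`` with named channels and voxel dimensions in
micrometres.  Stacks are stored on disk as OME-TIFF; case tables are
plain delimited text.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "STUDY_CHANNELS",
    "CHANNEL_ALIASES",
    "GROUPS",
    "SEXES",
    "SCORES",
    "ImageStack",
    "CaseRecord",
    "read_stack",
    "write_stack",
    "parse_case_table",
    "format_case_table",
    "packaged_case_table_path",
]

#: Canonical channel names for study stacks, in acquisition order.
STUDY_CHANNELS = ("GFAP", "Abeta4G8", "Synapsin1", "IBA1")

#: Variant channel names seen in figure legends mapped to canonical names.
CHANNEL_ALIASES = {
    "4G8": "Abeta4G8",
    "Abeta": "Abeta4G8",
    "Ab": "Abeta4G8",
    "amyloid-beta": "Abeta4G8",
    "SYN1": "Synapsin1",
    "Syn1": "Synapsin1",
    "synapsin-1": "Synapsin1",
    "Synapsin-1": "Synapsin1",
    "Iba1": "IBA1",
    "gfap": "GFAP",
}

GROUPS = ("Young", "Aged", "CDS")
SEXES = ("F", "M", "Unknown")
SCORES = ("none", "mild", "moderate", "severe")

# "-" in the published table is U+2212; both forms are accepted.
_SCORE_TOKENS = {
    "-": "none",
    "−": "none",
    "none": "none",
    "+": "mild",
    "++": "moderate",
    "+++": "severe",
    "mild": "mild",
    "moderate": "moderate",
    "severe": "severe",
}
_SEX_TOKENS = {"F": "F", "M": "M", "?": "Unknown", "Unknown": "Unknown"}
_SCORE_FORMAT = {"none": "-", "mild": "+", "moderate": "++", "severe": "+++"}
_SEX_FORMAT = {"F": "F", "M": "M", "Unknown": "?"}


def canonical_channel_name(name: str) -> str:
    """Map a variant channel label to its canonical study name."""
    return CHANNEL_ALIASES.get(name, name)


@dataclass
class ImageStack:
    """A multi-channel 3D intensity volume.

    Parameters
    ----------
    voxels
        Array of shape ``(n_channels, nz, ny, nx)``; finite, non-negative.
    channel_names
        One label per channel.  Study stacks carry exactly the four
        canonical channels (:data:`STUDY_CHANNELS`); other channel sets are
        allowed for generic use.
    voxel_size_um
        Physical voxel edge lengths ``(z, y, x)`` in micrometres.
    provenance
        Source path or generator seed string, for audit.
    """

    voxels: np.ndarray
    channel_names: tuple[str, ...]
    voxel_size_um: tuple[float, float, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be 4D (channel, z, y, x); got ndim={self.voxels.ndim}"
            )
        self.channel_names = tuple(
            canonical_channel_name(str(n)) for n in self.channel_names
        )
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"duplicate channel names: {self.channel_names}")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_um must be 3 positive reals; got {vs}")
        self.voxel_size_um = vs
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values")
        if np.any(self.voxels < 0):
            raise ValueError("voxels contain negative intensities")

    @property
    def shape_vox(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape_vox))

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's 3D volume, resolving name aliases."""
        name = canonical_channel_name(name)
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack (have {self.channel_names})"
            ) from None
        return self.voxels[idx]

    def validate_study_channels(self) -> None:
        """Raise if the stack does not carry the four study channels."""
        missing = [c for c in STUDY_CHANNELS if c not in self.channel_names]
        if missing or len(self.channel_names) != len(STUDY_CHANNELS):
            raise ValueError(
                "study stacks require exactly the channels "
                f"{STUDY_CHANNELS}; got {self.channel_names} "
                f"(missing {missing})"
            )


@dataclass(frozen=True)
class CaseRecord:
    """Metadata for one animal."""

    case_id: str
    group: str
    age_years: float
    sex: str
    ab_score: str
    tau_score: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}; got {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}; got {self.sex!r}")
        if self.ab_score not in SCORES or self.tau_score not in SCORES:
            raise ValueError(
                f"scores must be one of {SCORES}; got "
                f"ab={self.ab_score!r}, tau={self.tau_score!r}"
            )
        if not self.age_years > 0:
            raise ValueError(f"age_years must be > 0; got {self.age_years}")


def write_stack(path: str | Path, stack: ImageStack) -> Path:
    """Write a stack as OME-TIFF with channel names and voxel size metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    z, y, x = stack.voxel_size_um
    tifffile.imwrite(
        path,
        np.asarray(stack.voxels, dtype=np.float32),
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": list(stack.channel_names)},
            "PhysicalSizeX": x,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": y,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": z,
            "PhysicalSizeZUnit": "µm",
        },
    )
    return path


def _parse_ome(xml_text: str) -> tuple[list[str] | None, tuple[float, float, float] | None]:
    """Extract channel names and (z, y, x) voxel size from OME-XML."""
    root = ET.fromstring(xml_text)
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pix = root.find(".//ome:Pixels" if ns else ".//Pixels", ns)
    if pix is None:
        return None, None
    chans = pix.findall("ome:Channel" if ns else "Channel", ns)
    names: list[str] | None = [c.get("Name") or "" for c in chans] or None
    sx, sy, sz = (pix.get("PhysicalSizeX"), pix.get("PhysicalSizeY"),
                  pix.get("PhysicalSizeZ"))
    size = None
    if sx is not None and sy is not None and sz is not None:
        size = (float(sz), float(sy), float(sx))
    return names, size


def read_stack(
    path: str | Path,
    voxel_size_um: tuple[float, float, float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack into the internal representation.

    Metadata (channel names, voxel size) is taken from the OME header when
    present; explicit arguments override it.  A file lacking voxel-size
    metadata raises unless ``voxel_size_um`` is supplied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta_names, meta_size = (None, None)
        if tf.ome_metadata:
            meta_names, meta_size = _parse_ome(tf.ome_metadata)

    # Normalize axis order to (C, Z, Y, X), inserting missing singleton axes.
    axes = axes.replace("S", "C").replace("Q", "Z")
    for ax in "CZ":
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "CZYX" if ax in axes]
    extra = [i for i in range(data.ndim) if i not in order]
    if extra:  # drop leading singleton axes such as T
        data = data.squeeze(axis=tuple(extra))
        axes = "".join(a for i, a in enumerate(axes) if i not in extra)
        order = [axes.index(ax) for ax in "CZYX"]
    data = np.transpose(data, order)

    names = list(channel_names) if channel_names is not None else meta_names
    if names is None or any(not n for n in names):
        names = [f"ch{i}" for i in range(data.shape[0])]
    size = voxel_size_um if voxel_size_um is not None else meta_size
    if size is None:
        raise ValueError(
            f"{path}: no voxel size in metadata; supply voxel_size_um "
            "explicitly (e.g. via configuration)"
        )
    return ImageStack(
        voxels=data,
        channel_names=tuple(names),
        voxel_size_um=tuple(size),
        provenance=str(path),
    )


_CASE_COLUMNS = ["case_id", "group", "age_years", "sex", "ab_score", "tau_score"]


def parse_case_table(path: str | Path) -> list[CaseRecord]:
    """Parse a delimited case-metadata table into :class:`CaseRecord` rows.

    Accepts tab- or comma-separated text with the header columns
    ``case_id group age_years sex ab_score tau_score``.  Sex token ``?``
    maps to ``Unknown``; score tokens ``-``/``+``/``++``/``+++`` map to
    ``none``/``mild``/``moderate``/``severe``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in _CASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records: list[CaseRecord] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2  # 1-based, counting the header line
        group = str(row["group"]).strip()
        if group not in GROUPS:
            raise ValueError(f"{path} row {rowno}: unknown group {group!r}")
        sex_tok = str(row["sex"]).strip()
        if sex_tok not in _SEX_TOKENS:
            raise ValueError(f"{path} row {rowno}: unknown sex token {sex_tok!r}")
        scores = {}
        for col in ("ab_score", "tau_score"):
            tok = str(row[col]).strip()
            if tok not in _SCORE_TOKENS:
                raise ValueError(
                    f"{path} row {rowno}: unknown {col} token {tok!r}"
                )
            scores[col] = _SCORE_TOKENS[tok]
        try:
            age = float(row["age_years"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{path} row {rowno}: age_years not numeric: {row['age_years']!r}"
            ) from None
        records.append(
            CaseRecord(
                case_id=str(row["case_id"]).strip(),
                group=group,
                age_years=age,
                sex=_SEX_TOKENS[sex_tok],
                ab_score=scores["ab_score"],
                tau_score=scores["tau_score"],
            )
        )
    return records


def format_case_table(records: Sequence[CaseRecord], path: str | Path) -> Path:
    """Write case records back to canonical tab-separated form."""
    path = Path(path)
    rows = []
    for r in records:
        age = r.age_years
        rows.append(
            {
                "case_id": r.case_id,
                "group": r.group,
                "age_years": int(age) if float(age).is_integer() else age,
                "sex": _SEX_FORMAT[r.sex],
                "ab_score": _SCORE_FORMAT[r.ab_score],
                "tau_score": _SCORE_FORMAT[r.tau_score],
            }
        )
    pd.DataFrame(rows, columns=_CASE_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def packaged_case_table_path() -> Path:
    """Path to the case-metadata table shipped with the package."""
    return Path(__file__).parent / "data" / "case_table.tsv"
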