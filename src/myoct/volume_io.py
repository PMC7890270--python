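"""Calibrated volume and cohort-table input/output.

All internal computation is done in Hounsfield units; grey values are only
a storage representation linked to HU by an affine calibration
``HU = slope * grey + intercept``. Thresholds supplied in scanner-native
grey values are converted to HU on load, so segmentation is invariant to
the calibration in use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Calibration",
    "CalibratedVolume",
    "AnimalRecord",
    "CohortTable",
    "VolumeFormatError",
    "CohortSchemaError",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_cohort",
    "write_cohort",
]


class VolumeFormatError(ValueError):
    """Volume file missing required metadata or structurally invalid."""


class CohortSchemaError(ValueError):
    """Cohort CSV violates the documented schema."""


@dataclass(frozen=True)
class Calibration:
    """Affine grey→HU calibration: ``HU = slope * grey + intercept``."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")

    def hu_of(self, grey):
        return np.asarray(grey) * self.slope + self.intercept

    def grey_of(self, hu):
        return (np.asarray(hu) - self.intercept) / self.slope


@dataclass
class CalibratedVolume:
    """A 3D grey-value volume with voxel size and HU calibration attached."""

    grey_volume: np.ndarray
    voxel_size: float  # mm, isotropic
    calibration: Calibration
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.grey_volume.ndim != 3:
            raise VolumeFormatError("expected a 3D volume")
        if self.voxel_size <= 0:
            raise VolumeFormatError("voxel_size must be positive")

    @property
    def hu_volume(self) -> np.ndarray:
        return self.calibration.hu_of(self.grey_volume)

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_size**3 / 1000.0

    @property
    def pixel_area_mm2(self) -> float:
        return self.voxel_size**2


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def read_volume(path: str | Path, calibration_config: dict | None = None) -> CalibratedVolume:
    """Read a TIFF stack or NIfTI volume with calibration metadata.

    Voxel size and calibration come from *calibration_config* when given,
    else from a JSON sidecar next to the file (``<stem>.json``). A missing
    voxel size is an error — it is never silently assumed.

    The config may carry thresholds in grey values; conversion helpers live
    on the returned volume's :class:`Calibration`.
    """
    path = Path(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    if calibration_config:
        meta.update(calibration_config)

    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj).T.astype(np.float32)  # (x,y,z) -> (z,y,x)
        zooms = img.header.get_zooms()[:3]
        if meta.get("voxel_size") is None:
            if not np.allclose(zooms, zooms[0]):
                raise VolumeFormatError("anisotropic NIfTI without explicit voxel_size")
            meta["voxel_size"] = float(zooms[0])
    elif name.endswith((".tif", ".tiff")):
        import tifffile

        data = tifffile.imread(str(path))
        if data.ndim != 3:
            raise VolumeFormatError(f"TIFF stack must be 3D, got {data.ndim}D")
        data = data.astype(np.float32)
    else:
        raise VolumeFormatError(f"unsupported volume format: {path.suffix}")

    if "voxel_size" not in meta or meta["voxel_size"] is None:
        raise VolumeFormatError(f"no voxel size for {path}; supply config or sidecar")
    cal = meta.get("calibration")
    if cal is None:
        raise VolumeFormatError(f"no grey->HU calibration for {path}")
    calibration = Calibration(float(cal["slope"]), float(cal["intercept"]))
    return CalibratedVolume(
        grey_volume=data,
        voxel_size=float(meta["voxel_size"]),
        calibration=calibration,
        provenance={"source": str(path), **{k: meta[k] for k in meta if k not in ("calibration",)}},
    )


def write_volume(path: str | Path, vol: CalibratedVolume) -> Path:
    """Write grey values as TIFF stack or NIfTI plus a JSON sidecar."""
    path = Path(path)
    data = np.asarray(vol.grey_volume, dtype=np.float32)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([vol.voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(data.T, affine), str(path))
    elif name.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), data, photometric="minisblack")
    else:
        raise VolumeFormatError(f"unsupported volume format: {path.suffix}")
    sidecar = {
        "voxel_size": vol.voxel_size,
        "calibration": asdict(vol.calibration),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def write_mask(path: str | Path, mask: np.ndarray, voxel_size: float) -> Path:
    """Write a boolean mask volume as uint8 (0/1)."""
    path = Path(path)
    data = np.asarray(mask, dtype=np.uint8)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(data.T, affine), str(path))
    elif name.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), data, photometric="minisblack")
    else:
        raise VolumeFormatError(f"unsupported volume format: {path.suffix}")
    return path


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

_SCORE_RANGES = {"steatosis": (0, 3), "inflammation": (0, 3), "ballooning": (0, 2)}
_REQUIRED = ["animal_id", "group", "timepoint"]
_NONNEGATIVE = [
    "body_weight",
    "glycaemia",
    "insulinaemia",
    "muscle_lipid_biochem",
]


@dataclass
class AnimalRecord:
    """One animal at one timepoint: raw measurements plus derived fields.

    Grip trials are the pooled absolute-force readings from the two test
    sessions; histology sub-scores follow the Kleiner convention
    (steatosis 0–3, lobular inflammation 0–3, ballooning 0–2).
    """

    animal_id: str
    group: str
    timepoint: float  # weeks
    body_weight: float | None = None  # g
    glycaemia: float | None = None  # mmol/L
    insulinaemia: float | None = None  # mU/L
    grip_trials: list[float] = field(default_factory=list)
    steatosis: int | None = None
    inflammation: int | None = None
    ballooning: int | None = None
    muscle_lipid_biochem: float | None = None  # mg lipid / g tissue
    derived: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in _SCORE_RANGES.items():
            val = getattr(self, name)
            if val is not None and not lo <= val <= hi:
                raise CohortSchemaError(f"{name}={val} outside [{lo}, {hi}]")
        for name in _NONNEGATIVE:
            val = getattr(self, name)
            if val is not None and val < 0:
                raise CohortSchemaError(f"{name} must be non-negative")
        if any(g < 0 for g in self.grip_trials):
            raise CohortSchemaError("grip trials must be non-negative")

    def to_row(self) -> dict:
        row = {
            "animal_id": self.animal_id,
            "group": self.group,
            "timepoint": self.timepoint,
            "body_weight": self.body_weight,
            "glycaemia": self.glycaemia,
            "insulinaemia": self.insulinaemia,
            "grip_trials": ";".join(f"{g:.6g}" for g in self.grip_trials),
            "steatosis": self.steatosis,
            "inflammation": self.inflammation,
            "ballooning": self.ballooning,
            "muscle_lipid_biochem": self.muscle_lipid_biochem,
        }
        row.update(self.derived)
        return row


class CohortTable:
    """Thin typed wrapper around a pandas DataFrame of animal records."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise CohortSchemaError(f"missing required columns: {missing}")
        dup = df.duplicated(subset=["animal_id", "timepoint"])
        if dup.any():
            raise CohortSchemaError(
                f"duplicate (animal_id, timepoint) rows: {df.loc[dup, 'animal_id'].tolist()}"
            )
        for name, (lo, hi) in _SCORE_RANGES.items():
            if name in df.columns:
                vals = pd.to_numeric(df[name], errors="coerce").dropna()
                bad = vals[(vals < lo) | (vals > hi)]
                if len(bad):
                    raise CohortSchemaError(f"{name} outside [{lo}, {hi}]: {bad.tolist()}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records) -> "CohortTable":
        return cls(pd.DataFrame([r.to_row() for r in records]))

    def records(self) -> list[AnimalRecord]:
        out = []
        known = {
            "animal_id",
            "group",
            "timepoint",
            "body_weight",
            "glycaemia",
            "insulinaemia",
            "grip_trials",
            "steatosis",
            "inflammation",
            "ballooning",
            "muscle_lipid_biochem",
        }
        for _, row in self.df.iterrows():
            trials = row.get("grip_trials")
            if isinstance(trials, str) and trials:
                trials = [float(t) for t in trials.split(";")]
            elif not isinstance(trials, list):
                trials = []

            def _opt(name, cast=float):
                val = row.get(name)
                if val is None or (isinstance(val, float) and np.isnan(val)) or pd.isna(val):
                    return None
                return cast(val)

            rec = AnimalRecord(
                animal_id=str(row["animal_id"]),
                group=str(row["group"]),
                timepoint=float(row["timepoint"]),
                body_weight=_opt("body_weight"),
                glycaemia=_opt("glycaemia"),
                insulinaemia=_opt("insulinaemia"),
                grip_trials=trials,
                steatosis=_opt("steatosis", int),
                inflammation=_opt("inflammation", int),
                ballooning=_opt("ballooning", int),
                muscle_lipid_biochem=_opt("muscle_lipid_biochem"),
                derived={k: row[k] for k in self.df.columns if k not in known},
            )
            out.append(rec)
        return out


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort CSV (comma-separated, UTF-8, dot decimal).

    Rows missing any of the required identification fields are dropped
    with a logged count; unknown columns are preserved.
    """
    df = pd.read_csv(path)
    n_before = len(df)
    present = [c for c in _REQUIRED if c in df.columns]
    if len(present) < len(_REQUIRED):
        raise CohortSchemaError(
            f"missing required columns: {sorted(set(_REQUIRED) - set(present))}"
        )
    df = df.dropna(subset=_REQUIRED)
    dropped = n_before - len(df)
    if dropped:
        logger.warning("read_cohort: dropped %d rows with missing required fields", dropped)
    return CohortTable(df)


def write_cohort(table: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    table.df.to_csv(path, index=False, float_format="%.12g")
    return path
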