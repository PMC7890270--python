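"""Digital mouse phantom for whole-body micro-CT.

Generates 3D grey-value volumes with known tissue composition so that
segmentation and densitometry code can be validated against ground truth.
The phantom is deliberately built from geometric primitives: an ellipsoidal
soft-tissue envelope, a vertebral column with bead-shaped vertebrae, paired
dorsal-muscle prisms flanking the spine at the lumbar levels L4/L5, a
subcutaneous fat shell plus a visceral fat deposit, a liver containing
tubular vessels, and an ellipsoidal spleen (an internal density control,
always lipid-free).

Attenuation follows a linear Hounsfield-unit mixing model: a soft tissue
with lipid (fat) volume fraction ``f`` attenuates at

    HU(f) = (1 - f) * lean_hu + f * fat_hu

which makes every downstream density metric desk-checkable in closed form.
An optional "marbled" mode replaces the voxel-level mixture by discrete fat
voxels at proportion ``f`` to stress partial-volume behaviour.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TissueHU",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomVolume",
    "PhantomSizeError",
    "GroupSpec",
    "CohortDesign",
    "default_design",
    "generate_phantom",
    "generate_cohort",
    "VOLUMETRIC_DENSITY",
]

# Volumetric mass densities (g/cm^3) used for the CT-estimated body weight:
# fat-free (lean) mass, fat mass and bone mass.
VOLUMETRIC_DENSITY = {"fat": 0.95, "lean": 1.05, "bone": 1.92}


class PhantomSizeError(ValueError):
    """Requested anatomy does not fit the requested voxel grid."""


@dataclass(frozen=True)
class TissueHU:
    """Nominal attenuation of pure tissues on the Hounsfield scale."""

    air: float = -1000.0
    fat: float = -100.0
    lean: float = 50.0
    bone: float = 800.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic animal.

    Parameters
    ----------
    body_length : float
        Cranio-caudal length of the soft-tissue ellipsoid, mm.
    body_radii : (float, float)
        Dorso-ventral and left-right semi-axes of the elliptical
        cross-section, mm.
    fat_fraction : float
        Fraction of the soft-tissue (non-bone) volume that is adipose,
        in [0, 1).
    bone_fraction : float
        Fraction of the whole body volume that is bone, in [0, 1).
    muscle_lipid_fraction, liver_lipid_fraction : float
        Lipid volume fraction of dorsal muscle / liver parenchyma, [0, 1).
    voxel_size : float
        Isotropic voxel edge, mm.
    noise_sd : float
        Additive Gaussian noise on HU, standard deviation.
    seed : int
        Seed for the noise (and marbling) generator; identical
        (spec, seed) pairs produce bit-identical volumes.
    tissue_hu : TissueHU
        Pure-tissue attenuations.
    calibration : (float, float)
        Affine grey→HU pair (slope, intercept): HU = slope*grey + intercept.
        The stored grey volume is the inverse image of the HU volume.
    mixing : str
        "linear" (default) or "marbled" lipid model.
    grid_shape : tuple or None
        Optional fixed (nz, ny, nx) grid; raises PhantomSizeError when the
        body plus margin does not fit.
    """

    body_length: float = 90.0
    body_radii: tuple[float, float] = (14.0, 11.0)
    fat_fraction: float = 0.25
    bone_fraction: float = 0.05
    muscle_lipid_fraction: float = 0.0
    liver_lipid_fraction: float = 0.0
    voxel_size: float = 0.2
    noise_sd: float = 15.0
    seed: int = 0
    tissue_hu: TissueHU = field(default_factory=TissueHU)
    calibration: tuple[float, float] = (1.0, -1000.0)
    mixing: str = "linear"
    grid_shape: tuple[int, int, int] | None = None
    margin: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.fat_fraction < 1.0:
            raise ValueError("fat_fraction must lie in [0, 1)")
        if not 0.0 <= self.bone_fraction < 1.0:
            raise ValueError("bone_fraction must lie in [0, 1)")
        if self.fat_fraction + self.bone_fraction >= 1.0:
            raise ValueError("fat_fraction + bone_fraction must be < 1")
        for f in (self.muscle_lipid_fraction, self.liver_lipid_fraction):
            if not 0.0 <= f < 1.0:
                raise ValueError("lipid fractions must lie in [0, 1)")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.calibration[0] == 0:
            raise ValueError("calibration slope must be non-zero")
        if self.mixing not in ("linear", "marbled"):
            raise ValueError("mixing must be 'linear' or 'marbled'")

    def scaled(self, factor: float) -> "PhantomSpec":
        """Return a copy with all linear body dimensions scaled."""
        return dataclasses.replace(
            self,
            body_length=self.body_length * factor,
            body_radii=(self.body_radii[0] * factor, self.body_radii[1] * factor),
        )


@dataclass
class PhantomTruth:
    """Ground truth carried alongside the voxel data."""

    mass: float  # g
    volumes: dict[str, float]  # cm^3 per compartment (fat, lean, bone)
    muscle_lipid_fraction: float
    liver_lipid_fraction: float


@dataclass
class PhantomVolume:
    """A generated phantom: grey values, ground-truth masks and metadata.

    ``masks`` holds 3D boolean arrays for ``fat``, ``lean``, ``bone``,
    ``dorsal_muscle``, ``liver``, ``liver_vessels``, ``spleen`` and 2D
    boolean arrays (one axial slice) for ``dorsal_muscle_l4``,
    ``dorsal_muscle_l5`` and ``visceral_fat_l4``.
    """

    grey_volume: np.ndarray
    voxel_size: float
    calibration: tuple[float, float]
    masks: dict[str, np.ndarray]
    slice_index_l4: int
    slice_index_l5: int
    vertebra_slices: list[int]
    truth: PhantomTruth
    spec: PhantomSpec

    @property
    def hu_volume(self) -> np.ndarray:
        slope, intercept = self.calibration
        return self.grey_volume * slope + intercept

    def calibrated(self):
        """View this phantom as a :class:`~myoct.volume_io.CalibratedVolume`."""
        from .volume_io import CalibratedVolume, Calibration

        return CalibratedVolume(
            grey_volume=self.grey_volume,
            voxel_size=self.voxel_size,
            calibration=Calibration(*self.calibration),
            provenance={"source": "phantom", "seed": self.spec.seed},
        )

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path, fmt: str = "nifti") -> Path:
        """Write grey volume, masks and a JSON sidecar into *directory*."""
        from . import volume_io

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ext = ".nii" if fmt == "nifti" else ".tif"
        volume_io.write_volume(directory / f"grey{ext}", self.calibrated())
        for name, mask in self.masks.items():
            if mask.ndim == 3:
                volume_io.write_mask(directory / f"mask_{name}{ext}", mask, self.voxel_size)
        sidecar = {
            "voxel_size": self.voxel_size,
            "calibration": {"slope": self.calibration[0], "intercept": self.calibration[1]},
            "slice_index_l4": self.slice_index_l4,
            "slice_index_l5": self.slice_index_l5,
            "vertebra_slices": self.vertebra_slices,
            "truth": {
                "mass": self.truth.mass,
                "volumes": self.truth.volumes,
                "muscle_lipid_fraction": self.truth.muscle_lipid_fraction,
                "liver_lipid_fraction": self.truth.liver_lipid_fraction,
            },
        }
        (directory / "phantom.json").write_text(json.dumps(sidecar, indent=2))
        return directory


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

N_VERTEBRAE = 13  # beads along the spine; lumbar levels counted caudally


def _grid_coordinates(spec: PhantomSpec):
    """Physical (mm) coordinates of voxel centres and the grid shape."""
    v = spec.voxel_size
    ry, rx = spec.body_radii
    extent_z = spec.body_length + 2 * spec.margin
    extent_y = 2 * ry + 2 * spec.margin
    extent_x = 2 * rx + 2 * spec.margin
    shape = (
        int(math.ceil(extent_z / v)),
        int(math.ceil(extent_y / v)),
        int(math.ceil(extent_x / v)),
    )
    if spec.grid_shape is not None:
        if any(g < s for g, s in zip(spec.grid_shape, shape)):
            raise PhantomSizeError(
                f"body of extent ({extent_z:.1f}, {extent_y:.1f}, {extent_x:.1f}) mm "
                f"does not fit grid {spec.grid_shape} at voxel {v} mm"
            )
        shape = tuple(spec.grid_shape)
    z = (np.arange(shape[0], dtype=np.float32) + 0.5) * v
    y = (np.arange(shape[1], dtype=np.float32) + 0.5) * v
    x = (np.arange(shape[2], dtype=np.float32) + 0.5) * v
    return shape, z[:, None, None], y[None, :, None], x[None, None, :]


def _ellipsoid(z, y, x, center, semi) -> np.ndarray:
    cz, cy, cx = center
    az, ay, ax = semi
    u = ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2
    return u <= 1.0


def _take_smallest(metric: np.ndarray, candidates: np.ndarray, n: int) -> np.ndarray:
    """Boolean mask selecting the *n* candidate voxels with smallest metric."""
    out = np.zeros(metric.shape, dtype=bool)
    if n <= 0:
        return out
    idx = np.flatnonzero(candidates)
    if n >= idx.size:
        out.flat[idx] = True
        return out
    vals = metric.flat[idx]
    sel = np.argpartition(vals, n - 1)[:n]
    out.flat[idx[sel]] = True
    return out


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Realize a :class:`PhantomSpec` as a voxel volume with truth masks.

    The returned masks partition the body into fat / lean / bone; dorsal
    muscle, liver, vessels and spleen are sub-regions of lean. Voxel HU
    follow the linear mixing model, then seeded Gaussian noise is added and
    the affine calibration inverted to produce grey values.
    """
    shape, z, y, x = _grid_coordinates(spec)
    v = spec.voxel_size
    ry, rx = spec.body_radii
    L = spec.body_length
    cz = spec.margin + L / 2.0
    cy = spec.margin + ry
    cx = spec.margin + rx

    # soft-tissue envelope: ellipsoid with semi-axes (L/2, ry, rx)
    u = ((z - cz) / (L / 2.0)) ** 2 + ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2
    body = u <= 1.0
    n_body = int(body.sum())
    if n_body == 0:
        raise PhantomSizeError("body ellipsoid contains no voxels at this voxel size")

    # ---- vertebral column: rod with bead-shaped vertebrae ---------------
    z0, z1 = cz - 0.4 * L, cz + 0.4 * L  # spine spans central 80 %
    bead_z = np.linspace(z0, z1, N_VERTEBRAE)
    spine_y = cy - 0.55 * ry
    d2 = (y - spine_y) ** 2 + (x - cx) ** 2  # squared radial distance, mm^2
    spacing = (z1 - z0) / (N_VERTEBRAE - 1)
    # beads widen the rod periodically: modulation >= 1 near vertebra centres
    phase = np.cos(2.0 * np.pi * (z - z0) / spacing)
    modulation = 1.0 + 0.6 * np.clip(phase, 0.0, None) ** 2
    in_spine_z = (z >= z0 - spacing / 2) & (z <= z1 + spacing / 2)
    metric = d2 / modulation
    n_bone = int(round(spec.bone_fraction * n_body))
    bone = _take_smallest(
        np.broadcast_to(metric, shape), body & np.broadcast_to(in_spine_z, shape), n_bone
    )

    # lumbar landmarks counted caudally (caudal = high z): L5 is the 4th
    # and L4 the 5th vertebra from the caudal end of the column.
    vert_idx = [int(zz / v) for zz in bead_z]
    slice_l4 = vert_idx[-5]
    slice_l5 = vert_idx[-4]

    # ---- dorsal muscles: paired elliptical prisms flanking the spine ----
    m_ry, m_rx = 0.20 * ry, 0.18 * rx
    spine_r = math.sqrt(max(n_bone, 1) * v**3 / (z1 - z0) / math.pi) if n_bone else 0.12 * rx
    off = spine_r + 1.1 * m_rx
    mz0 = bead_z[-6] - 0.7 * spacing
    mz1 = bead_z[-3] + 0.7 * spacing
    in_muscle_z = (z >= mz0) & (z <= mz1)
    m_y = spine_y + 0.35 * m_ry
    ell_l = ((y - m_y) / m_ry) ** 2 + ((x - (cx - off)) / m_rx) ** 2 <= 1.0
    ell_r = ((y - m_y) / m_ry) ** 2 + ((x - (cx + off)) / m_rx) ** 2 <= 1.0
    muscle = body & ~bone & np.broadcast_to(in_muscle_z & (ell_l | ell_r), shape)

    # ---- organs ---------------------------------------------------------
    liver_c = (cz - 0.08 * L, cy + 0.15 * ry, cx)
    liver_semi = (0.11 * L, 0.50 * ry, 0.55 * rx)
    liver = _ellipsoid(z, y, x, liver_c, liver_semi) & body & ~bone & ~muscle

    vessel_r = max(0.35, 1.2 * v)
    vessels = np.zeros(shape, dtype=bool)
    for dy, dx in ((0.0, 0.0), (0.18 * ry, -0.22 * rx), (0.18 * ry, 0.22 * rx)):
        tube = ((y - (liver_c[1] + dy)) ** 2 + (x - (liver_c[2] + dx)) ** 2) <= vessel_r**2
        vessels |= np.broadcast_to(tube, shape)
    vessels &= liver

    spleen_c = (cz + 0.02 * L, cy + 0.30 * ry, cx - 0.62 * rx)
    spleen_semi = (0.06 * L, 0.16 * ry, 0.16 * rx)
    spleen = _ellipsoid(z, y, x, spleen_c, spleen_semi) & body & ~bone & ~liver & ~muscle

    # ---- fat: visceral deposit at L4 + subcutaneous shell ---------------
    visc_c = ((slice_l4 + 0.5) * v, cy + 0.45 * ry, cx + 0.10 * rx)
    visc_semi = (0.09 * L, 0.28 * ry, 0.34 * rx)
    organs = liver | spleen
    visceral = _ellipsoid(z, y, x, visc_c, visc_semi) & body & ~bone & ~muscle & ~organs

    n_soft = n_body - n_bone
    n_fat_target = int(round(spec.fat_fraction * n_soft))
    n_subq = max(n_fat_target - int(visceral.sum()), 0)
    unassigned = body & ~bone & ~muscle & ~organs & ~visceral
    # subcutaneous shell: the outermost unassigned voxels (largest
    # normalized ellipsoid radius u), taken to exact voxel count
    subq = _take_smallest(-u, unassigned, n_subq)
    fat = visceral | subq
    lean = body & ~bone & ~fat
    n_fat = int(fat.sum())
    n_lean = int(lean.sum())

    # ---- attenuation ----------------------------------------------------
    hu = spec.tissue_hu
    rng = np.random.default_rng(spec.seed)
    vol = np.full(shape, hu.air, dtype=np.float32)
    vol[lean] = hu.lean
    vol[fat] = hu.fat
    vol[bone] = hu.bone
    f_m, f_l = spec.muscle_lipid_fraction, spec.liver_lipid_fraction
    parenchyma = liver & ~vessels
    if spec.mixing == "linear":
        vol[muscle] = (1.0 - f_m) * hu.lean + f_m * hu.fat
        vol[parenchyma] = (1.0 - f_l) * hu.lean + f_l * hu.fat
    else:  # marbled: discrete fat voxels at proportion f
        for region, f in ((muscle, f_m), (parenchyma, f_l)):
            n = int(region.sum())
            marble = rng.random(n) < f
            vals = np.where(marble, hu.fat, hu.lean).astype(np.float32)
            vol[region] = vals
    # vessels attenuate like lean tissue (blood); spleen is lipid-free
    vol[vessels] = hu.lean
    vol[spleen] = hu.lean
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    slope, intercept = spec.calibration
    grey = (vol - intercept) / slope

    voxel_cm3 = (v**3) / 1000.0
    volumes = {
        "fat": n_fat * voxel_cm3,
        "lean": n_lean * voxel_cm3,
        "bone": n_bone * voxel_cm3,
    }
    mass = (
        VOLUMETRIC_DENSITY["fat"] * volumes["fat"]
        + VOLUMETRIC_DENSITY["lean"] * volumes["lean"]
        + VOLUMETRIC_DENSITY["bone"] * volumes["bone"]
    )
    truth = PhantomTruth(
        mass=mass, volumes=volumes, muscle_lipid_fraction=f_m, liver_lipid_fraction=f_l
    )
    masks = {
        "fat": fat,
        "lean": lean,
        "bone": bone,
        "dorsal_muscle": muscle,
        "liver": liver,
        "liver_vessels": vessels,
        "spleen": spleen,
        "dorsal_muscle_l4": muscle[slice_l4].copy(),
        "dorsal_muscle_l5": muscle[slice_l5].copy(),
        "visceral_fat_l4": visceral[slice_l4].copy(),
    }
    if not masks["dorsal_muscle_l4"].any() or not masks["dorsal_muscle_l5"].any():
        raise PhantomSizeError(
            "dorsal muscle empty on a lumbar slice; increase body size or reduce voxel_size"
        )
    return PhantomVolume(
        grey_volume=grey,
        voxel_size=v,
        calibration=spec.calibration,
        masks=masks,
        slice_index_l4=slice_l4,
        slice_index_l5=slice_l5,
        vertebra_slices=vert_idx,
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# cohort designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Distributional plan for one experimental group.

    Lipid fractions are drawn from clipped normals; the liver histology
    sub-scores are derived from the drawn liver lipid fraction (steatosis)
    and from group-level categorical probabilities (inflammation,
    ballooning), so that disease labels are consistent with the imaging
    ground truth.
    """

    name: str
    muscle_lipid: tuple[float, float] = (0.02, 0.01)  # mean, sd
    liver_lipid: tuple[float, float] = (0.02, 0.02)
    fat_fraction: tuple[float, float] = (0.20, 0.03)
    size_scale: tuple[float, float] = (1.0, 0.05)
    glycaemia: tuple[float, float] = (7.0, 1.0)  # mmol/L
    insulinaemia: tuple[float, float] = (8.0, 2.0)  # mU/L
    grip: tuple[float, float] = (240.0, 20.0)  # g-force per trial
    inflammation_p: tuple[float, ...] = (0.9, 0.1, 0.0, 0.0)  # P(score = 0..3)
    ballooning_p: tuple[float, ...] = (0.95, 0.05, 0.0)  # P(score = 0..2)


@dataclass(frozen=True)
class CohortDesign:
    """Group plan for :func:`generate_cohort`; animals are assigned to
    groups in round-robin order."""

    groups: tuple[GroupSpec, ...]
    timepoint: float = 34.0  # weeks on diet
    phantom: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort design must contain at least one group")


# Steatosis grade thresholds on liver lipid fraction (Kleiner-style 0-3).
_STEATOSIS_EDGES = (0.05, 0.15, 0.28)


def default_design(phantom: PhantomSpec | None = None) -> CohortDesign:
    """Four-group longitudinal design: chow controls, simple-steatosis
    (NAFL), early NASH and fibrosing NASH, with muscle lipid fraction
    rising along the disease spectrum and liver lipid driving the
    steatosis grade."""
    groups = (
        GroupSpec(
            name="control",
            muscle_lipid=(0.02, 0.01),
            liver_lipid=(0.02, 0.015),
            fat_fraction=(0.15, 0.02),
            size_scale=(0.92, 0.04),
            glycaemia=(6.5, 0.8),
            insulinaemia=(6.0, 1.5),
            grip=(243.0, 18.0),
            inflammation_p=(0.95, 0.05, 0.0, 0.0),
            ballooning_p=(1.0, 0.0, 0.0),
        ),
        GroupSpec(
            name="NAFL",
            muscle_lipid=(0.08, 0.02),
            liver_lipid=(0.12, 0.03),
            fat_fraction=(0.30, 0.03),
            size_scale=(1.05, 0.04),
            glycaemia=(9.0, 1.0),
            insulinaemia=(15.0, 4.0),
            grip=(237.0, 18.0),
            inflammation_p=(0.7, 0.3, 0.0, 0.0),
            ballooning_p=(0.9, 0.1, 0.0),
        ),
        GroupSpec(
            name="early-NASH",
            muscle_lipid=(0.18, 0.03),
            liver_lipid=(0.22, 0.04),
            fat_fraction=(0.35, 0.03),
            size_scale=(1.10, 0.04),
            glycaemia=(10.0, 1.2),
            insulinaemia=(22.0, 5.0),
            grip=(250.0, 20.0),
            inflammation_p=(0.0, 0.6, 0.35, 0.05),
            ballooning_p=(0.0, 0.8, 0.2),
        ),
        GroupSpec(
            name="fibrosing-NASH",
            muscle_lipid=(0.30, 0.03),
            liver_lipid=(0.32, 0.04),
            fat_fraction=(0.38, 0.03),
            size_scale=(1.12, 0.04),
            glycaemia=(11.0, 1.5),
            insulinaemia=(30.0, 6.0),
            grip=(165.0, 15.0),
            inflammation_p=(0.0, 0.3, 0.5, 0.2),
            ballooning_p=(0.0, 0.4, 0.6),
        ),
    )
    return CohortDesign(groups=groups, phantom=phantom or PhantomSpec())


def _clipped_normal(rng, mean, sd, lo, hi):
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def generate_cohort(n: int, design: CohortDesign, seed: int):
    """Generate *n* phantom animals plus matched records.

    Returns a list of ``(PhantomVolume, AnimalRecord)`` pairs. Animals are
    assigned to the design's groups in round-robin order; all randomness
    derives from *seed*, so identical (design, seed) pairs reproduce the
    cohort exactly.
    """
    from .volume_io import AnimalRecord

    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        group = design.groups[i % len(design.groups)]
        f_m = _clipped_normal(rng, *group.muscle_lipid, 0.0, 0.95)
        f_l = _clipped_normal(rng, *group.liver_lipid, 0.0, 0.95)
        fat_fraction = _clipped_normal(rng, *group.fat_fraction, 0.02, 0.6)
        scale = _clipped_normal(rng, *group.size_scale, 0.5, 1.6)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = dataclasses.replace(
            design.phantom.scaled(scale),
            fat_fraction=fat_fraction,
            muscle_lipid_fraction=f_m,
            liver_lipid_fraction=f_l,
            seed=sub_seed,
        )
        phantom = generate_phantom(spec)
        steatosis = int(np.searchsorted(_STEATOSIS_EDGES, f_l, side="right"))
        inflammation = int(rng.choice(4, p=_norm_p(group.inflammation_p, 4)))
        ballooning = int(rng.choice(3, p=_norm_p(group.ballooning_p, 3)))
        n_trials = int(rng.integers(3, 6))
        grip_trials = [
            max(0.0, float(rng.normal(group.grip[0], group.grip[1]))) for _ in range(n_trials)
        ]
        record = AnimalRecord(
            animal_id=f"{group.name}-{i:03d}",
            group=group.name,
            timepoint=design.timepoint,
            body_weight=phantom.truth.mass,
            glycaemia=_clipped_normal(rng, *group.glycaemia, 0.0, 60.0),
            insulinaemia=_clipped_normal(rng, *group.insulinaemia, 0.0, 300.0),
            grip_trials=grip_trials,
            steatosis=steatosis,
            inflammation=inflammation,
            ballooning=ballooning,
            muscle_lipid_biochem=1000.0 * f_m * 0.9 / 1.05,  # mg lipid / g tissue
        )
        out.append((phantom, record))
    return out


def _norm_p(p: Sequence[float], k: int) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.size != k or arr.min() < 0 or arr.sum() <= 0:
        raise ValueError("invalid categorical probabilities")
    return arr / arr.sum()
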