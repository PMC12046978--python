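"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Two groups share one voxel grid.  Cases carry confluent periventricular
lesions grown from a smoothed random field to a target volume fraction;
controls carry small or empty lesions.  Each metric map is a spatial baseline
plus a subject-level random intercept plus voxel noise, with an additive
lesion effect inside the lesion mask that decays exponentially with boundary
distance outside it.  A cognition outcome is linearly coupled to the planted
lesion myelin deficit and the demographic covariates.

No MR physics is simulated; the goal is downstream-testable statistical
structure, not anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .cognition import NormTable
from .volume import METRICS, METRIC_UNITS, MaskSet, SubjectRecord, VolumeMap

__all__ = [
    "MetricModel",
    "SimulationConfig",
    "simulate_cohort",
    "simulate_norm_table",
    "cohort_table",
]


class LesionPlacementError(ValueError):
    """Requested lesion volume cannot be placed on the configured grid."""


@dataclass
class MetricModel:
    """Generative parameters for one metric.

    ``lesion_effect`` is the additive shift applied inside the lesion mask;
    outside it the shift decays as ``effect * exp(-d / penumbra_decay_mm)``
    with ``d`` the Euclidean distance to the lesion boundary.
    """

    mean: float
    noise_sd: float
    subject_sd: float
    lesion_effect: float


def default_metric_models() -> dict[str, MetricModel]:
    # chi_neg is stored non-positive; a positive lesion effect moves it toward
    # zero, i.e. reduces its magnitude (the myelin deficit).  The default
    # shift equals 2.5 between-subject SDs, a planted one-sample effect size
    # of -2.5 on the magnitude difference scores.
    return {
        "chi_neg": MetricModel(mean=-0.030, noise_sd=0.008, subject_sd=0.004, lesion_effect=0.010),
        "chi_pos": MetricModel(mean=0.030, noise_sd=0.008, subject_sd=0.004, lesion_effect=-0.008),
        "md": MetricModel(mean=8.0e-4, noise_sd=1.5e-4, subject_sd=0.5e-4, lesion_effect=2.5e-4),
        "rd": MetricModel(mean=6.0e-4, noise_sd=1.5e-4, subject_sd=0.5e-4, lesion_effect=2.5e-4),
        "fw": MetricModel(mean=0.15, noise_sd=0.05, subject_sd=0.02, lesion_effect=0.15),
    }


def default_cognition_coefficients() -> dict[str, float]:
    # "deficit" multiplies the planted magnitude deficit (ppm) of chi_neg in
    # the lesion; positive coupling: less myelin -> lower cognition.
    return {
        "intercept": 0.0,
        "deficit": 150.0,
        "age": -0.01,
        "sex": -0.05,
        "education": 0.03,
        "noise_sd": 0.8,
    }


@dataclass
class SimulationConfig:
    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_case: int = 60
    n_control: int = 20
    wmh_volume_fraction: dict = field(
        default_factory=lambda: {"case": 0.06, "control": 0.002}
    )
    wmh_fraction_jitter: float = 0.3  # lognormal sigma of per-subject volume spread
    lacune_count_mean: dict = field(default_factory=lambda: {"case": 4.7, "control": 0.05})
    metrics: dict = field(default_factory=default_metric_models)
    penumbra_decay_mm: float = 3.0
    penumbra_extent_mm: float | None = None  # truncate planted effect beyond (None = no cutoff)
    cognition_coefficients: dict = field(default_factory=default_cognition_coefficients)
    seed: int = 0

    def validate(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be > 0")
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        for g, f in self.wmh_volume_fraction.items():
            if not (0.0 < f < 0.5):
                raise ValueError(f"wmh_volume_fraction[{g!r}] must lie in (0, 0.5), got {f}")
        if self.penumbra_decay_mm < 0:
            raise ValueError("penumbra_decay_mm must be >= 0")
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metric(s): {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metrics"] = {k: asdict(v) if isinstance(v, MetricModel) else v for k, v in self.metrics.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "metrics" in d:
            d["metrics"] = {
                k: v if isinstance(v, MetricModel) else MetricModel(**v)
                for k, v in d["metrics"].items()
            }
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "voxel_size_mm" in d:
            d["voxel_size_mm"] = tuple(d["voxel_size_mm"])
        return cls(**d)


# ---------------------------------------------------------------------------
# anatomy


def _ellipsoid(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = 0.0
    for g, sp, c, a in zip(grids, spacing, center_mm, semi_axes_mm):
        acc = acc + ((g * sp - c) / a) ** 2
    return acc <= 1.0


def build_anatomy(grid_shape, voxel_size_mm):
    """Deterministic brain / WM / ventricle geometry for a grid.

    Returns (brain, wm, ventricles, pv_weight) where ``pv_weight`` decays
    exponentially with distance from the ventricles and drives
    periventricular lesion seeding.
    """
    shape = tuple(grid_shape)
    sp = tuple(voxel_size_mm)
    extent = [n * s for n, s in zip(shape, sp)]
    center = [e / 2 for e in extent]
    brain = _ellipsoid(shape, sp, center, [0.45 * e for e in extent])
    wm = _ellipsoid(shape, sp, center, [0.36 * e for e in extent])
    # two lateral-ventricle stand-ins, offset along the first axis
    off = 0.10 * extent[0]
    vsize = [0.07 * extent[0], 0.22 * extent[1], 0.07 * extent[2]]
    vent = _ellipsoid(shape, sp, [center[0] - off, center[1], center[2]], vsize) | _ellipsoid(
        shape, sp, [center[0] + off, center[1], center[2]], vsize
    )
    vent &= brain
    wm &= ~vent
    dvent = ndimage.distance_transform_edt(~vent, sampling=sp)
    pv_weight = np.exp(-dvent / 8.0)
    return brain, wm, vent, pv_weight


# ---------------------------------------------------------------------------
# per-subject generation


def _place_wmh(rng, wm, brain, pv_weight, target_fraction, jitter, spacing):
    """Threshold a periventricularly weighted smooth random field to a target
    voxel count.  Raises LesionPlacementError when the grid cannot hold it."""
    n_brain = int(brain.sum())
    mult = float(np.exp(rng.normal(-0.5 * jitter**2, jitter))) if jitter > 0 else 1.0
    target_vox = int(round(target_fraction * mult * n_brain))
    if target_vox <= 0:
        return np.zeros(wm.shape, dtype=bool)
    eligible = wm
    n_eligible = int(eligible.sum())
    if target_vox > n_eligible:
        raise LesionPlacementError(
            f"requested lesion volume of {target_vox} voxels exceeds the "
            f"{n_eligible} eligible WM voxels on grid {wm.shape}; enlarge the "
            "grid or reduce wmh_volume_fraction"
        )
    sigma_vox = [4.0 / s for s in spacing]  # 4 mm smoothing
    fld = ndimage.gaussian_filter(rng.standard_normal(wm.shape), sigma=sigma_vox)
    fld = fld / fld.std() + 2.5 * pv_weight
    score = np.where(eligible, fld, -np.inf)
    flat = score.ravel()
    kth = flat.size - target_vox
    thresh = np.partition(flat, kth)[kth]
    wmh = score >= thresh
    # ties at the threshold could overshoot; trim deterministically
    if wmh.sum() > target_vox:
        extra = int(wmh.sum()) - target_vox
        idx = np.nonzero(wmh.ravel())[0][:extra]
        wmh_flat = wmh.ravel()
        wmh_flat[idx] = False
        wmh = wmh_flat.reshape(wm.shape)
    return wmh


def _place_lacunes(rng, wm, mean_count, spacing):
    n = int(rng.poisson(mean_count))
    lac = np.zeros(wm.shape, dtype=bool)
    if n == 0:
        return lac
    coords = np.nonzero(wm)
    if coords[0].size == 0:
        return lac
    picks = rng.integers(0, coords[0].size, size=n)
    # 6-connected cross: a lacune is a small cavity, 7 voxels here
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if i * i + j * j + k * k <= 1]
    for p in picks:
        c = (coords[0][p], coords[1][p], coords[2][p])
        for di, dj, dk in offsets:
            i, j, k = c[0] + di, c[1] + dj, c[2] + dk
            if 0 <= i < lac.shape[0] and 0 <= j < lac.shape[1] and 0 <= k < lac.shape[2]:
                lac[i, j, k] = True
    return lac & wm


def _clip_metric(name: str, values: np.ndarray) -> np.ndarray:
    if name == "chi_neg":
        return np.minimum(values, 0.0)
    if name == "chi_pos":
        return np.maximum(values, 0.0)
    if name == "fw":
        return np.clip(values, 0.0, 1.0)
    if name in ("md", "rd"):
        return np.maximum(values, 1e-6)
    return values


def simulate_cohort(config: SimulationConfig) -> list[SubjectRecord]:
    """Generate a deterministic synthetic cohort.

    Returns cases first, then controls.  Masks come with NAWM/rings not yet
    derived (that is the mask-ops stage's job).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape, sp = tuple(config.grid_shape), tuple(config.voxel_size_mm)
    brain, wm, _vent, pv_weight = build_anatomy(shape, sp)

    decay = config.penumbra_decay_mm
    extent = config.penumbra_extent_mm
    cog = config.cognition_coefficients

    subjects: list[SubjectRecord] = []
    specs = [("case", i) for i in range(config.n_case)] + [
        ("control", i) for i in range(config.n_control)
    ]
    for group, idx in specs:
        age = float(np.clip(rng.normal(55.0, 8.0), 30.0, 80.0))
        sex = int(rng.integers(0, 2))
        education = float(rng.integers(10, 19))

        wmh = _place_wmh(
            rng, wm, brain, pv_weight,
            config.wmh_volume_fraction[group], config.wmh_fraction_jitter, sp,
        )
        lacunes = _place_lacunes(rng, wm, config.lacune_count_mean[group], sp)
        lacunes &= ~wmh

        if wmh.any():
            dist = ndimage.distance_transform_edt(~wmh, sampling=sp)
            profile = np.where(wmh, 1.0, np.exp(-dist / decay) if decay > 0 else 0.0)
            if extent is not None:
                profile = np.where(~wmh & (dist > extent), 0.0, profile)
        else:
            profile = np.zeros(shape)
        profile = np.where(brain, profile, 0.0)

        maps: dict[str, VolumeMap] = {}
        intercepts: dict[str, float] = {}
        for name, model in config.metrics.items():
            intercept = float(rng.normal(0.0, model.subject_sd))
            intercepts[name] = intercept
            vals = (
                model.mean
                + intercept
                + model.lesion_effect * profile
                + model.noise_sd * rng.standard_normal(shape)
            )
            vals = _clip_metric(name, vals)
            vals = np.where(brain, vals, 0.0).astype(np.float32)
            maps[name] = VolumeMap(vals, sp, units=METRIC_UNITS.get(name, ""))

        # planted magnitude deficit of the myelin-sensitive metric in lesions:
        # |mean + shift + intercept| - |control-average mean| (both negative)
        deficit = 0.0
        if "chi_neg" in config.metrics:
            m = config.metrics["chi_neg"]
            shift = m.lesion_effect if (group == "case" and wmh.any()) else 0.0
            deficit = abs(m.mean + shift + intercepts["chi_neg"]) - abs(m.mean)
        cognition = (
            cog.get("intercept", 0.0)
            + cog.get("deficit", 0.0) * deficit
            + cog.get("age", 0.0) * (age - 55.0)
            + cog.get("sex", 0.0) * sex
            + cog.get("education", 0.0) * (education - 14.0)
            + cog.get("noise_sd", 0.0) * rng.standard_normal()
        )

        masks = MaskSet(wm=wm.copy(), wmh=wmh, lacunes=lacunes, voxel_size_mm=sp, brain=brain.copy())
        subjects.append(
            SubjectRecord(
                id=f"{group}-{idx:03d}",
                group=group,
                age=age,
                sex=sex,
                education=education,
                maps=maps,
                masks=masks,
                cognition=float(cognition),
                ground_truth={
                    "deficit": deficit,
                    "intercepts": intercepts,
                    "wmh_fraction": float(wmh.sum() / brain.sum()),
                    "lesion_effects": {k: v.lesion_effect for k, v in config.metrics.items()},
                },
            )
        )
    return subjects


def cohort_table(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Demographics/outcome table, one row per subject."""
    return pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "group": [s.group for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "education": [s.education for s in subjects],
            "cognition": [s.cognition for s in subjects],
            "wmh_fraction": [s.ground_truth.get("wmh_fraction", np.nan) for s in subjects],
            "lacune_count": [int(ndimage.label(s.masks.lacunes)[1]) for s in subjects],
        }
    )


def simulate_norm_table(age_bins, education_bins, seed: int) -> NormTable:
    """Random but plausible normative table over the given bin edges.

    Mean completion times increase with the age-bin midpoint and decrease
    mildly with education; SDs are positive draws.
    """
    age_bins = list(age_bins)
    education_bins = list(education_bins)
    if len(age_bins) < 2 or len(education_bins) < 2:
        raise ValueError("bins must be non-empty (need at least two edges each)")
    rng = np.random.default_rng(seed)
    rows = []
    for ai in range(len(age_bins) - 1):
        age_mid = (age_bins[ai] + age_bins[ai + 1]) / 2
        for ei in range(len(education_bins) - 1):
            edu_mid = (education_bins[ei] + education_bins[ei + 1]) / 2
            a_mean = 20.0 + 0.35 * age_mid - 0.5 * edu_mid + rng.normal(0, 2)
            b_mean = 45.0 + 0.9 * age_mid - 1.2 * edu_mid + rng.normal(0, 4)
            rows.append(
                {
                    "age_bin": ai,
                    "edu_bin": ei,
                    "tmt_a_mean": a_mean,
                    "tmt_a_sd": float(rng.uniform(6.0, 14.0)),
                    "tmt_b_mean": b_mean,
                    "tmt_b_sd": float(rng.uniform(15.0, 35.0)),
                }
            )
    return NormTable(age_bins, education_bins, pd.DataFrame(rows))
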