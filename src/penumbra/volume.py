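"""Core volume containers: scalar maps and mask bundles on a shared voxel grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Metric names used throughout the package.
METRICS = ("chi_neg", "chi_pos", "md", "rd", "fw")

#: Metrics whose ROI values are reported as absolute magnitudes.  The
#: diamagnetic susceptibility component is stored as a non-positive map but
#: analyzed as |value| so that a *lower* magnitude reads as a deficit.
MAGNITUDE_METRICS = frozenset({"chi_neg"})

#: Physical units per metric (ppm for susceptibility, mm^2/s for diffusivity).
METRIC_UNITS = {
    "chi_neg": "ppm",
    "chi_pos": "ppm",
    "md": "mm^2/s",
    "rd": "mm^2/s",
    "fw": "1",
}


class GridMismatchError(ValueError):
    """Raised when volumes expected to share a grid do not."""


@dataclass
class VolumeMap:
    """A single 3D scalar metric on a voxel grid with physical spacing.

    Parameters
    ----------
    values : ndarray
        3D array of metric values.
    voxel_size_mm : tuple of float
        Per-axis voxel spacing in millimetres.
    units : str
        Physical units of ``values``.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be 3 positive spacings, got {self.voxel_size_mm}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def same_grid(self, other: "VolumeMap") -> bool:
        return self.shape == other.shape and self.voxel_size_mm == other.voxel_size_mm


def check_same_grid(volumes: dict[str, np.ndarray]) -> tuple[int, ...]:
    """Verify that all named arrays share one shape; return it.

    Raises :class:`GridMismatchError` naming the offending volume.
    """
    shape = None
    ref_name = None
    for name, arr in volumes.items():
        arr = np.asarray(arr)
        if shape is None:
            shape, ref_name = arr.shape, name
        elif arr.shape != shape:
            raise GridMismatchError(
                f"volume {name!r} has shape {arr.shape}, expected {shape} (from {ref_name!r})"
            )
    if shape is None:
        raise ValueError("no volumes given")
    return shape


@dataclass
class MaskSet:
    """WM / WMH / lacune masks plus derived NAWM and penumbra ring labels.

    ``nawm`` and ``rings`` start as ``None`` and are filled by
    :func:`penumbra.masks.derive_nawm` / :func:`penumbra.masks.penumbra_rings`
    (or :meth:`derive`).  Ring label ``k`` marks the distance interval
    ``[step*(k-1), step*k)`` millimetres from the lesion boundary.
    """

    wm: np.ndarray
    wmh: np.ndarray
    lacunes: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    nawm: np.ndarray | None = None
    rings: np.ndarray | None = None
    brain: np.ndarray | None = None

    def __post_init__(self) -> None:
        vols = {"wm": self.wm, "wmh": self.wmh, "lacunes": self.lacunes}
        if self.brain is not None:
            vols["brain"] = self.brain
        check_same_grid(vols)
        self.wm = np.asarray(self.wm, dtype=bool)
        self.wmh = np.asarray(self.wmh, dtype=bool)
        self.lacunes = np.asarray(self.lacunes, dtype=bool)
        if self.brain is not None:
            self.brain = np.asarray(self.brain, dtype=bool)
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.wm.shape

    def derive(self, step_mm: float = 2.0, max_mm: float = 10.0) -> "MaskSet":
        """Fill ``nawm`` and ``rings`` in place; returns self for chaining."""
        from . import masks as _masks  # local import to avoid a cycle

        self.nawm = _masks.derive_nawm(self.wm, self.wmh, self.lacunes)
        if self.wmh.any():
            self.rings = _masks.penumbra_rings(
                self.wmh, self.nawm, self.voxel_size_mm, step_mm=step_mm, max_mm=max_mm
            )
        else:
            self.rings = np.zeros(self.shape, dtype=np.int16)
        return self

    def validate(self) -> None:
        """Assert the disjointness invariants; raises AssertionError on violation."""
        if self.nawm is not None:
            assert not (self.nawm & self.wmh).any(), "NAWM overlaps WMH"
            assert not (self.nawm & self.lacunes).any(), "NAWM overlaps lacunes"
        if self.rings is not None:
            assert self.nawm is not None
            in_ring = self.rings > 0
            assert (self.nawm | ~in_ring).all(), "ring voxel outside NAWM"
            assert not (in_ring & self.wmh).any(), "ring voxel inside WMH"
            assert not (in_ring & self.lacunes).any(), "ring voxel inside a lacune"


@dataclass
class SubjectRecord:
    """One subject: demographics, metric maps, masks, cognition, ground truth."""

    id: str
    group: str  # "case" | "control"
    age: float
    sex: int  # 0/1 indicator (1 = female)
    education: float
    maps: dict[str, VolumeMap]
    masks: MaskSet
    cognition: float = float("nan")
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be 'case' or 'control', got {self.group!r}")
        for name, vm in self.maps.items():
            if vm.shape != self.masks.shape:
                raise GridMismatchError(
                    f"map {name!r} shape {vm.shape} != mask shape {self.masks.shape}"
                )
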