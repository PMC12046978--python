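"""Spatially matched difference scores against a control-group reference atlas.

A subject's ROI value is compared to the control-group voxelwise mean averaged
over the *same* subject-specific ROI, so anatomical location is held constant.
A covariate adjustment can then re-express each case's value as the group-mean
prediction plus the subject residual, before the reference is subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import VolumeMap, check_same_grid

__all__ = [
    "ReferenceAtlas",
    "DifferenceScore",
    "cn_reference_map",
    "roi_difference_score",
    "adjusted_difference_scores",
]


@dataclass
class ReferenceAtlas:
    """Voxelwise control-group mean maps, one per metric."""

    maps: dict[str, VolumeMap]
    n_controls: int


@dataclass
class DifferenceScore:
    subject_id: str
    roi: str
    metric: str
    raw_value: float
    reference_value: float

    @property
    def diff(self) -> float:
        return self.raw_value - self.reference_value


def cn_reference_map(control_maps: list[VolumeMap]) -> VolumeMap:
    """Voxelwise arithmetic mean over control subjects for one metric."""
    if len(control_maps) == 0:
        raise ValueError("need at least one control map")
    check_same_grid({f"control[{i}]": m.values for i, m in enumerate(control_maps)})
    acc = np.zeros(control_maps[0].shape, dtype=np.float64)
    for m in control_maps:
        acc += m.values
    acc /= len(control_maps)
    return VolumeMap(acc, control_maps[0].voxel_size_mm, units=control_maps[0].units)


def roi_difference_score(
    subject_map: VolumeMap,
    roi_mask: np.ndarray,
    atlas_map: VolumeMap,
    subject_id: str = "",
    roi: str = "",
    metric: str = "",
    transform=None,
) -> DifferenceScore:
    """Subject ROI mean minus the atlas mean over the same ROI.

    ``transform`` (e.g. ``abs`` for magnitude metrics) is applied to both ROI
    means before differencing, so the sign convention is preserved: a negative
    difference means the subject lies below the control average.
    """
    roi_mask = np.asarray(roi_mask, bool)
    check_same_grid(
        {"subject": subject_map.values, "roi": roi_mask, "atlas": atlas_map.values}
    )
    if not roi_mask.any():
        raise ValueError(f"empty ROI {roi!r} for subject {subject_id!r}")
    raw = float(np.asarray(subject_map.values, dtype=float)[roi_mask].mean())
    ref = float(np.asarray(atlas_map.values, dtype=float)[roi_mask].mean())
    if transform is not None:
        raw, ref = float(transform(raw)), float(transform(ref))
    return DifferenceScore(subject_id, roi, metric, raw, ref)


def adjusted_difference_scores(
    values,
    covariates: pd.DataFrame,
    references,
) -> np.ndarray:
    """Covariate-adjusted difference scores for the case group.

    Fits OLS of ``values`` on ``covariates`` (with intercept) within the case
    group, then returns for each case ``i``::

        adjusted_i = (b0 + sum_j b_j * xbar_j) + resid_i - reference_i

    i.e. the prediction at the case-group mean covariate vector plus the
    subject residual, minus the subject-specific reference.  The case-group
    mean of (adjusted + reference) equals the mean raw value.
    """
    y = np.asarray(values, dtype=float).ravel()
    refs = np.asarray(references, dtype=float).ravel()
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(np.asarray(covariates, dtype=float))
    if len(covariates) != y.size or refs.size != y.size:
        raise ValueError("values, covariates and references must have one row per case")
    if covariates.isna().any().any():
        bad = list(covariates.columns[covariates.isna().any()])
        raise ValueError(f"missing covariate entries in columns {bad}")

    Xc = covariates.to_numpy(dtype=float)
    n, p = Xc.shape
    if n <= p + 1:
        raise ValueError(f"n = {n} cases cannot support p = {p} covariates plus intercept")
    X = np.column_stack([np.ones(n), Xc])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the collinear columns via the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad_idx = [i - 1 for i in np.nonzero(diag <= tol)[0] if i > 0]
        bad = [str(covariates.columns[i]) for i in bad_idx] or list(map(str, covariates.columns))
        raise ValueError(f"rank-deficient covariate matrix; collinear column(s): {bad}")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    xbar = np.concatenate([[1.0], Xc.mean(axis=0)])
    pred_at_mean = float(xbar @ beta)
    return pred_at_mean + resid - refs
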