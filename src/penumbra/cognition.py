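"""Processing-speed compound from timed test scores.

Raw completion times (seconds; higher = slower) are stratified against a
normative table keyed by age and education bins, averaged across the two test
parts, power-transformed (Box-Cox, MLE lambda on a grid), negated so that
higher = better, and z-standardized against the control group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NormTable",
    "CognitionResult",
    "stratify_tmt",
    "processing_speed_compound",
]


@dataclass
class NormTable:
    """Per-stratum normative means and SDs for TMT-A and TMT-B times.

    Strata are the cartesian product of half-open age bins and education bins
    defined by ascending edge lists; a value ``v`` falls in bin ``i`` when
    ``edges[i] <= v < edges[i+1]``.
    """

    age_edges: list[float]
    education_edges: list[float]
    table: pd.DataFrame  # columns: age_bin, edu_bin, tmt_{a,b}_{mean,sd}

    def __post_init__(self) -> None:
        if len(self.age_edges) < 2 or len(self.education_edges) < 2:
            raise ValueError("need at least one age bin and one education bin")
        for col in ("tmt_a_sd", "tmt_b_sd"):
            if (self.table[col] <= 0).any():
                raise ValueError(f"non-positive SD in column {col}")
        self._lut = self.table.set_index(["age_bin", "edu_bin"]).sort_index()

    def n_strata(self) -> int:
        return (len(self.age_edges) - 1) * (len(self.education_edges) - 1)

    def locate(self, age: float, education: float) -> tuple[int, int]:
        ai = int(np.searchsorted(self.age_edges, age, side="right")) - 1
        ei = int(np.searchsorted(self.education_edges, education, side="right")) - 1
        if not (0 <= ai < len(self.age_edges) - 1 and 0 <= ei < len(self.education_edges) - 1):
            nearest = (
                int(np.clip(ai, 0, len(self.age_edges) - 2)),
                int(np.clip(ei, 0, len(self.education_edges) - 2)),
            )
            raise ValueError(
                f"covariates (age={age}, education={education}) fall outside all "
                f"strata; nearest stratum is (age_bin={nearest[0]}, edu_bin={nearest[1]})"
            )
        return ai, ei

    def row(self, age: float, education: float) -> pd.Series:
        return self._lut.loc[self.locate(age, education)]

    def to_tsv(self, path) -> None:
        # layout: two comment lines carrying the bin edges, then a TSV body
        with open(path, "w") as fh:
            fh.write("# age_edges\t" + "\t".join(map(str, self.age_edges)) + "\n")
            fh.write("# education_edges\t" + "\t".join(map(str, self.education_edges)) + "\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "NormTable":
        with open(path) as fh:
            age_edges = [float(x) for x in fh.readline().split("\t")[1:]]
            edu_edges = [float(x) for x in fh.readline().split("\t")[1:]]
            table = pd.read_csv(fh, sep="\t")
        return cls(age_edges, edu_edges, table)


def stratify_tmt(
    raw_seconds: float, age: float, education: float, norms: NormTable, part: str = "a"
) -> float:
    """Stratified score: (raw - stratum mean) / stratum SD for the given part."""
    if raw_seconds <= 0:
        raise ValueError("completion time must be positive")
    if part not in ("a", "b"):
        raise ValueError("part must be 'a' or 'b'")
    row = norms.row(age, education)
    return float((raw_seconds - row[f"tmt_{part}_mean"]) / row[f"tmt_{part}_sd"])


@dataclass
class CognitionResult:
    compound_raw: np.ndarray
    compound: np.ndarray
    lmbda: float
    shift: float
    control_mean: float
    control_sd: float


def boxcox_mle_lambda(x: np.ndarray, grid=None, refine: int = 2) -> float:
    """Box-Cox lambda maximizing the profile log-likelihood over a grid."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires positive data")
    if grid is None:
        grid = np.linspace(-3.0, 3.0, 121)
    ll = np.array([sps.boxcox_llf(l, x) for l in grid])
    best = int(np.argmax(ll))
    lam = float(grid[best])
    step = float(grid[1] - grid[0])
    for _ in range(refine):
        fine = np.linspace(lam - step, lam + step, 41)
        ll = np.array([sps.boxcox_llf(l, x) for l in fine])
        best = int(np.argmax(ll))
        lam = float(fine[best])
        step = float(fine[1] - fine[0])
    return lam


def processing_speed_compound(
    strat_a,
    strat_b,
    is_control,
    lmbda: float | None = None,
) -> CognitionResult:
    """Compound processing-speed score across a pooled case+control sample.

    The per-subject compound is the mean of the two stratified times, shifted
    to positivity, Box-Cox transformed (MLE lambda over a grid unless a fixed
    ``lmbda`` is supplied), negated so that higher = faster, and standardized
    to control mean 0 / SD 1.
    """
    a = np.asarray(strat_a, dtype=float)
    b = np.asarray(strat_b, dtype=float)
    ctrl = np.asarray(is_control, bool)
    if not (a.size == b.size == ctrl.size):
        raise ValueError("strat_a, strat_b and is_control must have equal length")
    if not np.isfinite(a).all() or not np.isfinite(b).all():
        raise ValueError("stratified scores must be finite")
    if ctrl.sum() < 2:
        raise ValueError("need at least two controls for standardization")

    compound_raw = (a + b) / 2.0
    if compound_raw.std(ddof=1) == 0:
        raise ValueError("degenerate compound distribution (zero variance)")
    shift = 1.0 - compound_raw.min()
    x = compound_raw + shift
    if lmbda is None:
        lmbda = boxcox_mle_lambda(x)
    if lmbda == 0:
        bc = np.log(x)
    else:
        bc = (x**lmbda - 1.0) / lmbda
    oriented = -bc  # slower (larger time) => lower score
    mu = oriented[ctrl].mean()
    sd = oriented[ctrl].std(ddof=1)
    if sd == 0:
        raise ValueError("control scores degenerate: cannot standardize")
    compound = (oriented - mu) / sd
    return CognitionResult(
        compound_raw=compound_raw,
        compound=compound,
        lmbda=float(lmbda),
        shift=float(shift),
        control_mean=float(mu),
        control_sd=float(sd),
    )
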