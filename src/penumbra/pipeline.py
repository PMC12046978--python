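"""End-to-end orchestration: simulate/load -> masks -> matched scores ->
penumbra gradient -> correlations -> ridge cognition models -> voxelwise maps.

Each stage is a plain function over in-memory cohorts so tests can exercise
them directly; :func:`run_pipeline` wires them together and writes the report
bundle (TSV tables, NIfTI maps, JSON manifest).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .scores import ReferenceAtlas, adjusted_difference_scores, cn_reference_map, roi_difference_score
from .simulate import SimulationConfig, cohort_table, simulate_cohort
from .stats import (
    one_sample_test,
    pearson_test,
    ridge_fit,
    standardize,
    voxelwise_group_glm,
    welch_two_sample_test,
)
from .volume import MAGNITUDE_METRICS, SubjectRecord

log = logging.getLogger("penumbra")

#: Covariate metrics entering the adjustment model per target metric
#: (demographics age/sex/education are always included).
ADJUSTMENT_COVARIATES = {
    "chi_neg": ["chi_pos", "fw"],
    "chi_pos": ["fw"],
    "md": ["chi_pos"],
    "rd": ["chi_pos"],
    "fw": ["chi_pos"],
}

DEMOGRAPHICS = ["age", "sex", "education"]


@dataclass
class RunConfig:
    mode: str = "simulate"  # "simulate" | "load"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_dir: str | None = None
    output_dir: str = "penumbra_out"
    ring_step_mm: float = 2.0
    ring_max_mm: float = 10.0
    alpha: float = 0.05
    extent_k: int = 10
    connectivity: int = 26
    ridge_lambda: str | float = "auto"
    run_voxelwise: bool = True
    save_volumes: bool = True
    seed: int | None = None

    def validate(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"mode must be 'simulate' or 'load', got {self.mode!r}")
        if self.mode == "load":
            if self.input_dir is None or not Path(self.input_dir).exists():
                raise FileNotFoundError(f"input_dir {self.input_dir!r} does not exist")
        if self.seed is not None:
            self.simulation.seed = int(self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d


def _transform_for(metric: str):
    return abs if metric in MAGNITUDE_METRICS else None


def n_rings(cfg: RunConfig) -> int:
    return int(round(cfg.ring_max_mm / cfg.ring_step_mm))


# ---------------------------------------------------------------------------
# stages


def derive_all_masks(subjects: list[SubjectRecord], step_mm: float = 2.0, max_mm: float = 10.0) -> None:
    for s in subjects:
        s.masks.derive(step_mm=step_mm, max_mm=max_mm)
        s.masks.validate()


def build_reference_atlas(subjects: list[SubjectRecord]) -> ReferenceAtlas:
    controls = [s for s in subjects if s.group == "control"]
    if not controls:
        raise ValueError("no control subjects to build a reference atlas from")
    metrics = sorted(controls[0].maps)
    maps = {m: cn_reference_map([c.maps[m] for c in controls]) for m in metrics}
    return ReferenceAtlas(maps=maps, n_controls=len(controls))


def _subject_rois(s: SubjectRecord, k: int) -> dict[str, np.ndarray]:
    """Analysis ROIs for one subject.  Lacunes are excluded everywhere."""
    clean = ~s.masks.lacunes
    rois: dict[str, np.ndarray] = {"global_wm": s.masks.wm & clean}
    if s.masks.nawm is not None and s.masks.nawm.any():
        rois["nawm"] = s.masks.nawm
    if s.masks.wmh.any():
        rois["wmh"] = s.masks.wmh & clean
    if s.masks.rings is not None:
        for r in range(1, k + 1):
            ring = s.masks.rings == r
            if ring.any():
                rois[f"ring{r}"] = ring
    return rois


def compute_difference_scores(
    subjects: list[SubjectRecord], atlas: ReferenceAtlas, k: int = 5
) -> pd.DataFrame:
    """Long table of per-subject, per-ROI, per-metric scores.

    ``diff`` carries meaning for subject-specific ROIs of cases; for fixed
    ROIs (global WM) and for controls the ``raw`` column is what downstream
    group comparisons consume.
    """
    rows = []
    for s in subjects:
        rois = _subject_rois(s, k)
        for metric, vm in s.maps.items():
            tr = _transform_for(metric)
            for roi_name, mask in rois.items():
                ds = roi_difference_score(
                    vm, mask, atlas.maps[metric],
                    subject_id=s.id, roi=roi_name, metric=metric, transform=tr,
                )
                rows.append(
                    {
                        "subject_id": ds.subject_id,
                        "group": s.group,
                        "roi": roi_name,
                        "metric": metric,
                        "n_voxels": int(mask.sum()),
                        "raw": ds.raw_value,
                        "reference": ds.reference_value,
                        "diff": ds.diff,
                    }
                )
    return pd.DataFrame(rows)


def adjust_scores(
    scores: pd.DataFrame,
    table: pd.DataFrame,
    covariate_sets: dict | None = None,
) -> pd.DataFrame:
    """Add an ``adjusted_diff`` column for case rows of subject-specific ROIs.

    For each (metric, ROI) cell the case raw values are regressed on
    demographics plus the configured covariate metrics' raw values in the same
    ROI; the adjusted difference re-centers predictions at the case-group mean
    covariate vector before subtracting the subject-specific reference.
    """
    if covariate_sets is None:
        covariate_sets = ADJUSTMENT_COVARIATES
    scores = scores.copy()
    scores["adjusted_diff"] = np.nan
    demo = table.set_index("id")[DEMOGRAPHICS]
    cases = scores[scores["group"] == "case"]
    metrics_present = set(scores["metric"].unique())

    for (metric, roi), cell in cases.groupby(["metric", "roi"]):
        if roi == "global_wm":
            continue  # fixed ROI: plain group comparison, no difference scoring
        sids = cell["subject_id"].to_numpy()
        cov = demo.loc[sids].reset_index(drop=True).copy()
        for cm in covariate_sets.get(metric, []):
            if cm not in metrics_present:
                continue
            other = scores[
                (scores["metric"] == cm)
                & (scores["roi"] == roi)
                & scores["subject_id"].isin(sids)
            ].set_index("subject_id")["raw"]
            if other.index.size != sids.size:
                continue  # covariate metric missing for some subjects in this ROI
            cov[cm] = other.loc[sids].to_numpy()
        try:
            adj = adjusted_difference_scores(
                cell["raw"].to_numpy(), cov, cell["reference"].to_numpy()
            )
        except ValueError as exc:
            log.warning("adjustment skipped for metric=%s roi=%s: %s", metric, roi, exc)
            continue
        scores.loc[cell.index, "adjusted_diff"] = adj
    return scores


def penumbra_table(scores: pd.DataFrame, k: int = 5, use_adjusted: bool = True) -> pd.DataFrame:
    """One-sample tests (mu=0) of case difference scores per ROI per metric.

    Rows cover WMH, NAWM and each penumbra ring; columns mirror the
    (t, df, p, d, 95% CI) layout.
    """
    col = "adjusted_diff" if use_adjusted else "diff"
    rois = ["wmh", "nawm"] + [f"ring{r}" for r in range(1, k + 1)]
    rows = []
    cases = scores[scores["group"] == "case"]
    for metric, mcell in cases.groupby("metric"):
        for roi in rois:
            vals = mcell.loc[mcell["roi"] == roi, col].dropna().to_numpy()
            if vals.size < 2:
                continue
            res = one_sample_test(vals)
            rows.append(
                {
                    "metric": metric,
                    "roi": roi,
                    "n": res.n,
                    "mean": float(vals.mean()),
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "d": res.d,
                    "ci_low": res.ci[0],
                    "ci_high": res.ci[1],
                }
            )
    return pd.DataFrame(rows)


def correlation_tables(scores: pd.DataFrame, base_metric: str = "chi_neg") -> pd.DataFrame:
    """Pairwise Pearson correlations of the base metric with every other one.

    Cases are correlated on difference scores within NAWM and WMH; controls on
    plain NAWM means (controls carry too few lesions for a WMH ROI).
    """
    rows = []
    metrics = [m for m in scores["metric"].unique() if m != base_metric]

    def _corr(sub: pd.DataFrame, group: str, roi: str, col: str):
        base = sub[(sub["metric"] == base_metric) & (sub["roi"] == roi)].set_index("subject_id")[col]
        for m in metrics:
            other = sub[(sub["metric"] == m) & (sub["roi"] == roi)].set_index("subject_id")[col]
            common = base.index.intersection(other.index)
            if common.size < 3:
                continue
            x, y = base.loc[common], other.loc[common]
            if x.std() == 0 or y.std() == 0:
                continue
            r, t, df, p = pearson_test(x, y)
            rows.append(
                {"group": group, "roi": roi, "metric_x": base_metric, "metric_y": m,
                 "n": int(common.size), "r": r, "t": t, "df": df, "p": p}
            )

    cases = scores[scores["group"] == "case"]
    for roi in ("nawm", "wmh"):
        _corr(cases, "case", roi, "diff")
    controls = scores[scores["group"] == "control"]
    _corr(controls, "control", "nawm", "raw")
    return pd.DataFrame(rows)


RIDGE_ROIS = ("global_wm", "nawm", "wmh")


def ridge_models(
    scores: pd.DataFrame,
    table: pd.DataFrame,
    rois=RIDGE_ROIS,
    lam: str | float = "auto",
    outcome: str = "cognition",
) -> dict[str, "pd.DataFrame"]:
    """Ridge regressions of the outcome on per-ROI metric scores (cases only).

    Global-WM models use plain ROI means; subject-specific ROIs use adjusted
    difference scores.  Lesion volume fraction and demographics complete the
    predictor set.  Returns one coefficient table per ROI with the fitted
    lambda, effective df and model R^2 attached as attributes.
    """
    out: dict[str, pd.DataFrame] = {}
    cases = table[table["group"] == "case"].set_index("id")
    cscores = scores[scores["group"] == "case"]
    metrics = sorted(scores["metric"].unique())
    for roi in rois:
        col = "raw" if roi == "global_wm" else "adjusted_diff"
        wide = cscores[cscores["roi"] == roi].pivot_table(
            index="subject_id", columns="metric", values=col
        )
        wide = wide.dropna()
        if wide.empty:
            continue
        sids = wide.index
        X_parts = {m: wide[m].to_numpy() for m in metrics if m in wide}
        if "wmh_fraction" in cases.columns:
            X_parts["wmh_volume"] = cases.loc[sids, "wmh_fraction"].to_numpy()
        for c in DEMOGRAPHICS:
            X_parts[c] = cases.loc[sids, c].to_numpy(dtype=float)
        names = list(X_parts)
        X = np.column_stack([X_parts[n] for n in names])
        y = cases.loc[sids, outcome].to_numpy(dtype=float)
        if y.size <= X.shape[1] + 1:
            log.warning("ridge model skipped for roi=%s: n=%d too small", roi, y.size)
            continue
        Xs = standardize(X)
        yc = y - y.mean()
        lam_val = None if lam == "auto" else float(lam)
        fit = ridge_fit(Xs, yc, lam=lam_val, names=names)
        frame = fit.to_frame()
        frame.attrs["lambda"] = fit.lam
        frame.attrs["edf"] = fit.edf
        frame.attrs["r2"] = fit.r2
        frame.attrs["n"] = fit.n
        out[roi] = frame
    return out


def frequency_maps(subjects: list[SubjectRecord]) -> dict[str, dict]:
    """Per-group lesion frequency maps (percent) for WMH and lacunes."""
    from .masks import lesion_frequency_map

    out: dict[str, dict] = {}
    for group in ("case", "control"):
        subs = [s for s in subjects if s.group == group]
        if not subs:
            continue
        sp = subs[0].masks.voxel_size_mm
        out[group] = {
            "wmh": lesion_frequency_map([s.masks.wmh for s in subs], sp),
            "lacunes": lesion_frequency_map([s.masks.lacunes for s in subs], sp),
        }
    return out


def voxelwise_maps(subjects: list[SubjectRecord], cfg: RunConfig) -> dict[str, object]:
    """Voxelwise case-vs-control contrast per metric within the shared WM."""
    analysis_mask = None
    for s in subjects:
        m = s.masks.wm & ~s.masks.lacunes
        analysis_mask = m if analysis_mask is None else (analysis_mask & m)
    group = np.array([1.0 if s.group == "case" else 0.0 for s in subjects])
    results = {}
    for metric in sorted(subjects[0].maps):
        data = np.stack([np.asarray(s.maps[metric].values, dtype=float) for s in subjects])
        results[metric] = voxelwise_group_glm(
            data, group, analysis_mask,
            alpha=cfg.alpha, extent_k=cfg.extent_k, connectivity=cfg.connectivity,
        )
    return results


def cohort_report(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group demographics with Welch-t / chi-square group comparisons."""
    required = {"group", "age", "sex", "education"}
    missing = sorted(required - set(table.columns))
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    cn = table[table["group"] == "control"]
    cad = table[table["group"] == "case"]
    rows = []
    numeric = [c for c in ("age", "education", "cognition", "wmh_fraction", "lacune_count")
               if c in table.columns]
    for col in numeric:
        a, b = cn[col].dropna(), cad[col].dropna()
        row = {
            "variable": col,
            "control_mean": a.mean(),
            "control_iqr": a.quantile(0.75) - a.quantile(0.25),
            "case_mean": b.mean(),
            "case_iqr": b.quantile(0.75) - b.quantile(0.25),
        }
        try:
            res = welch_two_sample_test(a.to_numpy(), b.to_numpy())
            row.update({"stat": res.t, "df": res.df, "p": res.p, "d": res.d, "test": "welch_t"})
        except ValueError:
            row.update({"stat": np.nan, "df": np.nan, "p": np.nan, "d": np.nan, "test": "welch_t"})
        rows.append(row)
    # categorical: sex via Pearson chi-square
    from scipy.stats import chi2_contingency

    ct = pd.crosstab(table["group"], table["sex"])
    if ct.shape == (2, 2) and (ct.sum(axis=0) > 0).all() and (ct.sum(axis=1) > 0).all():
        chi2, p, dof, _ = chi2_contingency(ct, correction=False)
    else:
        chi2, p, dof = np.nan, np.nan, np.nan
    rows.append(
        {
            "variable": "sex_pct_female",
            "control_mean": 100 * cn["sex"].mean(),
            "control_iqr": np.nan,
            "case_mean": 100 * cad["sex"].mean(),
            "case_iqr": np.nan,
            "stat": chi2, "df": dof, "p": p, "d": np.nan, "test": "chi_square",
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns in-memory results."""
    from . import io as pio

    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_log: list[dict] = []

    def _stage(name, **info):
        log.info("stage %s: %s", name, info)
        stage_log.append({"stage": name, **info})

    if cfg.mode == "simulate":
        subjects = simulate_cohort(cfg.simulation)
        table = cohort_table(subjects)
        _stage("simulate", n=len(subjects), seed=cfg.simulation.seed)
    else:
        subjects = pio.load_cohort(cfg.input_dir)
        table = pd.read_csv(Path(cfg.input_dir) / "cohort.tsv", sep="\t")
        _stage("load", n=len(subjects), input_dir=str(cfg.input_dir))

    k = n_rings(cfg)
    derive_all_masks(subjects, step_mm=cfg.ring_step_mm, max_mm=cfg.ring_max_mm)
    _stage("masks", rings=k)

    freq = frequency_maps(subjects)
    if cfg.save_volumes:
        for group, d in freq.items():
            for kind, vm in d.items():
                pio.save_volume(vm, outdir / f"frequency_{kind}_{group}.nii.gz", dtype=np.float32)
    _stage("frequency_maps", groups=list(freq))

    atlas = build_reference_atlas(subjects)
    scores = compute_difference_scores(subjects, atlas, k=k)
    scores = adjust_scores(scores, table)
    scores.to_csv(outdir / "difference_scores.tsv", sep="\t", index=False)
    _stage("difference_scores", rows=len(scores), sha=_hash_frame(scores))

    pen = penumbra_table(scores, k=k)
    pen.to_csv(outdir / "penumbra_table.tsv", sep="\t", index=False)
    _stage("penumbra", rows=len(pen), sha=_hash_frame(pen))

    corr = correlation_tables(scores)
    corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    _stage("correlations", rows=len(corr))

    ridge = ridge_models(scores, table, lam=cfg.ridge_lambda)
    ridge_meta = {}
    for roi, frame in ridge.items():
        frame.to_csv(outdir / f"ridge_{roi}.tsv", sep="\t", index=False)
        ridge_meta[roi] = {
            "lambda": frame.attrs["lambda"],
            "edf": frame.attrs["edf"],
            "r2": frame.attrs["r2"],
            "n": frame.attrs["n"],
        }
    _stage("ridge", rois=list(ridge), meta=ridge_meta)

    voxelwise = {}
    if cfg.run_voxelwise:
        voxelwise = voxelwise_maps(subjects, cfg)
        cluster_frames = []
        for metric, res in voxelwise.items():
            if cfg.save_volumes:
                sp = subjects[0].masks.voxel_size_mm
                from .volume import VolumeMap

                pio.save_volume(VolumeMap(res.t_map, sp), outdir / f"tmap_{metric}.nii.gz",
                                dtype=np.float32)
            if not res.clusters.empty:
                cf = res.clusters.copy()
                cf.insert(0, "metric", metric)
                cluster_frames.append(cf)
        clusters = (
            pd.concat(cluster_frames, ignore_index=True) if cluster_frames else pd.DataFrame()
        )
        clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        _stage("voxelwise", metrics=list(voxelwise))

    report = cohort_report(table)
    report.to_csv(outdir / "cohort_report.tsv", sep="\t", index=False)
    table.to_csv(outdir / "cohort.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.simulation.seed if cfg.mode == "simulate" else None,
        "stages": stage_log,
    }
    pio.write_manifest(outdir / "manifest.json", manifest)

    return {
        "subjects": subjects,
        "table": table,
        "atlas": atlas,
        "scores": scores,
        "penumbra": pen,
        "correlations": corr,
        "ridge": ridge,
        "frequency": freq,
        "voxelwise": voxelwise,
        "report": report,
        "manifest": manifest,
    }
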