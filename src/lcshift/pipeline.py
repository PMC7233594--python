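"""End-to-end orchestration: landmarks -> geometry -> visual-field
classification -> cohort assembly -> statistics -> report bundle.

The report bundle is text-only and deterministic under a fixed seed: CSV
tables, a machine-readable JSON summary, a plain-text tree rendering and an
SVG polar scatter of trunk angular deviation by initial hemisphere.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, io as lio, vf
from .ctree import ctree_fit
from .grid import build_grid_242
from .simulate import SimConfig, simulate_cohort
from .stats import GroupSummary, anova_from_summary, chisq_test, screen_and_fit
from .types import EyeSeries, LandmarkRecord

__all__ = ["PipelineConfig", "exclusion_filter", "build_cohort_table", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Either a simulation block or the three input paths must be given."""

    out_dir: str | Path = "lcshift_out"
    simulate: SimConfig | None = None
    landmarks_path: str | Path | None = None
    exams_path: str | Path | None = None
    covariates_path: str | Path | None = None
    cluster_rule: str = "methods"
    adjacency: int = 8
    confirm_n: int = 2
    alpha_level: float = 0.05
    screen_threshold: float = 0.20
    ctree_n_perm: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = any(p is not None for p in (self.landmarks_path, self.exams_path, self.covariates_path))
        if (self.simulate is None) == (not has_paths):
            raise ValueError("exactly one of a simulate block or input paths must be provided")
        if self.cluster_rule not in vf.RULES:
            raise ValueError(f"unknown cluster rule {self.cluster_rule!r}")

    @property
    def rule(self) -> vf.ClusterRule:
        base = vf.RULES[self.cluster_rule]
        return dataclasses.replace(base, connectivity=self.adjacency)


#: eligibility rules applied before analysis; order is the reporting order
ELIGIBILITY_RULES = (
    ("myopia", "axial_length", lambda v: v >= 24.0),
    ("high_tension", "highest_iop", lambda v: v > 21.0),
    ("followup", "followup_years", lambda v: v >= 2.0),
    ("image_quality", "quality_score", lambda v: v >= 15.0),
)


def exclusion_filter(covariates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply eligibility rules; returns (eligible rows, exclusion log).

    Rules: axial length >= 24 mm (myopia), highest IOP > 21 mmHg (high-tension
    criterion), follow-up >= 2 years, and — when a ``quality_score`` column is
    present — imaging quality >= 15. A missing required covariate excludes the
    eye with reason ``missing:<covariate>``.
    """
    log = []
    keep = []
    for _, row in covariates.iterrows():
        reason = None
        for name, col, ok in ELIGIBILITY_RULES:
            if col not in covariates.columns:
                if name == "image_quality":
                    continue  # quality flag is optional
                reason = f"missing:{col}"
                break
            v = row[col]
            if pd.isna(v):
                reason = f"missing:{col}"
                break
            if not ok(float(v)):
                reason = name
                break
        if reason is None:
            keep.append(True)
        else:
            keep.append(False)
            log.append({"eye_id": row.get("eye_id", ""), "rule": reason})
    return covariates[np.array(keep, dtype=bool)].copy(), pd.DataFrame(log, columns=["eye_id", "rule"])


def select_study_eyes(covariates: pd.DataFrame, seed: int) -> pd.DataFrame:
    """One study eye per subject, chosen by a seeded draw keyed by subject id.

    Applies only when a ``subject_id`` column is present; otherwise every row
    is its own subject.
    """
    if "subject_id" not in covariates.columns:
        return covariates
    picked = []
    for sid, g in covariates.groupby("subject_id", sort=True):
        rng = np.random.default_rng([seed % (2**31), abs(hash(str(sid))) % (2**31)])
        picked.append(g.iloc[int(rng.integers(len(g)))])
    return pd.DataFrame(picked).reset_index(drop=True)


def build_cohort_table(
    records: list[LandmarkRecord],
    series: list[EyeSeries],
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge geometry, covariates and hemisphere labels into one row per eye.

    Eyes whose hemisphere cannot be determined (fewer than two reliable exams)
    are dropped and logged.
    """
    grid = build_grid_242()
    rule = config.rule
    by_id = {s.eye_id: s for s in series}
    rows, dropped = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rec in records:
            s = by_id.get(rec.eye_id)
            if s is None:
                dropped.append({"eye_id": rec.eye_id, "rule": "no_exams"})
                continue
            geo = geometry.summarize_geometry(rec)
            init = vf.initial_hemisphere(s, rule, config.confirm_n, grid)
            fin = vf.final_hemisphere(s, rule, config.confirm_n, grid)
            if init == "undetermined":
                dropped.append({"eye_id": rec.eye_id, "rule": "undetermined_hemisphere"})
                continue
            reliable = [e for e in s.sorted_exams() if vf.is_reliable(e)]
            md_final = reliable[-1].md_db if reliable else None
            rows.append(
                {
                    "eye_id": rec.eye_id,
                    "alpha_deg": geo.alpha_deg,
                    "abs_alpha_deg": None if geo.alpha_deg is None else abs(geo.alpha_deg),
                    "shift_index": geo.shift_index,
                    "shift_group": geo.shift_group,
                    "beta_deg": geo.beta_deg,
                    "obliqueness_deg": geo.obliqueness_deg,
                    "lcd_um": geo.lcd_um,
                    "bmo_area_mm2": geo.bmo_area_mm2,
                    **{k: s.covariates.get(k) for k in
                       ("age", "female", "highest_iop", "axial_length", "md0", "followup_years")},
                    "md_final": md_final,
                    "initial_hemisphere": init,
                    "final_hemisphere": fin,
                }
            )
    return (
        pd.DataFrame(rows),
        pd.DataFrame(dropped, columns=["eye_id", "rule"]),
    )


def _group_summaries(cohort: pd.DataFrame, var: str) -> list[GroupSummary]:
    out = []
    for g in ("A", "B", "C"):
        vals = cohort.loc[cohort.shift_group == g, var].dropna().astype(float)
        if len(vals) >= 2:
            out.append(GroupSummary(g, len(vals), float(vals.mean()), float(vals.std(ddof=1))))
    return out


def _shift_group_report(cohort: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for var in ("age", "highest_iop", "axial_length", "md0", "followup_years",
                "bmo_area_mm2", "shift_index"):
        gs = _group_summaries(cohort, var)
        if len(gs) < 2:
            continue
        f, df1, df2, p = anova_from_summary(gs)
        rows.append({"variable": var, "test": "anova",
                     **{f"group_{g.label}": f"{g.mean:.2f}+/-{g.sd:.2f} (n={g.n})" for g in gs},
                     "p": p})
    for var, outcome in (("initial_hemisphere", "bi"), ("final_hemisphere", "bi")):
        tab = []
        for g in ("A", "B", "C"):
            sub = cohort[cohort.shift_group == g]
            if len(sub):
                tab.append([int((sub[var] == outcome).sum()), int((sub[var] != outcome).sum())])
        if len(tab) >= 2 and all(r[0] + r[1] > 0 for r in tab):
            try:
                _, _, p = chisq_test(tab)
            except ValueError:
                p = float("nan")
            rows.append({"variable": f"bihemi_{var}", "test": "chisq", "p": p})
    return pd.DataFrame(rows)


def _logistic_frame(result) -> pd.DataFrame:
    uni = []
    for var, r in result.univariate.items():
        if r.p:
            uni.append({"stage": "univariate", "variable": var,
                        "odds_ratio": r.odds_ratio[var], "ci_low": r.ci_low[var],
                        "ci_high": r.ci_high[var], "p": r.p[var]})
    multi = [
        {"stage": "multivariate", "variable": v, "odds_ratio": result.odds_ratio[v],
         "ci_low": result.ci_low[v], "ci_high": result.ci_high[v], "p": result.p[v]}
        for v in result.variables
        if v in result.odds_ratio  # empty when the joint fit failed (flagged in note)
    ]
    return pd.DataFrame(uni + multi)


def _fit_models(cohort: pd.DataFrame, config: PipelineConfig) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    base_vars = ["age", "highest_iop", "axial_length", "bmo_area_mm2", "md0", "lcd_um"]

    # initial inferior defect: trunk angle is the candidate of interest
    sub = cohort.dropna(subset=["alpha_deg"])
    sub = sub[sub.initial_hemisphere.isin(["superior", "inferior"])]
    y = (sub.initial_hemisphere == "inferior").astype(int)
    X = sub[[c for c in base_vars + ["shift_index", "alpha_deg"] if c in sub]].dropna(axis=1)
    if len(sub) > 10 and y.nunique() == 2:
        out["initial_inferior"] = _logistic_frame(screen_and_fit(X, y, config.screen_threshold))

    # initial bi-hemispheric involvement: |alpha| replaces signed alpha
    sub = cohort.copy()
    y = (sub.initial_hemisphere == "bi").astype(int)
    X = sub[[c for c in base_vars + ["shift_index", "abs_alpha_deg"] if c in sub]].dropna()
    if len(X) > 10 and y.loc[X.index].nunique() == 2:
        out["initial_bihemi"] = _logistic_frame(
            screen_and_fit(X, y.loc[X.index], config.screen_threshold)
        )

    # final single-hemisphere defect: obliqueness per the final-visit model
    sub = cohort.copy()
    final_vars = [v for v in base_vars if v != "md0"] + ["md_final"]
    y = sub.final_hemisphere.isin(["superior", "inferior"]).astype(int)
    X = sub[[c for c in final_vars + ["shift_index", "obliqueness_deg", "followup_years"] if c in sub]].dropna()
    if len(X) > 10 and y.loc[X.index].nunique() == 2:
        out["final_single"] = _logistic_frame(
            screen_and_fit(X, y.loc[X.index], config.screen_threshold)
        )
    return out


def _polar_plot(cohort: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "lcshift"
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    colors = {"superior": "tab:red", "inferior": "tab:blue", "bi": "tab:green"}
    sub = cohort.dropna(subset=["alpha_deg"])
    for label, color in colors.items():
        g = sub[sub.initial_hemisphere == label]
        ax.scatter(np.radians(180.0 - g.alpha_deg.astype(float)), g.shift_index,
                   s=18, c=color, label=label, alpha=0.8)
    ax.set_rmax(1.0)
    ax.set_title("Trunk deviation by initial hemisphere")
    ax.legend(loc="lower left", bbox_to_anchor=(1.0, 0.0), fontsize=8)
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the report bundle under ``config.out_dir``.

    Returns a summary dict (also written as ``summary.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        records, series, truth = simulate_cohort(config.simulate)
        truth.to_csv(out_dir / "truth.csv", index=False)
    else:
        records = lio.read_landmarks_csv(config.landmarks_path)
        exams = lio.read_vf_exams_csv(config.exams_path)
        cov_df = pd.read_csv(config.covariates_path, dtype={"eye_id": str})
        cov_by_id = {r["eye_id"]: r for r in cov_df.to_dict("records")}
        series = [
            EyeSeries(eye_id=eid, exams=ex, covariates=cov_by_id.get(eid, {}))
            for eid, ex in exams.items()
        ]

    cov = pd.DataFrame([{"eye_id": s.eye_id, **s.covariates} for s in series])
    cov = select_study_eyes(cov, config.seed)
    eligible, excl_log = exclusion_filter(cov)
    keep_ids = set(eligible.eye_id)
    records = [r for r in records if r.eye_id in keep_ids]
    series = [s for s in series if s.eye_id in keep_ids]

    cohort, drop_log = build_cohort_table(records, series, config)
    excl_log = pd.concat([excl_log, drop_log], ignore_index=True)
    excl_log.to_csv(out_dir / "exclusions.csv", index=False)
    cohort.to_csv(out_dir / "cohort.csv", index=False)

    report = {"n_input": int(len(cov)), "n_cohort": int(len(cohort)),
              "n_excluded": int(len(excl_log)),
              "cluster_rule": config.cluster_rule,
              "adjacency": config.adjacency, "confirm_n": config.confirm_n}
    if len(cohort) == 0:
        (out_dir / "FAILED").write_text("empty cohort after exclusions\n")
        raise RuntimeError("cohort stage produced no analyzable eyes")

    report["initial_hemisphere_counts"] = cohort.initial_hemisphere.value_counts().to_dict()
    report["final_hemisphere_counts"] = cohort.final_hemisphere.value_counts().to_dict()
    report["shift_group_counts"] = cohort.shift_group.value_counts().to_dict()

    table1 = _shift_group_report(cohort)
    table1.to_csv(out_dir / "shift_group_comparisons.csv", index=False)

    models = _fit_models(cohort, config)
    for name, frame in models.items():
        frame.to_csv(out_dir / f"logistic_{name}.csv", index=False)
        sig = frame[(frame.stage == "multivariate") if (frame.stage == "multivariate").any()
                    else (frame.stage == "univariate")]
        report[f"logistic_{name}"] = {
            r["variable"]: {"or": r["odds_ratio"], "p": r["p"]} for _, r in sig.iterrows()
        }

    tree_sub = cohort.dropna(subset=["alpha_deg", "md0"])
    if len(tree_sub) >= 20:
        tree = ctree_fit(
            tree_sub[["alpha_deg", "md0"]],
            tree_sub.initial_hemisphere.to_numpy(),
            alpha=config.alpha_level,
            n_perm=config.ctree_n_perm,
            seed=config.seed,
        )
        (out_dir / "ctree.txt").write_text(tree.render() + "\n")
        report["ctree_root_split"] = tree.split_var
        report["ctree_depth"] = tree.depth_below()

    _polar_plot(cohort, out_dir / "alpha_polar.svg")

    (out_dir / "summary.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
    )
    return report
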