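"""End-to-end orchestration of the synthetic group-connectivity study.

Stage order mirrors the analysis it emulates: simulate the cohort → ROI
top-fraction summaries → outlier replacement → per-ROI mixed ANOVA with FDR
across ROIs per hemisphere → linear mixed model per hemisphere → bootstrap
difference-of-differences per hemisphere → ISPC and peak centroids on the
designated ROI → brain–behaviour partial correlation (resting connectivity
as covariate) in the older-musician group.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import bootstrap_delta_of_deltas
from .config import PipelineConfig
from .io import write_json
from .maps import ConnectivityMap
from .roistats import (brain_behavior_partial_corr, fdr_correct,
                       fit_group_lmm, mixed_anova, replace_outliers,
                       summarize_maps)
from .spatial import compare_centroids, ispc_between, ispc_within, \
    top_voxel_centroid
from .synthetic import generate_cohort
from scipy import stats

log = logging.getLogger("sinconn")


def summarize_cohort(cohort, fraction: float = 0.4) -> pd.DataFrame:
    """Tidy ROI summary table: one row per subject×roi×condition×measure."""
    rows = []
    group_of = dict(zip(cohort.subjects["subject_id"], cohort.subjects["group"]))
    for measure, per_roi in cohort.maps.items():
        for roi_name, per_cond in per_roi.items():
            conds = sorted(per_cond)
            n_sub = len(per_cond[conds[0]])
            for i in range(n_sub):
                sid = per_cond[conds[0]][i].subject_id
                values = {c: per_cond[c][i].values for c in conds}
                summ = summarize_maps(values, fraction)
                for c in conds:
                    rows.append({
                        "subject_id": sid, "group": group_of[sid],
                        "roi": roi_name, "condition": c, "measure": measure,
                        "value": summ[c], "outlier_replaced": False,
                    })
    return pd.DataFrame(rows)


def clean_table(table: pd.DataFrame, k_sd: float = 2.0) -> pd.DataFrame:
    """Outlier replacement per roi × condition × measure, within group."""
    out = table.copy()
    for _, idx in out.groupby(["roi", "condition", "measure"]).groups.items():
        sub = out.loc[idx]
        cleaned, flags = replace_outliers(sub["value"].to_numpy(),
                                          sub["group"].to_numpy(), k_sd)
        out.loc[idx, "value"] = cleaned
        out.loc[idx, "outlier_replaced"] = flags
    return out


def condition_mean_maps(cohort, measure: str, roi_name: str) -> dict[str, list[ConnectivityMap]]:
    """Per-group lists of cross-condition mean maps for one ROI."""
    per_cond = cohort.maps[measure][roi_name]
    conds = sorted(per_cond)
    out: dict[str, list[ConnectivityMap]] = {}
    for i in range(len(per_cond[conds[0]])):
        m0 = per_cond[conds[0]][i]
        mean_vals = np.mean([per_cond[c][i].values for c in conds], axis=0)
        cmap = ConnectivityMap(roi=m0.roi, values=mean_vals,
                               subject_id=m0.subject_id, meta=dict(m0.meta))
        out.setdefault(m0.meta["group"], []).append(cmap)
    return out


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute the full synthetic study; returns (and optionally writes) results."""
    t_start = time.time()
    timings: dict[str, float] = {}
    results: dict = {"provenance": {
        "package_version": __version__, "seed": config.seed,
        "summary_fraction": config.summary_fraction,
        "centroid_fraction": config.centroid_fraction,
        "outlier_k_sd": config.outlier_k_sd,
        "n_bootstrap": config.n_bootstrap,
        "ppi_mode": config.ppi_mode, "fisher_z": config.fisher_z,
        "robust_lmm": config.robust_lmm,
    }}

    def _stage(name):
        timings[name] = time.time()
        log.info("stage %s", name)

    def _done(name):
        timings[name] = round(time.time() - timings[name], 3)

    # ---- simulate --------------------------------------------------------
    _stage("simulate")
    rois = [rc.build() for rc in config.rois]
    measure_offsets = {"rsfc": config.rsfc_offsets} if \
        ("rsfc" in config.measures and config.rsfc_offsets) else None
    cohort = generate_cohort(
        specs=config.groups, rois=rois, conditions=config.conditions,
        measures=config.measures, seed=config.seed,
        behavior_roi=config.behavior_roi or None,
        summary_fraction=config.summary_fraction,
        measure_offsets=measure_offsets,
        cross_measure_corr=config.cross_measure_corr,
    )
    _done("simulate")

    # ---- ROI summaries + outlier replacement -----------------------------
    _stage("roi_summary")
    raw = summarize_cohort(cohort, config.summary_fraction)
    table = clean_table(raw, config.outlier_k_sd)
    _done("roi_summary")

    hemi_of = {rc.name: rc.hemisphere for rc in config.rois}
    tifc = table[table["measure"] == "tifc"]

    # ---- per-ROI mixed ANOVA, FDR across ROIs per hemisphere -------------
    _stage("anova")
    anova_rows = []
    for roi_name, sub in tifc.groupby("roi"):
        res = mixed_anova(sub, dv="value", within="condition",
                          subject="subject_id", between="group")
        grp = res.effect("group")
        anova_rows.append({
            "roi": roi_name, "hemisphere": hemi_of[roi_name],
            "F_group": float(grp["F"]), "df1": float(grp["df1"]),
            "df2": float(grp["df2"]), "p_raw": float(grp["p_raw"]),
            "gg_epsilon": res.gg_epsilon, "gg_applied": res.corrected,
        })
    anova_df = pd.DataFrame(anova_rows)
    anova_df["p_fdr"] = np.nan
    for hemi, idx in anova_df.groupby("hemisphere").groups.items():
        anova_df.loc[idx, "p_fdr"] = fdr_correct(anova_df.loc[idx, "p_raw"])
    results["anova"] = anova_df.to_dict(orient="records")
    _done("anova")

    # ---- linear mixed model per hemisphere (ONM vs YNM) ------------------
    _stage("lmm")
    results["lmm"] = {}
    for hemi in ("left", "right"):
        roi_names = [r for r, h in hemi_of.items() if h == hemi]
        if len(roi_names) < 2:
            continue
        sub = tifc[tifc["roi"].isin(roi_names)]
        lmm = fit_group_lmm(sub, dv="value", contrast=("YNM", "ONM"),
                            robust=config.robust_lmm)
        results["lmm"][hemi] = {
            "beta_group": lmm.beta_group, "se": lmm.se, "p": lmm.p,
            "converged": lmm.converged, "contrast": list(lmm.groups),
        }
    _done("lmm")

    # ---- bootstrap difference of differences per hemisphere --------------
    _stage("bootstrap")
    cond_mean = (tifc.groupby(["subject_id", "group", "roi"], as_index=False)
                 ["value"].mean())
    results["bootstrap"] = {}
    boot_rng = np.random.default_rng(config.seed + 1)
    for hemi in ("left", "right"):
        roi_names = [r for r, h in hemi_of.items() if h == hemi]
        if not roi_names:
            continue
        boot = bootstrap_delta_of_deltas(
            cond_mean, roi_set=roi_names, n_iterations=config.n_bootstrap,
            seed=int(boot_rng.integers(2**31)))
        results["bootstrap"][hemi] = {
            "delta_onm_ynm": boot.delta_onm_ynm,
            "delta_om_ynm": boot.delta_om_ynm,
            "delta_of_deltas": boot.delta_of_deltas,
            "ci_low": boot.ci_low, "ci_high": boot.ci_high,
            "significant": boot.significant,
            "n_iterations": boot.n_iterations, "roi_set": list(boot.roi_set),
        }
    _done("bootstrap")

    # ---- ISPC + centroids on the designated ROI --------------------------
    _stage("spatial")
    ispc_roi = config.ispc_roi or config.rois[0].name
    by_group = condition_mean_maps(cohort, "tifc", ispc_roi)
    per_cond = cohort.maps["tifc"][ispc_roi]

    def _scores(kind, *args, **kw):
        per_c = {}
        for c in sorted(per_cond):
            group_maps = {g: [] for g in by_group}
            for m in per_cond[c]:
                group_maps[m.meta["group"]].append(m)
            per_c[c] = group_maps
        # average per-condition scores
        scores = None
        for c, gm in per_c.items():
            if kind == "between":
                s = ispc_between(gm[args[0]], gm["YNM"],
                                 fisher_z=config.fisher_z)
            else:
                s = ispc_within(gm[args[0]], group=args[0],
                                fisher_z=config.fisher_z)
            vals = np.array([x.score for x in s])
            scores = vals if scores is None else scores + vals
        return scores / len(per_c)

    ispc = {"roi": ispc_roi,
            "between_to_ynm": {g: _scores("between", g).tolist()
                               for g in ("OM", "ONM")},
            "within": {g: _scores("within", g).tolist()
                       for g in ("OM", "ONM", "YNM")}}
    om_b = np.array(ispc["between_to_ynm"]["OM"])
    onm_b = np.array(ispc["between_to_ynm"]["ONM"])
    t_b, p_b = stats.ttest_ind(om_b, onm_b)
    ispc["om_vs_onm_between"] = {"t": float(t_b), "p": float(p_b),
                                 "mean_om": float(om_b.mean()),
                                 "mean_onm": float(onm_b.mean())}
    w_onm = np.array(ispc["within"]["ONM"])
    for other in ("OM", "YNM"):
        t_w, p_w = stats.ttest_ind(w_onm, np.array(ispc["within"][other]))
        ispc[f"onm_vs_{other.lower()}_within"] = {"t": float(t_w),
                                                  "p": float(p_w)}
    results["ispc"] = ispc

    centroids = {g: [top_voxel_centroid(m, config.centroid_fraction)
                     for m in by_group[g]] for g in by_group}
    results["centroids"] = {"roi": ispc_roi}
    for ga in ("ONM", "OM"):
        comp = compare_centroids(centroids[ga], centroids["YNM"])
        results["centroids"][f"{ga.lower()}_vs_ynm"] = {
            "t": comp.t.tolist(), "p_raw": comp.p_raw.tolist(),
            "p_fdr": comp.p_fdr.tolist(),
            "mean_diff_mm": comp.mean_diff_mm.tolist(),
        }
    _done("spatial")

    # ---- brain-behaviour partial correlation (OM group) ------------------
    _stage("behavior")
    b_roi = config.behavior_roi or config.rois[0].name
    subj = cohort.subjects
    om_ids = subj.loc[subj["group"] == "OM", "subject_id"]
    mean_by = (table.groupby(["subject_id", "measure", "roi"])["value"]
               .mean().unstack("measure"))
    tifc_om = np.array([mean_by.loc[(s, b_roi), "tifc"] for s in om_ids])
    acc_om = subj.loc[subj["group"] == "OM", "accuracy"].to_numpy()
    cov = {}
    if "rsfc" in config.measures:
        cov["rsfc"] = np.array([mean_by.loc[(s, b_roi), "rsfc"]
                                for s in om_ids])
    pc = brain_behavior_partial_corr(tifc_om, acc_om, cov)
    results["brain_behavior"] = {
        "roi": b_roi, "group": "OM", "slope": pc.slope, "p": pc.p,
        "n": pc.n, "covariates": list(pc.covariates),
    }
    _done("behavior")

    results["timings_s"] = timings
    results["total_s"] = round(time.time() - t_start, 3)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prov = results["provenance"]
        tbl = table.copy()
        for k in ("seed", "summary_fraction", "outlier_k_sd"):
            tbl[k] = prov[k]
        tbl.to_csv(outdir / "roi_summary.tsv", sep="\t", index=False)
        cohort.subjects.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
        write_json(results, outdir / "results.json")
        config.to_yaml(outdir / "config_resolved.yaml")
        with open(outdir / "run.log", "w") as fh:
            fh.write(f"sinconn {__version__}\nseed {config.seed}\n")
            for k, v in timings.items():
                fh.write(f"stage {k}: {v}s\n")
    return results
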