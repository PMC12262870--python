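"""ROI summarization and group-level statistics.

Implements the ROI pipeline used for every measure (task-induced
connectivity, resting connectivity, activation): select the top-fraction
voxels of each subject's map (ranked by the cross-condition mean), average
them, replace per-group outliers beyond k standard deviations with the group
median, then test group effects with a mixed-design ANOVA
(Greenhouse–Geisser corrected, FDR across ROIs), a linear mixed model with
crossed subject/region random intercepts, and brain–behaviour partial
correlation controlling for resting connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "select_top_voxels",
    "summarize_maps",
    "replace_outliers",
    "mixed_anova",
    "fdr_correct",
    "fit_group_lmm",
    "brain_behavior_partial_corr",
    "AnovaResult",
    "LmmResult",
    "PartialCorrResult",
]


# ---------------------------------------------------------------------------
# Top-fraction voxel summarization
# ---------------------------------------------------------------------------

def select_top_voxels(values: np.ndarray, fraction: float,
                      ranking_values: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean of the top-``fraction`` voxels of ``values``, ranked externally.

    ``ranking_values`` (typically the cross-condition mean map) decides which
    voxels enter; ``values`` is averaged over them.  k = ceil(fraction * V);
    ties are broken by ascending voxel linear index, so the selection is
    deterministic and permutation-checkable.

    Returns (selected indices sorted ascending, mean of values over them).
    """
    values = np.asarray(values, float)
    ranking = np.asarray(ranking_values, float)
    if values.size == 0:
        raise ValueError("empty ROI: no voxels to select")
    if values.shape != ranking.shape:
        raise ValueError("values and ranking_values must share voxel support")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = int(np.ceil(fraction * values.size))
    # stable argsort of -ranking keeps ascending index order among ties
    order = np.argsort(-ranking, kind="stable")
    sel = np.sort(order[:k])
    return sel, float(values[sel].mean())


def summarize_maps(per_condition_values: dict[str, np.ndarray],
                   fraction: float = 0.4) -> dict[str, float]:
    """Top-fraction summary per condition with a condition-independent voxel set.

    Voxels are ranked once by the mean across conditions, then the same set
    is averaged within each condition.
    """
    conds = sorted(per_condition_values)
    stack = np.stack([per_condition_values[c] for c in conds])
    ranking = stack.mean(axis=0)
    out = {}
    for c in conds:
        _, out[c] = select_top_voxels(per_condition_values[c], fraction, ranking)
    return out


# ---------------------------------------------------------------------------
# Outlier replacement
# ---------------------------------------------------------------------------

def replace_outliers(values: np.ndarray, groups: np.ndarray,
                     k_sd: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Replace per-group outliers beyond ``k_sd`` sample SDs with the group median.

    The mean, SD (ddof=1) and median are computed on the original values of
    the group, candidate included.  A zero-SD group is left unchanged.
    Returns (cleaned values, boolean replacement flags).
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    cleaned = values.copy()
    flags = np.zeros(values.size, dtype=bool)
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        v = values[idx]
        if v.size < 2:
            continue
        sd = v.std(ddof=1)
        if sd == 0:
            continue
        out = np.abs(v - v.mean()) > k_sd * sd
        cleaned[idx[out]] = np.median(v)
        flags[idx[out]] = True
    return cleaned, flags


# ---------------------------------------------------------------------------
# Mixed-design ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Mixed-design ANOVA table with sphericity correction metadata."""

    table: pd.DataFrame          # Source, F, df1, df2, p_raw columns
    gg_epsilon: float            # Greenhouse-Geisser epsilon of the within factor
    sphericity_ok: bool
    corrected: bool              # True if GG-corrected p reported for within terms

    def effect(self, name: str) -> pd.Series:
        row = self.table[self.table["Source"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def mixed_anova(data: pd.DataFrame, dv: str, within: str, subject: str,
                between: str = "group") -> AnovaResult:
    """Two-way mixed ANOVA (between group × within condition).

    Greenhouse–Geisser correction is applied to the within and interaction
    terms when Mauchly's sphericity test rejects at alpha = 0.05 (with a
    two-level within factor epsilon is exactly 1 and no correction occurs).
    """
    counts = data.groupby([subject])[within].nunique()
    full = counts.max()
    missing = counts[counts < full]
    if len(missing):
        raise ValueError("subjects missing within-factor cells: "
                         f"{sorted(missing.index.tolist())}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(data=data, dv=dv, within=within, subject=subject,
                             between=between, correction=True)
    within_row = aov[aov["Source"] == within].iloc[0]
    eps = float(within_row.get("eps", 1.0))
    spher_ok = bool(within_row.get("sphericity", True))
    k = data[within].nunique()
    if k == 2:
        eps, spher_ok = 1.0, True

    use_gg = not spher_ok
    rows = []
    for _, r in aov.iterrows():
        # column naming varies across pingouin versions (p-unc vs p_unc)
        p = r.get("p_unc", r.get("p-unc"))
        p_gg = r.get("p_GG_corr", r.get("p-GG-corr", np.nan))
        if use_gg and r["Source"] != between and not np.isnan(p_gg):
            p = p_gg
        rows.append({"Source": r["Source"], "F": r["F"],
                     "df1": r["DF1"], "df2": r["DF2"], "p_raw": p})
    return AnovaResult(table=pd.DataFrame(rows), gg_epsilon=eps,
                       sphericity_ok=spher_ok, corrected=use_gg)


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Linear mixed model: measure ~ group + (1|subject) + (1|region)
# ---------------------------------------------------------------------------

@dataclass
class LmmResult:
    """Group contrast from the crossed random-intercepts mixed model."""

    beta_group: float
    se: float
    p: float
    converged: bool
    groups: tuple[str, str]          # (reference, contrast)
    vc: dict = field(default_factory=dict)
    robust: bool = False


def fit_group_lmm(table: pd.DataFrame, dv: str = "value",
                  group_col: str = "group", subject_col: str = "subject_id",
                  region_col: str = "roi",
                  contrast: tuple[str, str] | None = None,
                  robust: bool = False, reml: bool = True,
                  max_robust_iter: int = 10) -> LmmResult:
    """REML fit of ``dv ~ group + (1|subject) + (1|region)``.

    ``contrast=(ref, other)`` restricts to two groups and reports the fixed
    coefficient of ``other`` relative to ``ref``.  The optional robust mode
    iteratively Huber-clips large residuals of the response (pseudo-data
    re-fitting), downweighting outliers without changing the model.
    """
    df = table.copy()
    if contrast is not None:
        df = df[df[group_col].isin(contrast)]
        ref, other = contrast
    else:
        levels = sorted(df[group_col].unique())
        if len(levels) != 2:
            raise ValueError("contrast required when more than two groups present")
        ref, other = levels
    if df[region_col].nunique() < 2:
        raise ValueError("need >= 2 regions for a region random intercept")
    for g in (ref, other):
        if (df[group_col] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 rows")

    df = df.reset_index(drop=True)
    y = df[dv].to_numpy(dtype=float)

    def _fit(resp):
        d = df.assign(__y=resp)
        md = smf.mixedlm(
            f"__y ~ C({group_col}, Treatment('{ref}'))", d,
            groups=np.ones(len(d)),
            vc_formula={"subject": f"0 + C({subject_col})",
                        "region": f"0 + C({region_col})"},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # default bfgs is unreliable here; powell/cg reproduce lme4
            for meth in ("powell", "cg", "lbfgs"):
                res = md.fit(reml=reml, method=meth, maxiter=2000)
                if res.converged:
                    break
        return res

    res = _fit(y)
    if robust:
        c = 1.345   # Huber tuning constant (95% Gaussian efficiency)
        for _ in range(max_robust_iter):
            resid = y - res.fittedvalues.to_numpy()
            scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            if scale == 0:
                break
            clipped = np.clip(resid, -c * scale, c * scale)
            y_new = res.fittedvalues.to_numpy() + clipped
            new_res = _fit(y_new)
            delta = abs(new_res.params.iloc[1] - res.params.iloc[1])
            res = new_res
            if delta < 1e-6:
                break

    beta = float(res.params.iloc[1])
    se = float(res.bse.iloc[1])
    p = float(res.pvalues.iloc[1])
    vc_names = list(res.model.exog_vc.names) if hasattr(res.model, "exog_vc") else []
    vc = {n: float(v) for n, v in zip(vc_names, np.asarray(res.vcomp))}
    return LmmResult(beta_group=beta, se=se, p=p, converged=bool(res.converged),
                     groups=(ref, other), vc=vc, robust=robust)


# ---------------------------------------------------------------------------
# Brain-behaviour partial correlation
# ---------------------------------------------------------------------------

@dataclass
class PartialCorrResult:
    slope: float                 # standardized TiFC slope
    p: float
    n: int
    covariates: tuple[str, ...]


def brain_behavior_partial_corr(
    tifc: np.ndarray, behavior: np.ndarray,
    covariates: dict[str, np.ndarray] | None = None,
) -> PartialCorrResult:
    """Standardized slope of behaviour on TiFC, controlling for covariates.

    All variables are z-scored, then behaviour is regressed on TiFC plus the
    covariates (ordinary least squares); the TiFC coefficient and its p-value
    are returned.  With no covariate this is the Pearson correlation.
    """
    tifc = np.asarray(tifc, float)
    behavior = np.asarray(behavior, float)
    covariates = covariates or {}
    n = tifc.size
    if behavior.size != n:
        raise ValueError("tifc and behavior lengths differ")
    if n < len(covariates) + 3:
        raise ValueError("need n >= number of covariates + 3")

    def z(v, name):
        v = np.asarray(v, float)
        s = v.std(ddof=1)
        if s == 0:
            raise ValueError(f"{name} is constant; slope undefined")
        return (v - v.mean()) / s

    X = np.column_stack([np.ones(n), z(tifc, "tifc")] +
                        [z(v, k) for k, v in covariates.items()])
    fit = sm.OLS(z(behavior, "behavior"), X).fit()
    return PartialCorrResult(slope=float(fit.params[1]),
                             p=float(fit.pvalues[1]), n=n,
                             covariates=tuple(covariates))
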