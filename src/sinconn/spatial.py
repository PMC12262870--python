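"""Inter-subject spatial correlation (ISPC) and connectivity-peak centroids.

ISPC quantifies how "youth-like" an older subject's voxel-wise connectivity
pattern is: the mean Pearson correlation of that subject's map against every
subject of a reference (young) group, over the ROI's voxels.  Within-group
ISPC correlates each subject with every other member of their own group and
indexes group homogeneity.

The centroid analysis locates each subject's connectivity peak as the
unweighted mean mm coordinate of the top-fraction (10% by default) voxels and
compares group mean coordinates axis-by-axis with two-sample t-tests,
FDR-corrected over the three axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .maps import ConnectivityMap
from .roistats import fdr_correct, select_top_voxels

__all__ = [
    "ispc_between",
    "ispc_within",
    "top_voxel_centroid",
    "compare_centroids",
    "ISPCScore",
    "CentroidResult",
    "CentroidComparison",
]


@dataclass(frozen=True)
class ISPCScore:
    subject_id: str
    reference_group: str
    score: float            # mean pairwise Pearson r, in [-1, 1]
    n_pairs: int            # pairs contributing (zero-variance pairs skipped)
    n_skipped: int = 0


def _as_matrix(maps) -> tuple[np.ndarray, list[str]]:
    if isinstance(maps, np.ndarray):
        m = np.asarray(maps, float)
        ids = [str(i) for i in range(m.shape[0])]
        return m, ids
    values = np.stack([m.values for m in maps])
    ids = [m.subject_id for m in maps]
    return values, ids


def _pairwise_corr(A: np.ndarray, B: np.ndarray,
                   method: str = "pearson") -> np.ndarray:
    """(nA, nB) correlations between rows; NaN where a row has zero variance."""
    if A.shape[1] != B.shape[1]:
        raise ValueError("maps must share one voxel support")
    if A.shape[1] < 2:
        raise ValueError("need >= 2 voxels to correlate")
    if method == "spearman":
        A = stats.rankdata(A, axis=1)
        B = stats.rankdata(B, axis=1)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((Ac**2).sum(axis=1))
    nb = np.sqrt((Bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac @ Bc.T) / np.outer(na, nb)
    r[na == 0, :] = np.nan
    r[:, nb == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _mean_scores(r: np.ndarray, ids, ref_group, fisher_z) -> list[ISPCScore]:
    scores = []
    for i, sid in enumerate(ids):
        row = r[i]
        valid = ~np.isnan(row)
        if not valid.any():
            raise ValueError(f"all pairs of subject {sid!r} were skipped "
                             "(zero-variance maps)")
        vals = row[valid]
        if fisher_z:
            score = float(np.tanh(np.arctanh(np.clip(vals, -1 + 1e-15,
                                                     1 - 1e-15)).mean()))
        else:
            score = float(vals.mean())
        scores.append(ISPCScore(subject_id=sid, reference_group=ref_group,
                                score=score, n_pairs=int(valid.sum()),
                                n_skipped=int((~valid).sum())))
    return scores


def ispc_between(older_maps, young_maps, reference_group: str = "YNM",
                 method: str = "pearson",
                 fisher_z: bool = False) -> list[ISPCScore]:
    """Each older subject's mean correlation to every young subject.

    Raw correlation coefficients are averaged arithmetically by default
    (``fisher_z=True`` averages on the z scale instead).  Zero-variance pairs
    are skipped and counted in ``n_skipped``.
    """
    A, ids = _as_matrix(older_maps)
    B, _ = _as_matrix(young_maps)
    r = _pairwise_corr(A, B, method)
    return _mean_scores(r, ids, reference_group, fisher_z)


def ispc_within(group_maps, group: str = "", method: str = "pearson",
                fisher_z: bool = False) -> list[ISPCScore]:
    """Each subject's mean correlation to the other members of their group."""
    A, ids = _as_matrix(group_maps)
    if A.shape[0] < 2:
        raise ValueError("within-group ISPC needs >= 2 subjects")
    r = _pairwise_corr(A, A, method)
    np.fill_diagonal(r, np.nan)          # self-pairs excluded
    scores = _mean_scores(r, ids, group or "self", fisher_z)
    # the self pair is excluded by construction, not "skipped"
    return [ISPCScore(s.subject_id, s.reference_group, s.score, s.n_pairs,
                      max(0, s.n_skipped - 1)) for s in scores]


def ispc_across_conditions(per_condition_maps: dict, kind: str = "between",
                           pooled: bool = False, **kwargs) -> list[ISPCScore]:
    """ISPC per condition, averaged across conditions (default), or pooled.

    ``per_condition_maps`` maps condition → the argument tuple of
    :func:`ispc_between` (older, young) or :func:`ispc_within` (group maps).
    ``pooled=True`` concatenates condition vectors into one long map first.
    """
    conds = sorted(per_condition_maps)
    fn = ispc_between if kind == "between" else ispc_within
    if pooled:
        if kind == "between":
            A = np.concatenate([_as_matrix(per_condition_maps[c][0])[0]
                                for c in conds], axis=1)
            B = np.concatenate([_as_matrix(per_condition_maps[c][1])[0]
                                for c in conds], axis=1)
            ids = _as_matrix(per_condition_maps[conds[0]][0])[1]
            r = _pairwise_corr(A, B, kwargs.get("method", "pearson"))
            return _mean_scores(r, ids, kwargs.get("reference_group", "YNM"),
                                kwargs.get("fisher_z", False))
        A = np.concatenate([_as_matrix(per_condition_maps[c])[0]
                            for c in conds], axis=1)
        return ispc_within(A, **kwargs)
    per_cond = [fn(*per_condition_maps[c], **kwargs) if kind == "between"
                else fn(per_condition_maps[c], **kwargs) for c in conds]
    out = []
    for subj_scores in zip(*per_cond):
        s0 = subj_scores[0]
        out.append(ISPCScore(
            subject_id=s0.subject_id, reference_group=s0.reference_group,
            score=float(np.mean([s.score for s in subj_scores])),
            n_pairs=s0.n_pairs,
            n_skipped=int(sum(s.n_skipped for s in subj_scores))))
    return out


# ---------------------------------------------------------------------------
# Peak centroids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CentroidResult:
    subject_id: str
    centroid_mm: tuple[float, float, float]
    fraction: float
    n_voxels: int


def top_voxel_centroid(cmap: ConnectivityMap,
                       fraction: float = 0.10) -> CentroidResult:
    """Unweighted mean mm coordinate of the top-fraction voxels by map value."""
    sel, _ = select_top_voxels(cmap.values, fraction, cmap.values)
    coords = cmap.coords_mm[sel]
    c = coords.mean(axis=0)
    return CentroidResult(subject_id=cmap.subject_id,
                          centroid_mm=(float(c[0]), float(c[1]), float(c[2])),
                          fraction=fraction, n_voxels=sel.size)


@dataclass
class CentroidComparison:
    axes: tuple[str, str, str]
    t: np.ndarray               # per-axis t statistic (NaN if undefined)
    p_raw: np.ndarray
    p_fdr: np.ndarray
    mean_diff_mm: np.ndarray    # group A mean - group B mean


def compare_centroids(group_a: list[CentroidResult],
                      group_b: list[CentroidResult],
                      welch: bool = False) -> CentroidComparison:
    """Axis-wise two-sample t-tests of group centroid coordinates.

    Student's pooled-variance t by default (``welch=True`` switches);
    Benjamini–Hochberg correction across the three axes.  An axis with zero
    variance in both groups yields NaN t and p = 1 for that axis.
    """
    A = np.array([c.centroid_mm for c in group_a], float)
    B = np.array([c.centroid_mm for c in group_b], float)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    t = np.full(3, np.nan)
    p = np.ones(3)
    for ax in range(3):
        a, b = A[:, ax], B[:, ax]
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if np.isclose(a.mean(), b.mean()):
                t[ax] = 0.0
            continue   # undefined t stays NaN, p stays 1
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t[ax], p[ax] = float(res.statistic), float(res.pvalue)
    return CentroidComparison(axes=("x", "y", "z"), t=t, p_raw=p,
                              p_fdr=fdr_correct(p),
                              mean_diff_mm=A.mean(axis=0) - B.mean(axis=0))
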