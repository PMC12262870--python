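"""Bootstrap contrast of group-difference magnitudes across ROIs.

The question: is the older-non-musician minus young gap (Δ_ONM−YNM) larger
than the older-musician minus young gap (Δ_OM−YNM), averaged over a set of
ROIs?  A nonparametric bootstrap resamples whole subjects within each group
with replacement (all of a subject's ROI values move together, preserving
cross-ROI correlation), recomputes both deltas each iteration, and reads the
95% confidence interval of their difference off the 2.5th/97.5th percentiles
of the resampled distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["percentile_ci", "bootstrap_delta_of_deltas", "BootstrapResult"]


def percentile_ci(samples, level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval (linear interpolation between ranks)."""
    s = np.asarray(samples, float)
    if s.size == 0:
        raise ValueError("no samples")
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(s, [100 * alpha, 100 * (1 - alpha)],
                           method="linear")
    return float(lo), float(hi)


@dataclass
class BootstrapResult:
    delta_onm_ynm: float        # mean ONM-YNM difference over ROIs (point)
    delta_om_ynm: float
    delta_of_deltas: float      # delta_onm_ynm - delta_om_ynm (point)
    ci_low: float
    ci_high: float
    significant: bool           # CI excludes zero
    n_iterations: int
    seed: int | None
    roi_set: tuple[str, ...]
    samples: np.ndarray | None = None


def _group_matrix(values: pd.DataFrame | dict, group: str,
                  roi_set) -> np.ndarray:
    """(n_subjects, n_rois) value matrix for one group, ROI columns ordered."""
    if isinstance(values, dict):
        m = np.asarray(values[group], float)
        if m.ndim != 2:
            raise ValueError("per-group arrays must be (subjects x rois)")
        return m
    sub = values[values["group"] == group]
    if sub.empty:
        raise ValueError(f"no rows for group {group!r}")
    wide = sub.pivot_table(index="subject_id", columns="roi", values="value")
    missing = [r for r in roi_set if r not in wide.columns]
    if missing:
        raise ValueError(f"group {group!r} lacks ROIs {missing}")
    if wide[list(roi_set)].isna().any().any():
        raise ValueError(f"group {group!r} has missing ROI values")
    return wide[list(roi_set)].to_numpy(dtype=float)


def bootstrap_delta_of_deltas(
    values: pd.DataFrame | dict,
    roi_set: tuple[str, ...] | list[str],
    groups: tuple[str, str, str] = ("ONM", "OM", "YNM"),
    n_iterations: int = 10_000,
    seed: int | None = 0,
    level: float = 0.95,
    keep_samples: bool = False,
) -> BootstrapResult:
    """Bootstrap CI for Δ_ONM−YNM − Δ_OM−YNM averaged over ``roi_set``.

    ``values`` is either a tidy table with columns (subject_id, group, roi,
    value) or a dict mapping group → (subjects × rois) array.  Each iteration
    resamples subject rows within each group with replacement at the original
    group size; per-ROI group-mean differences are averaged over the ROI set.
    Resampling order is fixed (ONM, OM, YNM) so a seed fixes the CI exactly.
    """
    roi_set = tuple(roi_set)
    if not roi_set:
        raise ValueError("roi_set must be non-empty")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if n_iterations < 100:
        warnings.warn("fewer than 100 bootstrap iterations: CI is unstable",
                      stacklevel=2)
    onm_g, om_g, ynm_g = groups
    onm = _group_matrix(values, onm_g, roi_set)
    om = _group_matrix(values, om_g, roi_set)
    ynm = _group_matrix(values, ynm_g, roi_set)
    for name, m in ((onm_g, onm), (om_g, om), (ynm_g, ynm)):
        if m.shape[0] < 2:
            raise ValueError(f"group {name!r} needs >= 2 subjects")

    def delta(a, b):
        return float((a.mean(axis=0) - b.mean(axis=0)).mean())

    point_onm = delta(onm, ynm)
    point_om = delta(om, ynm)

    rng = np.random.default_rng(seed)
    # resample subject indices; draw order fixed: ONM, OM, YNM
    idx_onm = rng.integers(0, onm.shape[0], (n_iterations, onm.shape[0]))
    idx_om = rng.integers(0, om.shape[0], (n_iterations, om.shape[0]))
    idx_ynm = rng.integers(0, ynm.shape[0], (n_iterations, ynm.shape[0]))
    # (iterations, rois): mean over resampled subjects, then over ROIs
    m_onm = onm[idx_onm].mean(axis=1).mean(axis=1)
    m_om = om[idx_om].mean(axis=1).mean(axis=1)
    m_ynm = ynm[idx_ynm].mean(axis=1).mean(axis=1)
    samples = (m_onm - m_ynm) - (m_om - m_ynm)

    lo, hi = percentile_ci(samples, level)
    return BootstrapResult(
        delta_onm_ynm=point_onm,
        delta_om_ynm=point_om,
        delta_of_deltas=point_onm - point_om,
        ci_low=lo, ci_high=hi,
        significant=bool(lo > 0 or hi < 0),
        n_iterations=n_iterations, seed=seed, roi_set=roi_set,
        samples=samples if keep_samples else None,
    )
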