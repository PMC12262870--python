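"""Task-induced (gPPI) and resting-state connectivity estimation.

The generalized psychophysiological interaction (gPPI) model regresses each
target voxel's BOLD series on: the per-condition HRF-convolved task
regressors, the seed time series, and one interaction (PPI) regressor per
condition formed as demeaned-seed × mean-centred condition regressor.  The
interaction coefficients are the task-induced functional connectivity (TiFC).

Resting-state connectivity is the Pearson correlation between band-pass
filtered (0.02–0.1 Hz by default) voxel series and the seed-mean series after
nuisance regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, signal
from scipy.stats import gamma as gamma_dist

from .synthetic import BOLDSeries, TaskDesign

__all__ = [
    "double_gamma_hrf",
    "build_design_matrix",
    "fit_glm",
    "compute_ppi_betas",
    "compute_rsfc",
    "PPIBetas",
]

DEFAULT_HRF = {"peak": 6.0, "undershoot": 16.0, "ratio": 6.0, "length": 32.0}


def double_gamma_hrf(tr: float, oversample: int = 16,
                     params: dict | None = None) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``tr / oversample`` seconds.

    h(t) = g(t; peak) − g(t; undershoot) / ratio, peak-normalised to 1.
    """
    p = dict(DEFAULT_HRF, **(params or {}))
    dt = tr / oversample
    t = np.arange(0.0, p["length"], dt)
    # shape a, scale 1: mode at a-1 → a = peak + 1 for mode `peak`
    h = gamma_dist.pdf(t, p["peak"] + 1.0) - \
        gamma_dist.pdf(t, p["undershoot"] + 1.0) / p["ratio"]
    return h / h.max()


def build_design_matrix(
    design: TaskDesign,
    hrf_params: dict | None = None,
    n_timepoints: int | None = None,
    block: int = 0,
    conditions: str = "snr",
    oversample: int = 16,
) -> pd.DataFrame:
    """HRF-convolved stimulus regressors for one block, sampled at the TR.

    ``conditions="snr"`` pools the four syllables within each SNR level (one
    regressor per SNR); ``"snr_syllable"`` models all 12 cells.  The first
    column is a constant intercept.  Duplicated identical onsets within a
    condition are summed, with a warning.
    """
    sel = design.block == block
    if not sel.any():
        raise ValueError(f"design has no trials in block {block}")
    onsets = design.onsets[sel]
    if conditions == "snr":
        all_labels = design.conditions
    elif conditions == "snr_syllable":
        all_labels = np.array([f"snr{s:+d}_{y}" for s, y in
                               zip(design.snr_db, design.syllable)])
    else:
        raise ValueError("conditions must be 'snr' or 'snr_syllable'")
    labels = all_labels[sel]

    if n_timepoints is None:
        n_timepoints = int(np.ceil(design.block_duration(block) / design.tr))
    dt = design.tr / oversample
    n_fine = n_timepoints * oversample
    hrf = double_gamma_hrf(design.tr, oversample, hrf_params)

    cols: dict[str, np.ndarray] = {"intercept": np.ones(n_timepoints)}
    for cond in sorted(set(all_labels)):
        c_onsets = onsets[labels == cond]
        if c_onsets.size == 0:
            raise ValueError(f"condition {cond!r} has no trials in block "
                             f"{block}: its regressor would be all zero")
        if np.unique(c_onsets).size < c_onsets.size:
            warnings.warn(f"duplicated onsets in condition {cond!r}; summed",
                          stacklevel=2)
        box = np.zeros(n_fine)
        for t0 in c_onsets:
            i0 = int(round(t0 / dt))
            i1 = max(i0 + 1, int(round((t0 + design.trial_duration) / dt)))
            box[i0:min(i1, n_fine)] += 1.0
        conv = np.convolve(box, hrf)[:n_fine]
        cols[cond] = conv[::oversample]
    return pd.DataFrame(cols)


def fit_glm(y: np.ndarray, X: pd.DataFrame,
            censor_flags: np.ndarray | None = None) -> tuple[pd.Series, float]:
    """Ordinary least squares of y on the named design columns.

    Censored rows (flag True) are dropped before fitting.  Raises on rank
    deficiency, naming the collinear columns.  Returns (coefficients named by
    column, residual variance with n−p denominator).
    """
    y = np.asarray(y, float)
    A = X.to_numpy(dtype=float)
    if censor_flags is not None:
        keep = ~np.asarray(censor_flags, bool)
        y, A = y[keep], A[keep]
    n, p = A.shape
    if n < p:
        raise ValueError(f"only {n} uncensored rows for {p} columns")
    rank = np.linalg.matrix_rank(A)
    if rank < p:
        # pivoted QR: the trailing pivots point at the dependent columns
        _, _, piv = linalg.qr(A, mode="economic", pivoting=True)
        bad = sorted(X.columns[i] for i in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {bad}")
    beta, res, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    dof = n - p
    sigma2 = float(resid @ resid / dof) if dof > 0 else np.nan
    return pd.Series(beta, index=X.columns), sigma2


@dataclass
class PPIBetas:
    """Per-voxel gPPI fit: interaction (TiFC) and task betas."""

    interaction: pd.DataFrame   # (voxels × conditions) PPI betas = TiFC
    task: pd.DataFrame          # (voxels × conditions) task activation betas
    seed_beta: np.ndarray       # (voxels,) physiological (seed) coefficient
    residual_variance: np.ndarray
    valid: np.ndarray           # False where the voxel had zero variance
    mode: str = "bold"


def _ppi_design(bold: BOLDSeries, design: TaskDesign, block: int,
                conditions: str, hrf_params: dict | None,
                mode: str) -> pd.DataFrame:
    X = build_design_matrix(design, hrf_params, n_timepoints=bold.n_timepoints,
                            block=block, conditions=conditions)
    task_cols = [c for c in X.columns if c != "intercept"]
    seed = bold.seed_series
    if seed.std() == 0:
        raise ValueError("seed series has zero variance")
    seed_c = seed - seed.mean()

    if mode == "bold":
        inter = {f"ppi_{c}": seed_c * (X[c].to_numpy() - X[c].mean())
                 for c in task_cols}
    elif mode == "neural":
        # deconvolve the seed, gate by the raw condition indicator
        # (box-car, mean-centred), reconvolve with the HRF
        neural = _wiener_deconvolve(seed_c, design.tr, hrf_params)
        hrf = double_gamma_hrf(design.tr, 1, hrf_params)
        boxcars = _condition_boxcars(design, block, conditions,
                                     bold.n_timepoints)
        inter = {}
        for c in task_cols:
            gate = boxcars[c] - boxcars[c].mean()
            prod = neural * gate
            recon = np.convolve(prod, hrf)[: bold.n_timepoints]
            inter[f"ppi_{c}"] = recon
    else:
        raise ValueError("mode must be 'bold' or 'neural'")

    out = X.copy()
    out["seed"] = seed
    for name, col in inter.items():
        out[name] = col
    return out


def _condition_boxcars(design: TaskDesign, block: int, conditions: str,
                       n_timepoints: int) -> dict[str, np.ndarray]:
    """Per-condition stimulus indicators sampled at the TR (fractional at edges)."""
    oversample = 16
    sel = design.block == block
    if conditions == "snr":
        labels = design.conditions[sel]
    else:
        labels = np.array([f"snr{s:+d}_{y}" for s, y in
                           zip(design.snr_db[sel], design.syllable[sel])])
    onsets = design.onsets[sel]
    dt = design.tr / oversample
    n_fine = n_timepoints * oversample
    out = {}
    for cond in sorted(set(labels)):
        box = np.zeros(n_fine)
        for t0 in onsets[labels == cond]:
            i0 = int(round(t0 / dt))
            i1 = max(i0 + 1, int(round((t0 + design.trial_duration) / dt)))
            box[i0:min(i1, n_fine)] = 1.0
        out[cond] = box.reshape(n_timepoints, oversample).mean(axis=1)
    return out


def _wiener_deconvolve(y: np.ndarray, tr: float, hrf_params: dict | None,
                       reg: float = 0.1) -> np.ndarray:
    """Regularised deconvolution of the HRF from a series (frequency domain)."""
    n = y.size
    hrf = double_gamma_hrf(tr, 1, hrf_params)
    H = np.fft.rfft(hrf, n)
    Y = np.fft.rfft(y, n)
    X = Y * np.conj(H) / (np.abs(H) ** 2 + reg)
    return np.fft.irfft(X, n)


def compute_ppi_betas(
    bold: BOLDSeries,
    design: TaskDesign,
    mode: str = "bold",
    block: int = 0,
    conditions: str = "snr",
    hrf_params: dict | None = None,
) -> PPIBetas:
    """Fit the gPPI model per target voxel.

    The design contains the intercept, the task regressors, the seed series
    and one PPI regressor per condition; the PPI coefficients are TiFC.
    Zero-variance target voxels are flagged invalid (NaN betas), not zeroed.
    """
    X = _ppi_design(bold, design, block, conditions, hrf_params, mode)
    targets = bold.target_series
    if targets.ndim == 1:
        targets = targets[:, None]
    keep = ~bold.censor_flags
    A = X.to_numpy(dtype=float)[keep]
    Y = targets[keep]
    if A.shape[0] < A.shape[1]:
        raise ValueError("not enough uncensored timepoints for the PPI design")

    valid = Y.std(axis=0) > 0
    betas = np.full((X.shape[1], Y.shape[1]), np.nan)
    resvar = np.full(Y.shape[1], np.nan)
    if valid.any():
        b, _, _, _ = np.linalg.lstsq(A, Y[:, valid], rcond=None)
        betas[:, valid] = b
        resid = Y[:, valid] - A @ b
        dof = A.shape[0] - A.shape[1]
        resvar[valid] = (resid**2).sum(axis=0) / dof

    names = list(X.columns)
    task_cols = [c for c in names if c not in ("intercept", "seed")
                 and not c.startswith("ppi_")]
    ppi_cols = [c for c in names if c.startswith("ppi_")]
    bt = pd.DataFrame(betas.T, columns=names)
    return PPIBetas(
        interaction=bt[ppi_cols].rename(columns=lambda c: c[len("ppi_"):]),
        task=bt[task_cols],
        seed_beta=bt["seed"].to_numpy(),
        residual_variance=resvar,
        valid=valid,
        mode=mode,
    )


def compute_rsfc(
    rest_target: np.ndarray,
    rest_seed_mean: np.ndarray,
    tr: float,
    band: tuple[float, float] = (0.02, 0.1),
    nuisance: np.ndarray | None = None,
    order: int = 4,
) -> np.ndarray:
    """Seed-based resting connectivity: band-passed voxel-wise Pearson r.

    Nuisance series (columns of ``nuisance``) are regressed out of seed and
    targets first; a zero-phase Butterworth band-pass (``order``, applied
    forward-backward) retains ``band`` Hz; the result is the per-voxel Pearson
    correlation with the seed mean series.  One cycle of the low cutoff is
    trimmed from each end before correlating (capped at a quarter of the
    series) to discard the filter's edge transients.
    """
    target = np.asarray(rest_target, float)
    if target.ndim == 1:
        target = target[:, None]
    seed = np.asarray(rest_seed_mean, float)
    n = seed.size
    if target.shape[0] != n:
        raise ValueError("target and seed series lengths differ")
    lo, hi = band
    nyq = 0.5 / tr
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} outside (0, Nyquist={nyq:.3f}) Hz")
    if n * tr < 2.0 / lo:
        raise ValueError("series too short: need >= 2 cycles of the low cutoff")

    if nuisance is not None:
        N = np.asarray(nuisance, float)
        if N.ndim == 1:
            N = N[:, None]
        N = np.column_stack([np.ones(n), N])
        seed = seed - N @ np.linalg.lstsq(N, seed, rcond=None)[0]
        target = target - N @ np.linalg.lstsq(N, target, rcond=None)[0]

    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=1.0 / tr,
                        output="sos")
    seed_f = signal.sosfiltfilt(sos, seed)
    target_f = signal.sosfiltfilt(sos, target, axis=0)

    trim = min(int(np.ceil(1.0 / (lo * tr))), n // 4)
    if trim > 0:
        seed_f = seed_f[trim:n - trim]
        target_f = target_f[trim:n - trim]

    seed_f = seed_f - seed_f.mean()
    target_f = target_f - target_f.mean(axis=0)
    denom = np.sqrt((seed_f**2).sum()) * np.sqrt((target_f**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = target_f.T @ seed_f / denom
    return np.clip(r, -1.0, 1.0)
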