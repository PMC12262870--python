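"""Synthetic cohort generator with known ground truth.

Everything downstream (PPI estimation, ROI statistics, spatial alignment,
bootstrap contrasts) is exercised on data produced here, so each generator
returns the ground-truth parameters alongside the data.

The emulated study: three groups — older musicians (OM), older non-musicians
(ONM) and young non-musicians (YNM), n≈24–25 each — perform a syllable-in-noise
identification task (3 SNR levels × 4 syllables, 60 trials per block, 4 blocks,
jittered ITI 4–6 s in 0.5 s steps, TR 0.64 s).  Per-subject voxel maps of
task-induced connectivity are modelled as a spatial template (isotropic
Gaussian bump) plus a group amplitude offset, an optional group-specific peak
shift along an axis, a smooth subject-specific perturbation field and white
measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .maps import ConnectivityMap, ROIGeometry

SNR_LEVELS_DB = (-8, 0, 8)
SYLLABLES = ("ba", "da", "pa", "ta")


# ---------------------------------------------------------------------------
# Task design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskDesign:
    """Trial timing and condition labels for the syllable-in-noise task.

    Onsets are seconds from the start of each block (blocks are separate
    runs); ``block`` holds the 0-based block index per trial.
    """

    onsets: np.ndarray          # (n_trials,) seconds from block start
    snr_db: np.ndarray          # (n_trials,) int
    syllable: np.ndarray        # (n_trials,) str
    block: np.ndarray           # (n_trials,) int
    iti_values: np.ndarray      # (n_trials,) seconds, ITI after each trial
    tr: float = 0.64
    trial_duration: float = 0.4
    n_blocks: int = 4
    trials_per_block: int = 60

    @property
    def n_trials(self) -> int:
        return self.onsets.size

    @property
    def conditions(self) -> np.ndarray:
        """SNR-pooled condition labels, e.g. ``"snr-8"``."""
        return np.array([f"snr{s:+d}" for s in self.snr_db])

    def block_duration(self, block: int, tail: float = 20.0) -> float:
        """Seconds needed to cover a block's trials plus an HRF tail."""
        sel = self.block == block
        return float(self.onsets[sel].max() + self.trial_duration + tail)


def generate_task_design(
    n_blocks: int = 4,
    snr_levels: tuple[int, ...] = SNR_LEVELS_DB,
    syllables: tuple[str, ...] = SYLLABLES,
    repetitions: int = 5,
    iti_min: float = 4.0,
    iti_max: float = 6.0,
    iti_step: float = 0.5,
    tr: float = 0.64,
    trial_duration: float = 0.4,
    seed: int | np.random.Generator = 0,
) -> TaskDesign:
    """Pseudo-randomised balanced task design.

    Each block contains every SNR × syllable pair ``repetitions`` times in a
    shuffled order, with the inter-trial interval drawn uniformly from the
    grid ``iti_min, iti_min+iti_step, ..., iti_max``.
    """
    if n_blocks < 1 or repetitions < 1 or not snr_levels or not syllables:
        raise ValueError("n_blocks, repetitions and level counts must be positive")
    if tr <= 0 or trial_duration <= 0:
        raise ValueError("tr and trial_duration must be positive")
    n_steps = round((iti_max - iti_min) / iti_step)
    if abs(n_steps * iti_step - (iti_max - iti_min)) > 1e-9:
        raise ValueError("iti_step must divide (iti_max - iti_min)")
    iti_grid = iti_min + iti_step * np.arange(n_steps + 1)

    rng = np.random.default_rng(seed)
    per_block = len(snr_levels) * len(syllables) * repetitions
    base = [(s, y) for s in snr_levels for y in syllables for _ in range(repetitions)]

    onsets, snrs, syls, blocks, itis = [], [], [], [], []
    for b in range(n_blocks):
        order = rng.permutation(per_block)
        block_itis = rng.choice(iti_grid, size=per_block)
        t = 0.0
        for j, idx in enumerate(order):
            s, y = base[idx]
            onsets.append(t)
            snrs.append(s)
            syls.append(y)
            blocks.append(b)
            itis.append(block_itis[j])
            t += trial_duration + block_itis[j]

    return TaskDesign(
        onsets=np.array(onsets),
        snr_db=np.array(snrs, dtype=int),
        syllable=np.array(syls),
        block=np.array(blocks, dtype=int),
        iti_values=np.array(itis),
        tr=tr,
        trial_duration=trial_duration,
        n_blocks=n_blocks,
        trials_per_block=per_block,
    )


# ---------------------------------------------------------------------------
# Group maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters for one group of subjects.

    amplitude_offset shifts every voxel of the template (connectivity units);
    amplitude_sd is the SD of a per-subject scalar offset around it (global
    between-subject amplitude variability); peak_shift_mm displaces the
    template peak; heterogeneity_sd scales a smooth subject-specific random
    field; noise_sd is i.i.d. voxel noise; behavior_slope couples the
    behavioural score to the subject's ROI summary.
    """

    name: str
    n_subjects: int = 25
    amplitude_offset: float = 0.0
    amplitude_sd: float = 0.3
    peak_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    heterogeneity_sd: float = 0.25
    noise_sd: float = 0.3
    behavior_slope: float = 0.0
    behavior_noise_sd: float = 0.05
    behavior_intercept: float = 0.45

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for v in (self.heterogeneity_sd, self.noise_sd, self.behavior_noise_sd,
                  self.amplitude_sd):
            if v < 0:
                raise ValueError("standard deviations must be >= 0")


def gaussian_template(roi: ROIGeometry, shift_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Isotropic Gaussian bump over the ROI's in-mask voxels.

    Peak value = ``roi.template_amplitude``, FWHM = ``roi.template_width_mm``.
    """
    center = np.asarray(roi.template_center_mm, float) + np.asarray(shift_mm, float)
    sigma = roi.template_width_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    d2 = ((roi.coords_mm - center) ** 2).sum(axis=1)
    return roi.template_amplitude * np.exp(-d2 / (2.0 * sigma**2))


def _smooth_field(roi: ROIGeometry, rng: np.random.Generator,
                  smooth_vox: float = 1.5) -> np.ndarray:
    """Unit-SD smooth random field over the ROI (Gaussian-filtered noise)."""
    white = rng.standard_normal(roi.mask.shape)
    smooth = gaussian_filter(white, sigma=smooth_vox)[roi.mask]
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_group_maps(
    spec: GroupSpec,
    roi: ROIGeometry,
    seed: int | np.random.Generator = 0,
    subject_prefix: str | None = None,
) -> tuple[list[ConnectivityMap], dict]:
    """Per-subject connectivity maps for one group on one ROI.

    map_i = template(peak shifted) + amplitude_offset + N(0, amplitude_sd)
            + heterogeneity_sd * smooth_field_i + N(0, noise_sd) per voxel
    (the N(0, amplitude_sd) draw is one scalar per subject).

    Returns the maps and a ground-truth dict (template, per-subject fields).
    """
    rng = np.random.default_rng(seed)
    prefix = subject_prefix or spec.name
    template = gaussian_template(roi, spec.peak_shift_mm)
    maps, fields, amps = [], [], []
    for i in range(spec.n_subjects):
        amp = rng.normal(0.0, spec.amplitude_sd) if spec.amplitude_sd > 0 else 0.0
        pert = spec.heterogeneity_sd * _smooth_field(roi, rng)
        noise = rng.normal(0.0, spec.noise_sd, roi.n_voxels) if spec.noise_sd > 0 \
            else np.zeros(roi.n_voxels)
        values = template + spec.amplitude_offset + amp + pert + noise
        fields.append(pert)
        amps.append(amp)
        maps.append(ConnectivityMap(
            roi=roi, values=values, subject_id=f"{prefix}{i:02d}",
            meta={"group": spec.name},
        ))
    truth = {
        "template": template,
        "amplitude_offset": spec.amplitude_offset,
        "peak_shift_mm": tuple(spec.peak_shift_mm),
        "subject_fields": fields,
        "subject_amplitudes": amps,
    }
    return maps, truth


# ---------------------------------------------------------------------------
# BOLD simulation (ground truth for the gPPI estimator)
# ---------------------------------------------------------------------------

@dataclass
class BOLDSeries:
    """Seed and target time series for one subject/run."""

    seed_series: np.ndarray        # (T,)
    target_series: np.ndarray      # (T,) or (T, V)
    tr: float
    censor_flags: np.ndarray | None = None   # True = censor this TR

    def __post_init__(self) -> None:
        self.seed_series = np.asarray(self.seed_series, float)
        self.target_series = np.asarray(self.target_series, float)
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.censor_flags is None:
            self.censor_flags = np.zeros(self.seed_series.size, dtype=bool)
        self.censor_flags = np.asarray(self.censor_flags, dtype=bool)
        if self.target_series.shape[0] != self.seed_series.size or \
                self.censor_flags.size != self.seed_series.size:
            raise ValueError("seed, target and censor lengths must match")

    @property
    def n_timepoints(self) -> int:
        return self.seed_series.size


def generate_bold(
    design: TaskDesign,
    coupling: dict[str, float],
    baseline_coupling: float = 0.5,
    hrf_params: dict | None = None,
    noise_sd: float = 1.0,
    duration: float | None = None,
    block: int = 0,
    seed: int | np.random.Generator = 0,
) -> tuple[BOLDSeries, dict]:
    """Simulate one block of seed/target BOLD with condition-modulated coupling.

    The seed is the HRF-convolved stimulus stream (all conditions) plus noise.
    The target is ``baseline_coupling * seed`` plus, per condition c, the
    interaction term ``coupling[c] * (seed - mean) * (x_c - mean(x_c))`` —
    exactly the psychophysiological-interaction construction the estimator
    models — plus independent noise.
    """
    # imported here to keep the generator importable without the estimator
    from .timeseries import build_design_matrix

    if duration is None:
        duration = design.block_duration(block)
    last = design.onsets[design.block == block].max() + design.trial_duration
    if duration < last:
        raise ValueError("duration does not cover all trials in the block")
    n_tp = int(np.ceil(duration / design.tr))
    unknown = set(coupling) - set(np.unique(design.conditions))
    if unknown:
        raise ValueError(f"coupling refers to unknown conditions: {sorted(unknown)}")

    X = build_design_matrix(design, hrf_params=hrf_params, n_timepoints=n_tp,
                            block=block)
    task = X.drop(columns="intercept")
    rng = np.random.default_rng(seed)

    stim = task.to_numpy().sum(axis=1)          # combined stimulus stream
    seed_series = stim + rng.normal(0.0, noise_sd, n_tp)
    seed_c = seed_series - seed_series.mean()

    target = baseline_coupling * seed_series
    for cond, amp in coupling.items():
        xc = task[cond].to_numpy()
        target = target + amp * seed_c * (xc - xc.mean())
    target = target + rng.normal(0.0, noise_sd, n_tp)

    truth = {"coupling": dict(coupling), "baseline_coupling": baseline_coupling,
             "noise_sd": noise_sd, "n_timepoints": n_tp}
    return BOLDSeries(seed_series=seed_series, target_series=target,
                      tr=design.tr), truth


# ---------------------------------------------------------------------------
# Behaviour
# ---------------------------------------------------------------------------

def generate_behavior(
    roi_summaries: np.ndarray,
    spec: GroupSpec,
    seed: int | np.random.Generator = 0,
    clip: bool = True,
    snr_effects: dict[int, float] | None = None,
) -> np.ndarray:
    """Behavioural accuracy coupled to each subject's ROI summary.

    score_i = intercept + behavior_slope * summary_i + N(0, behavior_noise_sd),
    clipped to [0, 1] when emulating proportion-correct accuracy.  With
    ``snr_effects`` given, returns an (n, n_snr) array where each SNR column
    adds the corresponding offset before noise (per-SNR accuracies); otherwise
    a single mean accuracy per subject.
    """
    rng = np.random.default_rng(seed)
    summaries = np.asarray(roi_summaries, float)
    base = spec.behavior_intercept + spec.behavior_slope * summaries
    if snr_effects is None:
        scores = base + rng.normal(0.0, spec.behavior_noise_sd, summaries.shape)
    else:
        offs = np.array([snr_effects[s] for s in sorted(snr_effects)])
        scores = base[:, None] + offs[None, :] + rng.normal(
            0.0, spec.behavior_noise_sd, (summaries.size, offs.size))
    return np.clip(scores, 0.0, 1.0) if clip else scores


# ---------------------------------------------------------------------------
# Whole-cohort convenience
# ---------------------------------------------------------------------------

@dataclass
class StudyCohort:
    """Maps, behaviour and group labels for a full three-group study.

    ``maps[measure][roi_name][condition]`` is a list of ConnectivityMap in
    subject order; ``subjects`` is a tidy table (subject_id, group, accuracy).
    """

    specs: dict[str, GroupSpec]
    rois: list[ROIGeometry]
    maps: dict[str, dict[str, dict[str, list[ConnectivityMap]]]]
    subjects: "pd.DataFrame"  # noqa: F821 - imported lazily
    truth: dict = field(default_factory=dict)


def generate_cohort(
    specs: dict[str, GroupSpec],
    rois: list[ROIGeometry],
    conditions: tuple[str, ...] = ("snr-8", "snr+0", "snr+8"),
    measures: tuple[str, ...] = ("tifc",),
    seed: int | np.random.Generator = 0,
    behavior_measure: str = "tifc",
    behavior_roi: str | None = None,
    summary_fraction: float = 0.4,
    measure_offsets: dict[str, dict[str, float]] | None = None,
    cross_measure_corr: float = 0.5,
) -> StudyCohort:
    """Generate a three-group cohort of per-condition voxel maps + behaviour.

    Per subject and ROI a smooth perturbation field is drawn per measure;
    fields of different measures share a common component with correlation
    ``cross_measure_corr`` (task and resting maps of one subject are related
    but not identical).  Within a measure the field is shared across
    conditions; independent measurement noise is added per condition map.
    ``measure_offsets[measure][group]`` overrides the group amplitude offset
    for non-primary measures (e.g. a resting-state measure where both older
    groups sit above the young group).
    """
    import pandas as pd

    from .roistats import select_top_voxels

    rng = np.random.default_rng(seed)
    maps: dict = {m: {r.name: {c: [] for c in conditions} for r in rois}
                  for m in measures}
    rows = []
    truth: dict = {"specs": {g: s for g, s in specs.items()}}

    for gname, spec in specs.items():
        for i in range(spec.n_subjects):
            sid = f"{gname}{i:02d}"
            rows.append({"subject_id": sid, "group": gname})
        # per-subject scalar amplitude: one draw per measure, sharing a
        # common component across measures (corr = cross_measure_corr)
        rho = float(np.clip(cross_measure_corr, 0.0, 1.0))
        amp_shared = rng.normal(0.0, 1.0, spec.n_subjects)
        subj_amp = {}
        for measure in measures:
            own = rng.normal(0.0, 1.0, spec.n_subjects)
            mix = amp_shared if len(measures) == 1 else \
                rho * amp_shared + np.sqrt(1.0 - rho**2) * own
            subj_amp[measure] = spec.amplitude_sd * mix
        for roi in rois:
            template = gaussian_template(roi, spec.peak_shift_mm)
            flat_template = gaussian_template(roi)   # unshifted, for non-tifc
            for i in range(spec.n_subjects):
                sid = f"{gname}{i:02d}"
                shared = _smooth_field(roi, rng)
                for measure in measures:
                    if len(measures) == 1:
                        fld = shared
                    else:
                        own = _smooth_field(roi, rng)
                        fld = rho * shared + np.sqrt(1.0 - rho**2) * own
                    pert = spec.heterogeneity_sd * fld
                    off = spec.amplitude_offset
                    tmpl = template
                    if measure_offsets and measure in measure_offsets:
                        off = measure_offsets[measure].get(gname, 0.0)
                        tmpl = flat_template
                    for cond in conditions:
                        noise = rng.normal(0.0, spec.noise_sd, roi.n_voxels)
                        values = tmpl + off + subj_amp[measure][i] + pert + noise
                        maps[measure][roi.name][cond].append(ConnectivityMap(
                            roi=roi, values=values, subject_id=sid,
                            meta={"group": gname, "condition": cond,
                                  "measure": measure},
                        ))

    subjects = pd.DataFrame(rows)

    # behaviour coupled to the top-fraction summary of the designated ROI
    b_roi = behavior_roi or rois[0].name
    acc = np.empty(len(subjects))
    pos = 0
    for gname, spec in specs.items():
        summaries = []
        for i in range(spec.n_subjects):
            per_cond = np.stack([
                maps[behavior_measure][b_roi][c][_subject_index(specs, gname, i)].values
                for c in conditions])
            ranking = per_cond.mean(axis=0)
            _, mean_val = select_top_voxels(ranking, summary_fraction, ranking)
            summaries.append(mean_val)
        scores = generate_behavior(np.array(summaries), spec, seed=rng)
        acc[pos:pos + spec.n_subjects] = scores
        pos += spec.n_subjects
    subjects["accuracy"] = acc

    truth["behavior_roi"] = b_roi
    return StudyCohort(specs=specs, rois=rois, maps=maps, subjects=subjects,
                       truth=truth)


def _subject_index(specs: dict[str, GroupSpec], gname: str, i: int) -> int:
    """Position of subject i of group gname in the per-ROI map lists."""
    pos = 0
    for g, s in specs.items():
        if g == gname:
            return pos + i
        pos += s.n_subjects
    raise KeyError(gname)
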