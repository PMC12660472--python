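"""Synthetic neurofeedback runs and behavioural cohorts with known ground truth.

Two generators live here:

``simulate_roi_run``
    Voxel x time intensity matrices for a target ROI (posterior cingulate,
    the NF target) and a physiological confound ROI, following a
    multiplicative BOLD-like model around a per-voxel baseline:

        y_v(t) = b_v * (1 + a_v * s(t) + drift_v(t) + l_v * p(t) + eps_v(t))

    where s(t) is the HRF-convolved meditation boxcar with plateau 1,
    a_v = target_deactivation_pct/100 times a per-voxel gain for the subset
    of voxels that carry the effect, p(t) is a low-frequency physiological
    component shared between both ROIs, and eps is white thermal noise.

``simulate_cohort``
    Per-subject behavioural records: State Mindfulness Scale (SMS) Mind and
    Body subscales before/after six 5-min meditation sessions, Stanford
    Sleepiness Scale (SSS) arousal, DASS-21 emotional-distress totals at
    baseline and 1-week follow-up, breath-counting task (BCT) accuracies,
    a simulated seed-coupling beta correlated with distress change in the
    experimental group, age, sex, group, and mean framewise displacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hrf
from .design import MEDITATION, AcquisitionParams, BlockDesign

logger = logging.getLogger(__name__)

SMS_SCALE_MIN = 1.0  # per-item mean scoring of the 5-point SMS
SMS_SCALE_MAX = 5.0
SSS_SCALE_MIN = 1.0
SSS_SCALE_MAX = 8.0
N_BCT_PROBES = 5


@dataclass(frozen=True)
class GroundTruth:
    """Ground-truth parameters of one simulated NF run."""

    target_deactivation_pct: float = -0.5
    coupling_gamma: float = 0.0
    drift_amplitude: float = 0.5       # percent of baseline, peak of slow drift
    physio_sd: float = 0.3             # percent, sd of the shared physio component
    thermal_sd: float = 0.5            # percent, white-noise sd
    signal_fraction: float = 0.5       # fraction of target voxels carrying the effect
    seed: int = 0

    def __post_init__(self):
        vals = (self.target_deactivation_pct, self.coupling_gamma,
                self.drift_amplitude, self.physio_sd, self.thermal_sd)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("ground-truth parameters must be finite")
        if self.physio_sd < 0 or self.thermal_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0 < self.signal_fraction <= 1:
            raise ValueError("signal_fraction must be in (0, 1]")


@dataclass
class RoiRun:
    """Target and confound ROI time series for one NF run."""

    target: np.ndarray      # (n_target_voxels, n_volumes)
    confound: np.ndarray    # (n_confound_voxels, n_volumes)
    design: BlockDesign
    acquisition: AcquisitionParams
    signal_voxels: np.ndarray | None = None  # indices of effect-carrying target voxels
    truth: GroundTruth | None = None

    def __post_init__(self):
        self.target = np.asarray(self.target, dtype=float)
        self.confound = np.asarray(self.confound, dtype=float)
        if self.target.ndim != 2 or self.confound.ndim != 2:
            raise ValueError("ROI matrices must be 2-D (voxels x volumes)")
        if self.target.shape[1] != self.confound.shape[1]:
            raise ValueError("target and confound must share the volume dimension")
        if min(self.target.shape[0], self.confound.shape[0]) < 3:
            raise ValueError("each ROI needs at least 3 voxels")
        if not (np.isfinite(self.target).all() and np.isfinite(self.confound).all()):
            raise ValueError("ROI matrices contain non-finite values")


def _physio_series(rng: np.random.Generator, n_volumes: int, tr: float) -> np.ndarray:
    """Low-frequency nuisance component shared across ROIs, unit variance.

    A sum of slow sinusoids with run-specific frequencies drawn from typical
    drift / respiratory-volume / residual-respiration bands (subjects differ
    in breathing rate, so the bands are sampled rather than fixed) and random
    phases; not a physiological waveform model.
    """
    t = np.arange(n_volumes) * tr
    freqs = np.array([rng.uniform(0.005, 0.02), rng.uniform(0.05, 0.12),
                      rng.uniform(0.2, 0.35)])
    amps = rng.uniform(0.5, 1.0, size=freqs.size)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    p = np.zeros(n_volumes)
    for f, a, ph in zip(freqs, amps, phases):
        p += a * np.sin(2 * np.pi * f * t + ph)
    sd = p.std()
    return p / sd if sd > 0 else p


def simulate_roi_run(design: BlockDesign, acquisition: AcquisitionParams,
                     truth: GroundTruth, n_target_voxels: int = 40,
                     n_confound_voxels: int = 40) -> RoiRun:
    """Simulate one NF run's target and confound ROI matrices.

    Deterministic given ``truth.seed``.  The meditation effect is carried by
    ``round(signal_fraction * n_target_voxels)`` voxels (at least 1) with
    per-voxel gains that average exactly 1, so the mean amplitude of the
    carriers equals ``target_deactivation_pct``.
    """
    if n_target_voxels < 3 or n_confound_voxels < 3:
        raise ValueError("voxel counts must be >= 3")
    rng = np.random.default_rng(truth.seed)
    n_vol = acquisition.n_volumes
    tr = acquisition.tr_seconds
    t = np.arange(n_vol) * tr

    s = design.regressor(MEDITATION, n_vol, tr, convolve=True)

    n_sig = max(1, int(round(truth.signal_fraction * n_target_voxels)))
    carriers = np.sort(rng.choice(n_target_voxels, size=n_sig, replace=False))
    gains = rng.uniform(0.7, 1.3, size=n_sig)
    gains /= gains.mean()
    amp = np.zeros(n_target_voxels)
    amp[carriers] = truth.target_deactivation_pct / 100.0 * gains

    baseline_t = rng.uniform(900.0, 1100.0, size=n_target_voxels)
    baseline_c = rng.uniform(900.0, 1100.0, size=n_confound_voxels)

    drift_amp = truth.drift_amplitude / 100.0
    tau = (t / t[-1] - 0.5) if n_vol > 1 else np.zeros(1)

    def drift_matrix(n_voxels):
        lin = rng.uniform(-1, 1, size=n_voxels)[:, None] * tau[None, :]
        ph = rng.uniform(0, 2 * np.pi, size=n_voxels)
        cos = 0.5 * np.cos(2 * np.pi * t[None, :] / max(t[-1], tr) + ph[:, None])
        return drift_amp * (lin + cos)

    drift_t = drift_matrix(n_target_voxels)
    drift_c = drift_matrix(n_confound_voxels)

    p = _physio_series(rng, n_vol, tr)
    load_t = truth.physio_sd / 100.0 * rng.uniform(0.5, 1.5, size=n_target_voxels)
    load_c = truth.physio_sd / 100.0 * rng.uniform(0.5, 1.5, size=n_confound_voxels)

    eps_t = rng.normal(0, truth.thermal_sd / 100.0, size=(n_target_voxels, n_vol))
    eps_c = rng.normal(0, truth.thermal_sd / 100.0, size=(n_confound_voxels, n_vol))

    target = baseline_t[:, None] * (
        1 + amp[:, None] * s[None, :] + drift_t + load_t[:, None] * p[None, :] + eps_t
    )
    confound = baseline_c[:, None] * (
        1 + drift_c + load_c[:, None] * p[None, :] + eps_c
    )
    return RoiRun(target=target, confound=confound, design=design,
                  acquisition=acquisition, signal_voxels=carriers, truth=truth)


@dataclass(frozen=True)
class CohortConfig:
    """Ground truth for a simulated behavioural cohort.

    Group order everywhere is (experimental, control).  SMS slopes are in
    mean-score units per day of the residual-awareness trajectory; DASS
    change means/SDs are follow-up minus baseline totals; ``bct_change_d``
    are the targeted group-difference Cohen's d for task and probe accuracy
    changes; ``coupling_distress_r`` is the within-experimental-group
    correlation between the simulated seed-coupling beta and DASS change.
    """

    n_per_group: int = 19
    session_days: tuple = (0.0, 3.0, 4.0, 5.0, 6.0, 7.0)
    sms_slope_mean_by_group: tuple = (0.05, -0.05)
    sms_slope_sd: float = 0.06
    sms_noise_sd: float = 0.25
    sms_body_slope_mean_by_group: tuple = (0.0, 0.0)
    dass_change_mean_by_group: tuple = (-4.8, -1.6)
    dass_change_sd_by_group: tuple = (5.0, 3.6)
    bct_change_d: tuple = (0.39, 0.56)
    bct_task_change_sd: float = 10.0
    coupling_mean_by_group: tuple = (-0.07, 0.08)
    coupling_sd: float = 0.11
    coupling_distress_r: float = 0.71
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        days = np.asarray(self.session_days, dtype=float)
        if days.size != 6 or np.any(np.diff(days) <= 0):
            raise ValueError("session_days must be 6 strictly increasing values")
        if abs(self.coupling_distress_r) >= 1:
            raise ValueError("|coupling_distress_r| must be < 1")
        for sd in (*self.dass_change_sd_by_group, self.sms_slope_sd,
                   self.sms_noise_sd, self.bct_task_change_sd, self.coupling_sd):
            if sd < 0:
                raise ValueError("SDs must be >= 0")
        if self.sms_noise_sd == 0 and self.sms_slope_sd > 0:
            pass  # allowed: slope heterogeneity without measurement noise


# generative covariate effects on post-meditation SMS (shared by Mind/Body)
_SMS_B0 = 1.2
_SMS_B_PRE = 0.5
_SMS_B_SSS = -0.08
_SMS_B_AGE = 0.0
_SMS_B_SEX = 0.0


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate one behavioural cohort as a wide per-subject table.

    Columns (T = timepoints 0..5): subject_id, group, age, sex,
    sms_mind_pre_T, sms_mind_post_T, sms_body_pre_T, sms_body_post_T, sss_T,
    dass_baseline, dass_followup, bct_task_baseline, bct_task_followup,
    bct_probe_baseline, bct_probe_followup, coupling_beta, mfd.
    Deterministic given ``config.seed``; SMS values are clipped to the
    instrument bounds after noise and clip events are logged.
    """
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_per_group
    days = np.asarray(config.session_days, dtype=float)
    group = np.array(["experimental"] * config.n_per_group
                     + ["control"] * config.n_per_group)
    gidx = (group == "control").astype(int)  # 0 = experimental, 1 = control
    sex = np.tile([0, 1], n)[:n]  # balanced binary covariate
    age = rng.uniform(19.0, 50.0, size=n)

    sss = rng.normal(3.0, 0.8, size=(n, 6)).clip(SSS_SCALE_MIN, SSS_SCALE_MAX)

    rows = {"subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "group": group, "age": age, "sex": sex}
    n_clipped = 0

    for subscale, slope_means in (
        ("mind", config.sms_slope_mean_by_group),
        ("body", config.sms_body_slope_mean_by_group),
    ):
        trait = rng.normal(3.3, 0.4, size=n)
        pre = trait[:, None] + rng.normal(0, config.sms_noise_sd, size=(n, 6))
        slopes = (np.asarray(slope_means)[gidx]
                  + config.sms_slope_sd * rng.standard_normal(n))
        post = (
            _SMS_B0
            + _SMS_B_PRE * trait[:, None]
            + _SMS_B_SSS * sss.mean(axis=1)[:, None]
            + _SMS_B_AGE * age[:, None]
            + _SMS_B_SEX * sex[:, None]
            + slopes[:, None] * days[None, :]
            + rng.normal(0, config.sms_noise_sd, size=(n, 6))
        )
        for mat in (pre, post):
            clipped = (mat < SMS_SCALE_MIN) | (mat > SMS_SCALE_MAX)
            n_clipped += int(clipped.sum())
            np.clip(mat, SMS_SCALE_MIN, SMS_SCALE_MAX, out=mat)
        for t in range(6):
            rows[f"sms_{subscale}_pre_{t}"] = pre[:, t]
            rows[f"sms_{subscale}_post_{t}"] = post[:, t]
    if n_clipped:
        logger.info("simulate_cohort: clipped %d SMS values to [%g, %g]",
                    n_clipped, SMS_SCALE_MIN, SMS_SCALE_MAX)
    for t in range(6):
        rows[f"sss_{t}"] = sss[:, t]

    # DASS change and seed-coupling beta: bivariate in the experimental group
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    r = np.where(gidx == 0, config.coupling_distress_r, 0.0)
    coupling = (np.asarray(config.coupling_mean_by_group)[gidx]
                + config.coupling_sd * z1)
    dass_mean = np.asarray(config.dass_change_mean_by_group)[gidx]
    dass_sd = np.asarray(config.dass_change_sd_by_group)[gidx]
    dass_change = dass_mean + dass_sd * (r * z1 + np.sqrt(1 - r**2) * z2)
    dass_baseline = np.maximum(rng.normal(12.0, 6.0, size=n), 0.0)
    rows["dass_baseline"] = dass_baseline
    rows["dass_followup"] = dass_baseline + dass_change
    rows["coupling_beta"] = coupling

    # BCT task accuracy: continuous percent, targeted group-difference d
    task_base = rng.normal(75.0, 12.0, size=n).clip(0.0, 100.0)
    task_shift = np.where(gidx == 0, -config.bct_change_d[0] * config.bct_task_change_sd, 0.0)
    task_change = task_shift + rng.normal(0, config.bct_task_change_sd, size=n)
    rows["bct_task_baseline"] = task_base
    rows["bct_task_followup"] = (task_base + task_change).clip(0.0, 100.0)

    # BCT probe accuracy: correct probes out of 5, percent scale (discrete)
    p0 = 0.85
    probe_sd_counts = np.sqrt(2 * N_BCT_PROBES * p0 * (1 - p0))
    p1 = float(np.clip(p0 - config.bct_change_d[1] * probe_sd_counts / N_BCT_PROBES,
                       0.05, 0.95))
    probe_base = rng.binomial(N_BCT_PROBES, p0, size=n)
    p_follow = np.where(gidx == 0, p1, p0)
    probe_follow = rng.binomial(N_BCT_PROBES, p_follow)
    rows["bct_probe_baseline"] = 100.0 * probe_base / N_BCT_PROBES
    rows["bct_probe_followup"] = 100.0 * probe_follow / N_BCT_PROBES

    rows["mfd"] = np.abs(rng.normal(0.12, 0.04, size=n))
    return pd.DataFrame(rows)


def cohort_column_dictionary() -> dict:
    """Human-readable description of every cohort CSV column."""
    d = {
        "subject_id": "participant identifier",
        "group": "experimental (veridical NF) or control (yoked sham)",
        "age": "age in years",
        "sex": "binary indicator (0/1), balanced",
        "dass_baseline": "DASS-21 total, week before baseline",
        "dass_followup": "DASS-21 total, post-NF week",
        "bct_task_baseline": "breath counting task accuracy %, baseline",
        "bct_task_followup": "breath counting task accuracy %, follow-up",
        "bct_probe_baseline": "breath counting probe accuracy %, baseline",
        "bct_probe_followup": "breath counting probe accuracy %, follow-up",
        "coupling_beta": "simulated seed-coupling (gPPI) beta, session 2",
        "mfd": "mean framewise displacement (mm)",
    }
    for t in range(6):
        d[f"sms_mind_pre_{t}"] = f"SMS-Mind mean score before session {t}"
        d[f"sms_mind_post_{t}"] = f"SMS-Mind mean score after session {t}"
        d[f"sms_body_pre_{t}"] = f"SMS-Body mean score before session {t}"
        d[f"sms_body_post_{t}"] = f"SMS-Body mean score after session {t}"
        d[f"sss_{t}"] = f"Stanford Sleepiness Scale mean rating, session {t}"
    return d
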