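"""Real-time intermittent neurofeedback engine.

The engine streams volumes of the target (PCC) and confound ROIs through a
cumulative ("incremental") general linear model with intercept, linear trend
and the HRF-convolved meditation regressor.  After each meditation block it:

1. selects the 33% of target voxels most responsive to meditation vs. rest
   (most negative meditation t-statistic — deactivation is rewarded);
2. computes their per-volume percent signal change (PSC) against the
   cumulative rest baseline (intercept + trend prediction);
3. residualizes the target PSC series against the confound-ROI PSC series
   with a cumulative least-squares fit (online physiological control);
4. averages the residualized PSC over the haemodynamically shifted block
   window to obtain the NF score; and
5. maps the score onto a 20-level thermometer (higher = more deactivation).

In yoked-sham mode the displayed scores are a matched donor's stored scores,
replayed verbatim, while the recipient's own scores are still computed and
logged for the blinding check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import MEDITATION, BlockDesign
from .synthetic import RoiRun

logger = logging.getLogger(__name__)


class ScoringError(RuntimeError):
    """Raised when block scoring hits degenerate intensities."""


class ReplayError(RuntimeError):
    """Raised when a sham schedule cannot be replayed against the session."""


@dataclass(frozen=True)
class NfConfig:
    """Configuration of the online scoring engine.

    ``score_floor_pct``/``score_ceiling_pct`` define the linear thermometer
    mapping: a residual PSC at the ceiling (default 0%) maps to level 1 and
    at the floor (default -1%) to the top level.  ``block_statistic`` chooses
    between the block mean of the per-volume PSC (default) and the per-block
    extremum ("peak").
    """

    responsive_fraction: float = 0.33
    thermometer_levels: int = 20
    score_floor_pct: float = -1.0
    score_ceiling_pct: float = 0.0
    hemodynamic_shift_s: float = 4.0
    mode: str = "veridical"
    block_statistic: str = "mean"  # or "peak" (most negative per-volume PSC)

    def __post_init__(self):
        if not 0 < self.responsive_fraction <= 1:
            raise ValueError("responsive_fraction must be in (0, 1]")
        if self.thermometer_levels < 2:
            raise ValueError("thermometer_levels must be >= 2")
        if not self.score_floor_pct < self.score_ceiling_pct:
            raise ValueError("score_floor_pct must be < score_ceiling_pct")
        if self.mode not in ("veridical", "sham"):
            raise ValueError("mode must be 'veridical' or 'sham'")
        if self.block_statistic not in ("mean", "peak"):
            raise ValueError("block_statistic must be 'mean' or 'peak'")


class IncrementalGlm:
    """Cumulative least-squares GLM updated one volume at a time.

    Maintains the sufficient statistics (X'X, X'Y, Y'Y) of the ordinary
    least-squares fit on all volumes seen so far; coefficients at volume t
    equal a full refit on volumes 1..t.  Volumes with non-finite intensities
    are rejected with a warning and leave the state unchanged.
    """

    def __init__(self, n_columns: int, n_voxels: int, store_data: bool = True):
        self.k = int(n_columns)
        self.n_voxels = int(n_voxels)
        self.xtx = np.zeros((self.k, self.k))
        self.xty = np.zeros((self.k, self.n_voxels))
        self.yty = np.zeros(self.n_voxels)
        self.volumes_seen = 0
        self._rows = [] if store_data else None
        self._data = [] if store_data else None

    def update(self, design_row: np.ndarray, volume: np.ndarray) -> "IncrementalGlm":
        row = np.asarray(design_row, dtype=float)
        vol = np.asarray(volume, dtype=float)
        if row.shape != (self.k,):
            raise ValueError(f"design_row must have length {self.k}, got {row.shape}")
        if vol.shape != (self.n_voxels,):
            raise ValueError(f"volume must have length {self.n_voxels}")
        if not np.isfinite(vol).all():
            warnings.warn("rejected volume with non-finite intensities; state unchanged",
                          stacklevel=2)
            return self
        self.xtx += np.outer(row, row)
        self.xty += np.outer(row, vol)
        self.yty += vol**2
        self.volumes_seen += 1
        if self._rows is not None:
            self._rows.append(row)
            self._data.append(vol)
        return self

    @property
    def ready(self) -> bool:
        """True once the fit is determined (>= n_columns + 1 volumes)."""
        return self.volumes_seen >= self.k + 1

    def coefficients(self) -> np.ndarray:
        """(k, n_voxels) OLS coefficients on all volumes so far."""
        if not self.ready:
            raise RuntimeError(
                f"underdetermined: {self.volumes_seen} volumes for {self.k} columns"
            )
        return np.linalg.solve(self.xtx, self.xty)

    def t_statistics(self, column: int) -> np.ndarray:
        """Per-voxel t-statistic of one design column."""
        beta = self.coefficients()
        dof = self.volumes_seen - self.k
        if dof < 1:
            raise RuntimeError("no residual degrees of freedom yet")
        rss = self.yty - np.einsum("kv,kv->v", beta, self.xty)
        sigma2 = np.maximum(rss, 0.0) / dof
        var_beta = sigma2 * np.linalg.inv(self.xtx)[column, column]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[column] / np.sqrt(var_beta)
        return np.where(var_beta > 0, t, 0.0)

    @property
    def design_so_far(self) -> np.ndarray:
        if self._rows is None:
            raise RuntimeError("state was created with store_data=False")
        return np.asarray(self._rows)

    @property
    def data_so_far(self) -> np.ndarray:
        """(n_voxels, volumes_seen) raw intensities accepted so far."""
        if self._data is None:
            raise RuntimeError("state was created with store_data=False")
        return np.asarray(self._data).T

    def baseline_prediction(self, baseline_columns) -> np.ndarray:
        """(n_voxels, volumes_seen) cumulative rest-baseline prediction.

        The prediction from the baseline design columns only (intercept and
        trend), i.e. the model's estimate of what the signal would be in the
        absence of the task effect.
        """
        beta = self.coefficients()
        X = self.design_so_far
        cols = list(baseline_columns)
        return (X[:, cols] @ beta[cols, :]).T

    def psc_series(self, baseline_columns) -> np.ndarray:
        """(n_voxels, volumes_seen) percent signal change vs. the baseline."""
        baseline = self.baseline_prediction(baseline_columns)
        if np.any(baseline <= 0):
            raise ScoringError("baseline prediction <= 0: degenerate intensities")
        return 100.0 * (self.data_so_far - baseline) / baseline


def update_incremental_glm(state: IncrementalGlm, new_volume, design_row) -> IncrementalGlm:
    """Functional wrapper over :meth:`IncrementalGlm.update`."""
    return state.update(design_row, new_volume)


def select_responsive_voxels(state: IncrementalGlm, config: NfConfig,
                             meditation_column: int = 2) -> np.ndarray:
    """Indices of the most deactivation-responsive voxels.

    The ``max(1, floor(fraction * V))`` voxels with the most negative
    meditation-vs-rest t-statistic; ties broken by ascending voxel id.
    """
    if not state.ready:
        raise RuntimeError("cannot select voxels before the GLM is determined")
    t = state.t_statistics(meditation_column)
    n_sel = max(1, int(np.floor(config.responsive_fraction * state.n_voxels)))
    order = np.lexsort((np.arange(state.n_voxels), t))  # ascending t, then id
    return np.sort(order[:n_sel])


def _block_window(onset_s: float, duration_s: float, tr: float, shift_s: float,
                  n_available: int) -> np.ndarray:
    """Volume indices of the haemodynamically shifted block window."""
    t = np.arange(n_available) * tr
    lo, hi = onset_s + shift_s, onset_s + duration_s + shift_s
    idx = np.nonzero((t >= lo) & (t < hi))[0]
    if idx.size == 0:
        raise ScoringError("shifted block window contains no acquired volumes")
    return idx


def compute_block_psc(state: IncrementalGlm, selected_voxels, block_onset_s: float,
                      block_duration_s: float, tr: float, shift_s: float = 4.0,
                      baseline_columns=(0, 1), statistic: str = "mean") -> float:
    """Raw block PSC: selected-voxel mean PSC summarised over the shifted window.

    Intermittent contract: the block must have fully elapsed, i.e. the state
    must contain every volume of the shifted window.
    """
    n = state.volumes_seen
    end_needed = block_onset_s + block_duration_s + shift_s
    if (n - 1) * tr < end_needed - tr:
        raise ScoringError(
            f"block not fully elapsed: have {n} volumes, window ends at {end_needed:g} s"
        )
    psc = state.psc_series(baseline_columns)[np.asarray(selected_voxels)]
    window = _block_window(block_onset_s, block_duration_s, tr, shift_s, n)
    per_volume = psc[:, window].mean(axis=0)
    if statistic == "peak":
        return float(per_volume.min())
    return float(per_volume.mean())


def residualize_against_confound(raw_psc_series, confound_psc_series) -> np.ndarray:
    """Residuals of a cumulative least-squares fit of target on confound PSC.

    The fit (intercept + confound) uses all volumes of both series; the
    residuals are orthogonal to the confound over the fitted window.  A
    constant confound series degrades to an intercept-only fit with a warning.
    """
    y = np.asarray(raw_psc_series, dtype=float)
    c = np.asarray(confound_psc_series, dtype=float)
    if y.shape != c.shape or y.ndim != 1:
        raise ValueError("series must be 1-D and equal length")
    if np.ptp(c) == 0:
        warnings.warn("constant confound series; intercept-only fit", stacklevel=2)
        return y - y.mean()
    X = np.column_stack([np.ones_like(c), c])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def map_to_thermometer(residual_psc: float, config: NfConfig) -> int:
    """Linear map of residual PSC onto thermometer levels 1..L.

    The ceiling (default 0% PSC) maps to level 1 and the floor (default -1%)
    to level L; values outside are clipped; rounding is half away from zero.
    Monotone non-increasing in the residual PSC, so deeper deactivation
    yields a higher bar.
    """
    L = config.thermometer_levels
    span = config.score_ceiling_pct - config.score_floor_pct
    frac = (config.score_ceiling_pct - residual_psc) / span
    frac = min(max(frac, 0.0), 1.0)
    level = np.floor(1 + (L - 1) * frac + 0.5)  # half away from zero (values >= 1)
    return int(min(max(level, 1), L))


@dataclass
class NfScore:
    """One meditation block's feedback record."""

    run_index: int
    block_index: int
    raw_psc: float
    residual_psc: float
    thermometer_level: int
    selected_voxel_ids: np.ndarray
    displayed_level: int | None = None  # differs from thermometer_level under sham


@dataclass
class ShamSchedule:
    """A matched donor's stored scores for yoked-sham replay."""

    donor_id: str
    donor_scores: list  # list of NfScore in block order across the session
    matching_key: float = 0.0  # donor meditation-experience hours


def match_sham_donor(donors: dict, recipient_experience_hours: float) -> str:
    """Donor id with nearest meditation-experience hours; ties by donor id."""
    if not donors:
        raise ReplayError("no donors available for sham matching")
    items = sorted(donors.items(), key=lambda kv: (abs(kv[1] - recipient_experience_hours), kv[0]))
    return items[0][0]


def run_nf_session(run_data, config: NfConfig, sham: ShamSchedule | None = None,
                   cue_feedback_regressors: bool = False):
    """Score a full NF session (list of runs), emitting 6 scores per run.

    Returns ``(scores, log)`` where ``scores`` is a list of :class:`NfScore`
    in block order and ``log`` a tidy per-block DataFrame.  In sham mode the
    displayed levels are the donor's stored levels verbatim while the
    recipient's own raw/residual PSC and level are computed and logged for
    the blinding check.
    """
    runs = list(run_data)
    if config.mode == "sham":
        if sham is None:
            raise ReplayError("sham mode requires a ShamSchedule")
        expected = sum(len(r.design.of_condition(MEDITATION)) for r in runs)
        if len(sham.donor_scores) != expected:
            raise ReplayError(
                f"donor has {len(sham.donor_scores)} scores, session needs {expected}"
            )
    scores: list[NfScore] = []
    records = []
    for run_index, run in enumerate(runs):
        run_scores = _score_one_run(run, config, run_index,
                                    cue_feedback_regressors=cue_feedback_regressors)
        scores.extend(run_scores)
    if config.mode == "sham":
        for own, donor in zip(scores, sham.donor_scores):
            own.displayed_level = donor.thermometer_level
    else:
        for own in scores:
            own.displayed_level = own.thermometer_level
    for s in scores:
        records.append({
            "run": s.run_index, "block": s.block_index, "raw_psc": s.raw_psc,
            "residual_psc": s.residual_psc, "level": s.thermometer_level,
            "displayed_level": s.displayed_level,
            "n_selected": len(s.selected_voxel_ids),
        })
    log = pd.DataFrame.from_records(records)
    return scores, log


def _score_one_run(run: RoiRun, config: NfConfig, run_index: int,
                   cue_feedback_regressors: bool = False) -> list:
    tr = run.acquisition.tr_seconds
    n_vol = run.target.shape[1]
    t = np.arange(n_vol) * tr
    columns = [np.ones(n_vol), (t - t.mean()) / max(t[-1] - t[0], tr)]
    names = ["intercept", "trend"]
    columns.append(run.design.regressor(MEDITATION, n_vol, tr, convolve=True))
    names.append(MEDITATION)
    if cue_feedback_regressors:
        for cond in ("cue", "feedback"):
            if run.design.of_condition(cond):
                columns.append(run.design.regressor(cond, n_vol, tr, convolve=True))
                names.append(cond)
    X = np.column_stack(columns)
    med_col = names.index(MEDITATION)
    base_cols = (0, 1)

    target_glm = IncrementalGlm(X.shape[1], run.target.shape[0])
    confound_glm = IncrementalGlm(X.shape[1], 1)
    confound_mean = run.confound.mean(axis=0)

    blocks = run.design.of_condition(MEDITATION)
    pending = sorted(blocks, key=lambda e: e.onset)
    block_end_vol = [
        int(np.ceil((e.onset + e.duration + config.hemodynamic_shift_s) / tr)) - 1
        for e in pending
    ]
    scores = []
    next_block = 0
    for i in range(n_vol):
        target_glm.update(X[i], run.target[:, i])
        confound_glm.update(X[i], confound_mean[i:i + 1])
        while next_block < len(pending) and i == min(block_end_vol[next_block], n_vol - 1):
            block = pending[next_block]
            selected = select_responsive_voxels(target_glm, config, med_col)
            target_psc = target_glm.psc_series(base_cols)[selected].mean(axis=0)
            confound_psc = confound_glm.psc_series(base_cols)[0]
            residual = residualize_against_confound(target_psc, confound_psc)
            window = _block_window(block.onset, block.duration, tr,
                                   config.hemodynamic_shift_s, target_glm.volumes_seen)
            if config.block_statistic == "peak":
                raw = float(target_psc[window].min())
                res = float(residual[window].min())
            else:
                raw = float(target_psc[window].mean())
                res = float(residual[window].mean())
            scores.append(NfScore(
                run_index=run_index, block_index=next_block, raw_psc=raw,
                residual_psc=res, thermometer_level=map_to_thermometer(res, config),
                selected_voxel_ids=selected,
            ))
            next_block += 1
    if next_block != len(pending):
        raise ScoringError(
            f"run ended before all blocks could be scored ({next_block}/{len(pending)})"
        )
    return scores
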