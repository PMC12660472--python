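"""Offline inference on neurofeedback sessions.

Contains the offline block GLM (activation betas for meditation vs. rest),
generalized psychophysiological interaction (gPPI) estimation of
condition-dependent seed coupling, a max-statistic cluster-level permutation
test for group differences, and baseline-to-transfer functional-connectivity
change scores.

gPPI model per voxel: intercept + trend + condition regressors + mean seed
time course + (seed x centred condition regressor) terms + nuisance.  The
PPI contrast is the meditation-minus-rest difference of the interaction
coefficients; negative values indicate stronger negative coupling with the
seed during meditation.  No deconvolution is applied (block design).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .design import CUE, FEEDBACK, MEDITATION, REST, BlockDesign


class CollinearityError(ValueError):
    """Raised when a design is rank deficient, naming the offending columns."""


def _check_rank(X: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate near-dependent columns via the R diagonal of a pivoted QR
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.nonzero(diag < 1e-8 * diag.max())[0]]
        raise CollinearityError(f"rank-deficient design; collinear columns: {bad or names}")


def _condition_number_guard(X: np.ndarray, names: list, limit: float = 1e8) -> None:
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] == 0 or sv[0] / sv[-1] > limit:
        raise CollinearityError(
            f"ill-conditioned design (condition number > {limit:g}); columns: {names}"
        )


def _as_matrix(data: np.ndarray):
    """Accept (V, T) matrices or (nx, ny, nz, T) grids; return (V, T) + shape."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        return data, None
    if data.ndim == 4:
        shape = data.shape[:3]
        return data.reshape(-1, data.shape[3]), shape
    raise ValueError("data must be (voxels, volumes) or a 4-D grid")


def _ols(X: np.ndarray, Y: np.ndarray):
    """OLS of Y (T, V) on X (T, k); returns beta (k, V), sigma2 (V,), XtX_inv."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    return beta, sigma2, xtx_inv, dof


@dataclass
class GlmFit:
    """Per-voxel condition betas and the meditation-vs-rest contrast."""

    beta: np.ndarray            # (k, V)
    column_names: list
    contrast: np.ndarray        # (V,) meditation - rest, negative = deactivation
    contrast_t: np.ndarray      # (V,)
    sigma2: np.ndarray
    dof: int
    grid_shape: tuple | None = None


def _condition_regressors(design: BlockDesign, n_volumes: int, tr: float,
                          convolve: bool = True):
    cols, names = [], []
    for cond in (MEDITATION, REST, CUE, FEEDBACK):
        if design.of_condition(cond):
            cols.append(design.regressor(cond, n_volumes, tr, convolve=convolve))
            names.append(cond)
    return cols, names


def _base_design(n_volumes: int, tr: float):
    t = np.arange(n_volumes) * tr
    trend = (t - t.mean()) / max(t[-1] - t[0], tr)
    return [np.ones(n_volumes), trend], ["intercept", "trend"]


def fit_block_glm(data, design: BlockDesign, tr: float, nuisance=None,
                  scale_psc: bool = True) -> GlmFit:
    """Voxel-wise GLM of the blocked run; contrast = meditation - rest.

    ``data`` is (voxels, volumes) or a 4-D grid.  With ``scale_psc`` each
    voxel is converted to percent signal change around its mean, so the
    contrast is in PSC units (the condition regressors have plateau 1).
    """
    Y2, grid_shape = _as_matrix(data)
    V, T = Y2.shape
    if scale_psc:
        mean = Y2.mean(axis=1, keepdims=True)
        if np.any(mean <= 0):
            raise ValueError("non-positive voxel means; cannot scale to PSC")
        Y2 = 100.0 * (Y2 / mean - 1.0)
    cols, names = _base_design(T, tr)
    cond_cols, cond_names = _condition_regressors(design, T, tr)
    cols += cond_cols
    names += cond_names
    if nuisance is not None:
        nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuis.shape[0] != T:
            nuis = nuis.T
        for j in range(nuis.shape[1]):
            cols.append(nuis[:, j])
            names.append(f"nuisance_{j}")
    X = np.column_stack(cols)
    _check_rank(X, names)
    beta, sigma2, xtx_inv, dof = _ols(X, Y2.T)
    c = np.zeros(X.shape[1])
    if MEDITATION in names:
        c[names.index(MEDITATION)] = 1.0
    if REST in names:
        c[names.index(REST)] = -1.0
    contrast = c @ beta
    var_c = sigma2 * float(c @ xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_map = np.where(var_c > 0, contrast / np.sqrt(var_c), 0.0)
    return GlmFit(beta=beta, column_names=names, contrast=contrast,
                  contrast_t=t_map, sigma2=sigma2, dof=dof, grid_shape=grid_shape)


@dataclass
class GppiResult:
    """Per-voxel PPI coefficients for the meditation-vs-rest seed coupling."""

    gamma: np.ndarray           # (V,) PPI contrast (meditation - rest interaction)
    gamma_t: np.ndarray
    beta: np.ndarray
    column_names: list
    dof: int
    subject_id: str | None = None
    session_id: str | None = None
    grid_shape: tuple | None = None


def fit_gppi(data, seed_series, design: BlockDesign, tr: float, nuisance=None,
             convolve_psych: bool = True, subject_id=None, session_id=None) -> GppiResult:
    """Generalized PPI fit seeded on ``seed_series``.

    The psychological regressors are mean-centred before forming the
    seed x condition products (the estimate is therefore invariant to adding
    a constant to the seed).  Raises :class:`CollinearityError` when a
    condition never occurs or the PPI columns are collinear with the main
    effects.
    """
    Y2, grid_shape = _as_matrix(data)
    V, T = Y2.shape
    seed = np.asarray(seed_series, dtype=float)
    if seed.shape != (T,):
        raise ValueError("seed series must match the volume dimension")
    seed_c = seed - seed.mean()

    cols, names = _base_design(T, tr)
    ppi_names = []
    for cond in (MEDITATION, REST):
        if not design.of_condition(cond):
            raise CollinearityError(f"design has no {cond} events; PPI undefined")
        reg = design.regressor(cond, T, tr, convolve=convolve_psych)
        if np.ptp(reg) == 0:
            raise CollinearityError(f"constant {cond} regressor; PPI undefined")
        cols.append(reg)
        names.append(cond)
        cols.append(seed_c * (reg - reg.mean()))
        ppi_name = f"ppi_{cond}"
        names.append(ppi_name)
        ppi_names.append(ppi_name)
    for cond in (CUE, FEEDBACK):
        if design.of_condition(cond):
            cols.append(design.regressor(cond, T, tr, convolve=convolve_psych))
            names.append(cond)
    cols.append(seed_c)
    names.append("seed")
    if nuisance is not None:
        nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuis.shape[0] != T:
            nuis = nuis.T
        for j in range(nuis.shape[1]):
            cols.append(nuis[:, j])
            names.append(f"nuisance_{j}")
    X = np.column_stack(cols)
    _check_rank(X, names)
    _condition_number_guard(X / np.linalg.norm(X, axis=0, keepdims=True), names)
    beta, sigma2, xtx_inv, dof = _ols(X, Y2.T)
    c = np.zeros(X.shape[1])
    c[names.index("ppi_meditation")] = 1.0
    c[names.index("ppi_rest")] = -1.0
    gamma = c @ beta
    var_c = sigma2 * float(c @ xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_map = np.where(var_c > 0, gamma / np.sqrt(var_c), 0.0)
    return GppiResult(gamma=gamma, gamma_t=t_map, beta=beta, column_names=names,
                      dof=dof, subject_id=subject_id, session_id=session_id,
                      grid_shape=grid_shape)


@dataclass(frozen=True)
class PermutationConfig:
    """Cluster-level permutation test settings (6-neighbour connectivity)."""

    n_permutations: int = 1000
    cluster_forming_p: float = 0.005
    fwe_alpha: float = 0.05
    tail: str = "one"           # "one": group A > group B; "two": either direction
    # mass (sum of supra-threshold |t|) by default: on unsmoothed grids the
    # extent null is so discrete (max cluster of 1-2 voxels) that extent-based
    # FWE p-values cannot be calibrated; extent remains available
    cluster_statistic: str = "mass"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.cluster_forming_p < self.fwe_alpha <= 1:
            raise ValueError("need 0 < cluster_forming_p < fwe_alpha <= 1")
        if self.n_permutations < 100:
            raise ValueError("n_permutations < 100 gives an unstable tail; refusing")
        if self.tail not in ("one", "two"):
            raise ValueError("tail must be 'one' or 'two'")
        if self.cluster_statistic not in ("extent", "mass"):
            raise ValueError("cluster_statistic must be 'extent' or 'mass'")


_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def _residualize_columns(maps: np.ndarray, covariates) -> tuple:
    """Regress covariates (plus intercept) out of each voxel column."""
    n = maps.shape[0]
    if covariates is None:
        return maps, 0
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] != n:
        Z = Z.T
    X = np.column_stack([np.ones(n), Z])
    beta, *_ = np.linalg.lstsq(X, maps, rcond=None)
    return maps - X @ beta, Z.shape[1]


def _two_sample_t_batch(group_sum, group_sumsq, n1, total_sum, total_sumsq, n):
    """Pooled-variance two-sample t from per-permutation group sums."""
    n2 = n - n1
    m1 = group_sum / n1
    m2 = (total_sum - group_sum) / n2
    ss1 = group_sumsq - n1 * m1**2
    ss2 = (total_sumsq - group_sumsq) - n2 * m2**2
    sp2 = (ss1 + ss2) / (n - 2)
    denom = np.sqrt(np.maximum(sp2, 0.0) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return np.where(denom > 0, t, 0.0)


def _cluster_stats(exceed: np.ndarray, tvals: np.ndarray, statistic: str):
    """Cluster labels, sizes and masses on a 3-D boolean exceedance map."""
    labels, n_clusters = ndimage.label(exceed, structure=_STRUCT_6)
    if n_clusters == 0:
        return labels, np.array([], dtype=int), np.array([])
    sizes = np.bincount(labels.ravel())[1:]
    if statistic == "mass":
        masses = ndimage.sum_labels(np.abs(tvals), labels, index=np.arange(1, n_clusters + 1))
    else:
        masses = sizes.astype(float)
    return labels, sizes, masses


def group_permutation_test(subject_maps, groups, config: PermutationConfig,
                           covariates=None, grid_shape=None):
    """Cluster-level FWE permutation test of a group difference on maps.

    Parameters
    ----------
    subject_maps : (n_subjects, V) array or (n_subjects, nx, ny, nz)
    groups : boolean/0-1 array, True/1 for group A (statistic is A - B)
    covariates : optional (n_subjects, k); residualized out before permuting

    Returns a dict with the observed t-map, the cluster table (label, size,
    mass, statistic, fwe_p), the significant-cluster mask, and the
    cluster-forming threshold.  FWE p-values use the max-cluster-statistic
    null with the (1 + exceedances) / (1 + permutations) convention.
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim == 4:
        grid_shape = maps.shape[1:]
        maps = maps.reshape(maps.shape[0], -1)
    if grid_shape is None:
        raise ValueError("grid_shape is required for cluster formation")
    g = np.asarray(groups).astype(bool)
    n = maps.shape[0]
    n1 = int(g.sum())
    if n1 < 2 or n - n1 < 2:
        raise ValueError("need at least 2 subjects per group")

    maps, k_cov = _residualize_columns(maps, covariates)
    dof = n - 2 - k_cov
    if config.tail == "one":
        t_crit = stats.t.ppf(1 - config.cluster_forming_p, dof)
    else:
        t_crit = stats.t.ppf(1 - config.cluster_forming_p / 2, dof)

    total_sum = maps.sum(axis=0)
    total_sumsq = (maps**2).sum(axis=0)

    def tmap_for(indicator):
        gs = indicator @ maps
        gss = indicator @ maps**2
        return _two_sample_t_batch(gs, gss, n1, total_sum, total_sumsq, n)

    obs_t = tmap_for(g.astype(float)[None, :])[0]
    obs_exceed = (obs_t > t_crit) if config.tail == "one" else (np.abs(obs_t) > t_crit)
    labels, sizes, masses = _cluster_stats(
        obs_exceed.reshape(grid_shape), obs_t.reshape(grid_shape), config.cluster_statistic
    )

    rng = np.random.default_rng(config.seed)
    P = config.n_permutations
    indicators = np.zeros((P, n))
    for p in range(P):
        idx = rng.permutation(n)[:n1]
        indicators[p, idx] = 1.0

    max_stat = np.zeros(P)
    batch = 128
    for start in range(0, P, batch):
        tb = tmap_for(indicators[start:start + batch])
        exceed = (tb > t_crit) if config.tail == "one" else (np.abs(tb) > t_crit)
        for j in range(tb.shape[0]):
            if not exceed[j].any():
                continue
            _, _, m = _cluster_stats(exceed[j].reshape(grid_shape),
                                     tb[j].reshape(grid_shape), config.cluster_statistic)
            if m.size:
                max_stat[start + j] = m.max()

    records = []
    sig_mask = np.zeros(grid_shape, dtype=bool)
    for i, (size, mass) in enumerate(zip(sizes, masses), start=1):
        stat = mass
        fwe_p = (1.0 + float((max_stat >= stat).sum())) / (1.0 + P)
        records.append({"label": i, "size": int(size), "mass": float(mass),
                        "statistic": float(stat), "fwe_p": fwe_p})
        if fwe_p <= config.fwe_alpha:
            sig_mask |= labels == i
    table = pd.DataFrame.from_records(
        records, columns=["label", "size", "mass", "statistic", "fwe_p"]
    )
    return {
        "t_map": obs_t.reshape(grid_shape),
        "threshold": float(t_crit),
        "clusters": table,
        "significant_mask": sig_mask,
        "max_null": max_stat,
        "dof": dof,
    }


@dataclass(frozen=True)
class FcChange:
    """Baseline and transfer seed-cluster correlations and their change."""

    baseline_r: float
    transfer_r: float

    @property
    def delta(self) -> float:
        return self.transfer_r - self.baseline_r


def _pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and paired")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance series: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def fc_change(seed_baseline, cluster_baseline, seed_transfer, cluster_transfer) -> FcChange:
    """Pearson FC per task and the transfer-minus-baseline change."""
    return FcChange(
        baseline_r=_pearson(seed_baseline, cluster_baseline),
        transfer_r=_pearson(seed_transfer, cluster_transfer),
    )
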