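"""Simulation studies validating the pipeline against its own ground truth.

Each function runs a self-contained, seeded Monte-Carlo study at desk scale:
type-I calibration of the cluster permutation test, gPPI recovery, the
streaming-vs-batch GLM equivalence, yoked-sham blinding behaviour, and
recovery of the behavioural endpoint effects.  They are used by the test
suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import behavior, nf, offline, synthetic
from .design import AcquisitionParams, make_block_design


def streaming_batch_max_deviation(n_instances: int = 100, n_volumes: int = 40,
                                  n_voxels: int = 5, seed: int = 0) -> float:
    """Worst absolute deviation between incremental and full-refit OLS.

    Random design (intercept, trend, noise regressor) and random data; the
    incremental coefficients are compared against ``numpy.linalg.lstsq`` at
    every volume from the first determined fit onward.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        X = np.column_stack([np.ones(n_volumes), np.linspace(-1, 1, n_volumes),
                             rng.normal(size=n_volumes)])
        Y = rng.normal(size=(n_volumes, n_voxels))
        state = nf.IncrementalGlm(3, n_voxels)
        for t in range(n_volumes):
            state.update(X[t], Y[t])
            if state.ready:
                batch, *_ = np.linalg.lstsq(X[: t + 1], Y[: t + 1], rcond=None)
                dev = np.abs(state.coefficients() - batch).max()
                worst = max(worst, float(dev))
    return worst


def null_fwe_rate(n_datasets: int = 200, n_permutations: int = 500,
                  grid_shape=(20, 20, 10), n_per_group: int = 17,
                  seed: int = 0) -> float:
    """Empirical FWE rejection rate of the cluster permutation test under the null.

    Each dataset is pure standard-normal noise for two groups; a dataset
    counts as a rejection when any cluster reaches FWE p <= alpha.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    rejections = 0
    n = 2 * n_per_group
    g = np.arange(n) < n_per_group
    for i in range(n_datasets):
        maps = rng.normal(size=(n, *grid_shape))
        cfg = offline.PermutationConfig(
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31)),
        )
        out = offline.group_permutation_test(maps, g, cfg)
        if out["significant_mask"].any():
            rejections += 1
    return rejections / n_datasets


def gppi_recovery(gamma_true: float = 0.4, n_seeds: int = 100, n_voxels: int = 10,
                  noise_sd: float = 1.5, seed: int = 0) -> float:
    """Mean recovered PPI modulation across seeded replicates."""
    acq = AcquisitionParams()
    design = make_block_design(acq)
    n, tr = acq.n_volumes, acq.tr_seconds
    reg = design.regressor("meditation", n, tr, convolve=True)
    reg_c = reg - reg.mean()
    rng = np.random.default_rng(seed)
    gammas = []
    for _ in range(n_seeds):
        seed_series = 1000 + 5 * np.sin(np.arange(n) * 0.07) + rng.normal(0, 2, n)
        vox = (1000.0 + gamma_true * (seed_series - seed_series.mean()) * reg_c
               + rng.normal(0, noise_sd, size=(n_voxels, n)))
        res = offline.fit_gppi(vox, seed_series, design, tr)
        gammas.append(res.gamma.mean())
    return float(np.mean(gammas))


def sham_blinding_nonsignificant_fraction(n_pairs: int = 100, n_voxels: int = 16,
                                          seed: int = 0, alpha: float = 0.05) -> float:
    """Fraction of donor/recipient pairs whose displayed sham scores are
    uncorrelated (p > alpha) with the recipient's own block PSC.

    Donor and recipient sessions are simulated independently; the displayed
    scores are the donor's residualized block scores replayed verbatim, the
    recipient's actual activity is their raw block PSC, and the correlation
    is computed across the session's 18 blocks.
    """
    acq = AcquisitionParams()
    design = make_block_design(acq)
    rng = np.random.default_rng(seed)
    nonsig = 0
    for _ in range(n_pairs):
        def session(base_seed):
            runs = [
                synthetic.simulate_roi_run(
                    design, acq,
                    synthetic.GroundTruth(target_deactivation_pct=-0.5,
                                          seed=base_seed + r),
                    n_voxels, n_voxels)
                for r in range(3)
            ]
            return nf.run_nf_session(runs, nf.NfConfig())
        donor_scores, donor_log = session(int(rng.integers(2**31 - 10)))
        _, recip_log = session(int(rng.integers(2**31 - 10)))
        displayed = donor_log["residual_psc"].to_numpy()
        actual = recip_log["raw_psc"].to_numpy()
        _, p = stats.pearsonr(displayed, actual)
        if p > alpha:
            nonsig += 1
    return nonsig / n_pairs


def endpoint_recovery(n_small: int = 200, n_large: int = 20,
                      large_n_per_group: int = 2000, seed: int = 0) -> dict:
    """Recovery of the behavioural endpoint effects from replicate cohorts.

    Returns the direction-match rates at large n (DASS group effect negative,
    SMS-Mind slope difference positive) and the small-n (19/group) means of
    the estimated SMS slope difference and the DASS ANCOVA group coefficient.
    """
    rng = np.random.default_rng(seed)

    dass_neg = slope_pos = 0
    for _ in range(n_large):
        cohort = synthetic.simulate_cohort(
            synthetic.CohortConfig(n_per_group=large_n_per_group,
                                   seed=int(rng.integers(2**31))))
        is_exp = (cohort["group"] == "experimental").to_numpy()
        covs = cohort[["age", "sex"]].to_numpy(dtype=float)
        diff = (cohort["dass_followup"] - cohort["dass_baseline"]).to_numpy()
        if behavior.ancova_difference_scores(diff, is_exp, covs).statistic < 0:
            dass_neg += 1
        resid = behavior.residualize_sms(cohort, "mind")
        slopes = behavior.fit_subject_slopes(resid, (0, 3, 4, 5, 6, 7))
        e = np.mean([s.slope for s in slopes if s.group == "experimental"])
        c = np.mean([s.slope for s in slopes if s.group == "control"])
        if e - c > 0:
            slope_pos += 1

    slope_diffs, dass_coefs = [], []
    for _ in range(n_small):
        cohort = synthetic.simulate_cohort(
            synthetic.CohortConfig(seed=int(rng.integers(2**31))))
        resid = behavior.residualize_sms(cohort, "mind")
        slopes = behavior.fit_subject_slopes(resid, (0, 3, 4, 5, 6, 7))
        e = np.mean([s.slope for s in slopes if s.group == "experimental"])
        c = np.mean([s.slope for s in slopes if s.group == "control"])
        slope_diffs.append(e - c)
        is_exp = (cohort["group"] == "experimental").to_numpy()
        covs = cohort[["age", "sex"]].to_numpy(dtype=float)
        diff = (cohort["dass_followup"] - cohort["dass_baseline"]).to_numpy()
        X = np.column_stack([np.ones(len(diff)), is_exp.astype(float),
                             (covs - covs.mean(0)) / covs.std(0)])
        beta = np.linalg.lstsq(X, diff, rcond=None)[0]
        dass_coefs.append(beta[1])

    return {
        "dass_direction_match_rate": dass_neg / n_large,
        "sms_slope_direction_match_rate": slope_pos / n_large,
        "sms_slope_diff_mean_n19": float(np.mean(slope_diffs)),
        "dass_group_effect_mean_n19": float(np.mean(dass_coefs)),
    }


def ranksum_exact_agreement(seed: int = 0) -> float:
    """Fraction of small-sample splits where the exact rank-sum p equals a
    brute-force enumeration over all label assignments (combined n <= 10)."""
    from itertools import combinations
    from math import comb

    rng = np.random.default_rng(seed)
    agree = total = 0
    for n1 in range(3, 8):
        for n2 in range(3, 11 - n1):
            for _ in range(3):
                pooled = rng.integers(-3, 4, size=n1 + n2).astype(float)
                if np.ptp(pooled) == 0:
                    continue
                mine = behavior.ranksum_probe(pooled[:n1], pooled[n1:]).raw_p
                ranks = stats.rankdata(pooled)
                mu = n1 * (n1 + n2 + 1) / 2
                obs = abs(ranks[:n1].sum() - mu)
                count = sum(
                    1 for idx in combinations(range(n1 + n2), n1)
                    if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-12
                )
                oracle = count / comb(n1 + n2, n1)
                total += 1
                agree += abs(mine - oracle) < 1e-12
    return agree / total if total else 1.0
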