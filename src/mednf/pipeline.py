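"""End-to-end desk-scale pipeline: simulate -> NF scoring -> gPPI -> endpoints.

``pipeline_run`` chains every stage on synthetic data with one global seed
(per-stage seeds are derived with the documented splitting rule) and writes a
manifest.  Any stage failure aborts with the stage name while the manifest
records the partial progress and the failure reason.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, io, nf, offline, synthetic
from .design import MEDITATION, AcquisitionParams, make_block_design

STAGES = ("simulate", "nf_run", "gppi", "behavior", "report")

DEFAULT_CONFIG = {
    "n_subjects_imaging": 4,       # simulated NF participants (half sham)
    "n_target_voxels": 30,
    "n_confound_voxels": 30,
    "n_runs": 3,
    "target_deactivation_pct": -0.5,
    "coupling_gamma": 0.3,
    "n_per_group": 19,
    "gppi_grid_voxels": 60,
    "fdr_q": 0.05,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def _simulate_subject_runs(acq, design, seed, n_runs, cfg):
    runs = []
    for r in range(n_runs):
        truth = synthetic.GroundTruth(
            target_deactivation_pct=cfg["target_deactivation_pct"],
            coupling_gamma=cfg["coupling_gamma"], seed=seed + r,
        )
        runs.append(synthetic.simulate_roi_run(
            design, acq, truth, cfg["n_target_voxels"], cfg["n_confound_voxels"]))
    return runs


def pipeline_run(config: dict | None = None, seed: int = 0, out_dir="results") -> io.RunManifest:
    """Run the full synthetic study once; deterministic given the seed."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = io.stage_seeds(seed, STAGES)
    manifest = io.RunManifest(seed=seed, config=cfg, stage_seeds=seeds)
    manifest_path = out / "manifest.json"

    try:
        _run_stages(cfg, seeds, out, manifest)
    except StageError as exc:
        manifest.failures[exc.stage] = str(exc.original)
        manifest.write(manifest_path)
        raise
    manifest.write(manifest_path)
    return manifest


def _run_stages(cfg, seeds, out: Path, manifest: io.RunManifest) -> None:
    acq = AcquisitionParams()
    design = make_block_design(acq)

    # --- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        cohort = synthetic.simulate_cohort(
            synthetic.CohortConfig(n_per_group=cfg["n_per_group"], seed=seeds[stage]))
        cohort_path = out / "cohort.csv"
        io.write_cohort_csv(cohort, cohort_path)
        manifest.add(stage, "cohort", cohort_path)

        subjects = []
        for s in range(cfg["n_subjects_imaging"]):
            runs = _simulate_subject_runs(acq, design, seeds[stage] + 100 * (s + 1),
                                          cfg["n_runs"], cfg)
            paths = io.write_roi_run(runs[0], out / "imaging", prefix=f"sub{s:02d}_run0")
            manifest.add(stage, f"sub{s:02d}_run0_target", paths["target"])
            subjects.append(runs)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # --- nf_run: veridical for donors, yoked sham for the other half ------
    stage = "nf_run"
    try:
        half = len(subjects) // 2
        nf_logs = []
        donor_scores = []
        for s, runs in enumerate(subjects[:half]):
            scores, log = nf.run_nf_session(runs, nf.NfConfig(mode="veridical"))
            donor_scores.append(scores)
            log.insert(0, "subject", f"sub{s:02d}")
            log.insert(1, "mode", "veridical")
            nf_logs.append(log)
        for s, runs in enumerate(subjects[half:], start=half):
            sham = nf.ShamSchedule(donor_id=f"sub{s - half:02d}",
                                   donor_scores=donor_scores[s - half])
            _, log = nf.run_nf_session(runs, nf.NfConfig(mode="sham"), sham=sham)
            log.insert(0, "subject", f"sub{s:02d}")
            log.insert(1, "mode", "sham")
            nf_logs.append(log)
        nf_log = pd.concat(nf_logs, ignore_index=True)
        nf_path = out / "nf_scores.csv"
        io._atomic_write(nf_path, lambda tmp: nf_log.to_csv(tmp, index=False))
        manifest.add(stage, "scores", nf_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- gppi at desk scale ------------------------------------------------
    stage = "gppi"
    try:
        rng = np.random.default_rng(seeds[stage])
        gammas = []
        for s, runs in enumerate(subjects):
            run = runs[0]
            seed_series = run.target.mean(axis=0)
            reg = design.regressor(MEDITATION, acq.n_volumes, acq.tr_seconds)
            reg_c = reg - reg.mean()
            grid = (1000.0
                    + cfg["coupling_gamma"] * (seed_series - seed_series.mean())[None, :]
                    * reg_c[None, :]
                    + rng.normal(0, 5.0, size=(cfg["gppi_grid_voxels"], acq.n_volumes)))
            res = offline.fit_gppi(grid, seed_series, design, acq.tr_seconds,
                                   subject_id=f"sub{s:02d}")
            gammas.append(res.gamma.mean())
        gppi_path = out / "gppi_gamma.csv"
        frame = pd.DataFrame({"subject": [f"sub{s:02d}" for s in range(len(subjects))],
                              "mean_gamma": gammas})
        io._atomic_write(gppi_path, lambda tmp: frame.to_csv(tmp, index=False))
        manifest.add(stage, "gamma", gppi_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- behaviour ---------------------------------------------------------
    stage = "behavior"
    try:
        table = behavior.run_endpoints(cohort, fdr_q=cfg["fdr_q"])
        table_path = out / "endpoints.csv"
        io._atomic_write(table_path, lambda tmp: table.to_csv(tmp, index=False))
        manifest.add(stage, "endpoints", table_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- report ------------------------------------------------------------
    stage = "report"
    try:
        report = {
            "endpoints": table.to_dict(orient="records"),
            "nf": {
                "n_scores": int(len(nf_log)),
                "mean_residual_psc": float(nf_log["residual_psc"].mean()),
                "mean_level": float(nf_log["level"].mean()),
            },
            "gppi": {"mean_gamma": float(np.mean(gammas))},
        }
        report_path = out / "report.json"
        io.write_json(report_path, report)
        manifest.add(stage, "report", report_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
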