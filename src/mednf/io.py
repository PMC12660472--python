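"""Readers, writers and run manifests.

Grids travel as NIfTI-1 (4-D, RAS+), ROI masks as 0/1 NIfTI, events as
BIDS-style TSV (onset, duration, trial_type; seconds), cohorts as CSV with a
JSON column dictionary, and configuration as YAML/JSON.  All writes are
atomic (write to a temporary sibling, then rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import AcquisitionParams, BlockDesign
from .synthetic import RoiRun, cohort_column_dictionary


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the expected format."""


def _atomic_write(path: Path, write_fn) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_nifti(path, data: np.ndarray, voxel_size_mm: float = 1.6) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    # keep the full NIfTI extension on the temp name so nibabel picks the format
    tmp = path.with_name(f".tmp-{os.getpid()}-{path.name}")
    try:
        nib.save(img, str(tmp))
        os.replace(tmp, path)
    finally:
        if tmp.exists():
            tmp.unlink()


def read_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def write_events_tsv(path, design: BlockDesign) -> None:
    frame = design.to_frame()
    _atomic_write(Path(path), lambda tmp: frame.to_csv(tmp, sep="\t", index=False))


def read_events_tsv(path, run_length_seconds: float) -> BlockDesign:
    frame = pd.read_csv(path, sep="\t")
    missing = {"onset", "duration", "trial_type"} - set(frame.columns)
    if missing:
        raise FormatError(f"events TSV missing columns: {sorted(missing)}")
    if not frame["onset"].is_monotonic_increasing:
        raise FormatError("events TSV onsets are not monotone non-decreasing")
    try:
        return BlockDesign.from_frame(frame, run_length_seconds)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_roi_run(run: RoiRun, out_dir, prefix: str = "run") -> dict:
    """Write a RoiRun as target/confound 4-D NIfTI + masks + events TSV.

    ROI-collapsed matrices are stored on a (V, 1, 1, T) grid; the masks mark
    every stored voxel.  Returns the path dictionary.
    """
    out = Path(out_dir)
    paths = {
        "target": out / f"{prefix}_target.nii.gz",
        "confound": out / f"{prefix}_confound.nii.gz",
        "target_mask": out / f"{prefix}_target_mask.nii.gz",
        "confound_mask": out / f"{prefix}_confound_mask.nii.gz",
        "events": out / f"{prefix}_events.tsv",
    }
    for key, mat in (("target", run.target), ("confound", run.confound)):
        grid = mat[:, None, None, :]
        write_nifti(paths[key], grid)
        write_nifti(paths[f"{key}_mask"], np.ones(grid.shape[:3], dtype=np.float32))
    write_events_tsv(paths["events"], run.design)
    return {k: str(v) for k, v in paths.items()}


def read_roi_run(target_nifti, confound_nifti, target_mask, confound_mask,
                 events_tsv, acquisition: AcquisitionParams) -> RoiRun:
    """Load and validate a RoiRun written by :func:`write_roi_run`.

    Masks are applied as ``mask > 0``; grids must share the volume dimension.
    """
    def _extract(grid_path, mask_path, name):
        grid = read_nifti(grid_path)
        if grid.ndim != 4:
            raise FormatError(f"{name} grid must be 4-D")
        mask = read_nifti(mask_path)
        if mask.shape != grid.shape[:3]:
            raise FormatError(f"{name} mask shape {mask.shape} does not match "
                              f"grid {grid.shape[:3]}")
        sel = mask > 0
        if not sel.any():
            raise FormatError(f"{name} mask selects 0 voxels")
        return grid[sel, :]

    target = _extract(target_nifti, target_mask, "target")
    confound = _extract(confound_nifti, confound_mask, "confound")
    if target.shape[1] != confound.shape[1]:
        raise FormatError("target and confound grids disagree on the volume dimension")
    design = read_events_tsv(events_tsv, acquisition.run_length_seconds)
    return RoiRun(target=target, confound=confound, design=design,
                  acquisition=acquisition)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    _atomic_write(Path(path), lambda tmp: cohort.to_csv(tmp, index=False))
    dict_path = Path(path).with_suffix(".columns.json")
    write_json(dict_path, cohort_column_dictionary())


def read_cohort_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"subject_id", "group", "age", "sex", "dass_baseline", "dass_followup"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"cohort CSV missing columns: {sorted(missing)}")
    return frame


def write_json(path, payload) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    _atomic_write(Path(path), lambda tmp: Path(tmp).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_default) + "\n"
    ))


def read_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_config(path, payload: dict) -> None:
    _atomic_write(Path(path), lambda tmp: Path(tmp).write_text(
        yaml.safe_dump(payload, sort_keys=True)
    ))


@dataclass
class RunManifest:
    """Record of one pipeline invocation: artifact paths, config, seeds."""

    seed: int
    config: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    stage_seeds: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)
    version: str = __version__
    created: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def add(self, stage: str, name: str, path) -> None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"manifest entry does not exist: {path}")
        self.artifacts.setdefault(stage, {})[name] = str(path)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "config": self.config, "artifacts": self.artifacts,
            "stage_seeds": self.stage_seeds, "failures": self.failures,
            "version": self.version, "created": self.created,
        }

    def write(self, path) -> None:
        write_json(path, self.to_dict())


def stage_seeds(global_seed: int, stages) -> dict:
    """Derive one child seed per stage from the global seed.

    Splitting rule: ``numpy.random.SeedSequence(global_seed).spawn(n)``, one
    child per stage in the given order; children are reduced to a 31-bit
    integer for portability.
    """
    children = np.random.SeedSequence(global_seed).spawn(len(list(stages)))
    return {stage: int(child.generate_state(1)[0] % (2**31))
            for stage, child in zip(stages, children)}
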