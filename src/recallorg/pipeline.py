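"""End-to-end pipeline: simulate -> score -> analyze, with a manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as rio
from .config import RunConfig
from .scoring import adjacent_remote_summary, score_cohort
from .simulate import SimParams, simulate_study, write_cohort
from .stats import analyze_measures
from .types import measures_frame

__all__ = ["PipelineStageError", "run_pipeline"]

logger = logging.getLogger("recallorg")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: Path | str) -> Path:
    """Run simulate -> score -> analyze and write all artifacts.

    Returns the artifact directory. A ``manifest.yaml`` records the
    package version, per-stage sub-seeds and SHA-256 digests of every
    output, so a rerun with the same config is verifiably identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    artifacts: dict[str, Path] = {}

    stage = "simulate"
    try:
        _log(stage, f"seed={seeds[stage]} subjects={config.sim.n_subjects}")
        params = dataclasses.replace(config.sim, seed=seeds[stage])
        cohort = simulate_study(params)
        artifacts.update(write_cohort(cohort, outdir))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineStageError(stage, exc) from exc

    stage = "score"
    try:
        lists = rio.read_study_lists(artifacts["lists"])
        sim = rio.read_similarity_matrix(artifacts["similarity"])
        recalls = rio.read_recalls(artifacts["recalls"])
        _log(stage, f"{len(recalls)} transcripts, {len(lists)} lists")
        measures, curves = score_cohort(
            recalls,
            lists,
            sim=sim,
            max_edit_distance=config.max_edit_distance,
            semantic_possible=config.semantic_possible,  # type: ignore[arg-type]
        )
        mframe = measures_frame(measures)
        artifacts["measures"] = outdir / "measures.csv"
        mframe.to_csv(artifacts["measures"], index=False)
        crp_rows = []
        for cond, curve in curves.items():
            crp = curve.crp
            for lag, c, npos in zip(curve.lags, crp, curve.possible):
                crp_rows.append(
                    {"condition": cond, "lag": int(lag), "crp": c,
                     "n_possible": int(npos)}
                )
            summary = adjacent_remote_summary(curve)
            _log(stage, f"{cond}: adjacent/remote {summary}")
        artifacts["lag_crp"] = outdir / "lag_crp.csv"
        pd.DataFrame(crp_rows).to_csv(artifacts["lag_crp"], index=False)
        spc_rows = []
        for m in measures:
            for pos, v in enumerate(m.spc, start=1):
                spc_rows.append(
                    {"subject_id": m.subject_id, "condition": m.condition,
                     "serial_position": pos, "recalled": int(v)}
                )
        artifacts["spc"] = outdir / "spc.csv"
        pd.DataFrame(spc_rows).to_csv(artifacts["spc"], index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    stage = "analyze"
    try:
        mframe = pd.read_csv(artifacts["measures"])
        contrasts = analyze_measures(
            mframe, n_perm=config.n_perm, seed=seeds[stage]
        )
        artifacts["contrasts"] = outdir / "contrasts.csv"
        contrasts.to_csv(artifacts["contrasts"], index=False)
        _log(stage, f"{len(contrasts)} contrasts written")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    manifest = {
        "recallorg_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "config": dataclasses.asdict(config),
        "artifacts": {k: {"path": p.name, "sha256": _digest(p)}
                      for k, p in sorted(artifacts.items())},
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir
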