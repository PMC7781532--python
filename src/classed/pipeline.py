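"""End-to-end orchestration of the four-stage revision workflow.

Stages (each optional, consuming the previous stage's outputs):

1. ``estimate`` — network-wide default parameter estimation on all contexts.
2. ``validate`` — classified qualitative validation report.
3. ``deletion`` / ``morris`` — key-reaction identification per context.
4. ``sobol`` — variance decomposition over the Morris-selected subset.
5. ``calibrate_ec50`` — per-reaction EC50 calibration on the key subset.
6. ``crosstalk`` — OR/AND edge-addition screen.

A global seed fans out to deterministic per-stage seeds, every stage writes
an append-only artifact under the output directory, and a run manifest
records the config snapshot, input hashes, seeds and per-stage objective
values so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import calibrate_ec50, estimate_defaults
from .crosstalk import (
    enumerate_and_candidates,
    enumerate_or_candidates,
    screen_crosstalks,
)
from .lde_engine import SimulationConfig
from .model import ExperimentRecord, ModelError, NetworkModel, ParameterSet
from .network_io import parse_experiments, parse_network
from .sensitivity import (
    ObjectiveSpec,
    deletion_scan,
    morris_screen,
    select_important,
    sobol_analysis,
)
from .validation import validate

__all__ = ["RunManifest", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)

_STAGES = (
    "estimate",
    "validate",
    "deletion",
    "morris",
    "sobol",
    "calibrate_ec50",
    "crosstalk",
)


@dataclass
class RunManifest:
    config: Dict
    input_hashes: Dict[str, str]
    seeds: Dict[str, int]
    stage_outputs: Dict[str, str]
    objectives: Dict[str, float]
    version: str = ""

    def write(self, path: Path) -> Path:
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2, default=float))
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out, kept below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _make_objective(stage_cfg, model, params, records, factors, context,
                    sim_config) -> ObjectiveSpec:
    """GSA objective per stage config: context validation percent (default)
    or mean output-node activity (continuous alternative)."""
    kind = stage_cfg.get("objective", "validation")
    if kind == "validation":
        return ObjectiveSpec.for_validation(
            model, params, records, factors=factors, config=sim_config
        )
    if kind == "output_activity":
        from .model import Perturbation

        perts = [Perturbation("stimulus", context)] if context else []
        return ObjectiveSpec.for_output_activity(
            model, params, perts, factors=factors, config=sim_config
        )
    raise ModelError(f"unknown GSA objective {kind!r}")


def load_config(path) -> Dict:
    path = Path(path)
    if not path.exists():
        raise ModelError(f"config file {path} not found")
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(
    config: Mapping,
    model: Optional[NetworkModel] = None,
    records: Optional[Sequence[ExperimentRecord]] = None,
) -> RunManifest:
    """Execute the configured stages in order and write a run manifest.

    ``config`` keys: ``model`` / ``data`` (paths, unless objects are passed
    directly), ``context``, ``stages`` (subset of the stage names in order),
    ``seed``, ``outdir``, plus optional per-stage sections.  Missing stage
    dependencies (e.g. Sobol without a Morris subset or configured factor
    list) raise before any computation of that stage.
    """
    cfg = dict(config)
    outdir = Path(cfg.get("outdir", "classed_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg.get("stages", _STAGES))
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise ModelError(f"unknown pipeline stages {unknown}")
    seed = int(cfg.get("seed", 0))
    sim_config = SimulationConfig(**cfg.get("simulation", {}))

    input_hashes: Dict[str, str] = {}
    if model is None:
        model_path = Path(cfg["model"])
        if not model_path.exists():
            raise ModelError(f"model path {model_path} not found")
        for f in sorted(model_path.glob("*.csv")) if model_path.is_dir() else [model_path]:
            input_hashes[str(f)] = _sha256(f)
        model = parse_network(model_path)
    if records is None:
        data_path = Path(cfg["data"])
        if not data_path.exists():
            raise ModelError(f"data path {data_path} not found")
        input_hashes[str(data_path)] = _sha256(data_path)
        records = parse_experiments(data_path)

    context = cfg.get("context")
    ctx_records = [r for r in records if context is None or r.context == context]
    qual = [r for r in ctx_records if not r.is_semiquant]
    semi = [r for r in ctx_records if r.is_semiquant]
    records_by_context: Dict[str, List[ExperimentRecord]] = {}
    for r in records:
        if not r.is_semiquant:
            records_by_context.setdefault(r.context, []).append(r)

    params = ParameterSet()
    seeds: Dict[str, int] = {}
    stage_outputs: Dict[str, str] = {}
    objectives: Dict[str, float] = {}
    morris_subset: Optional[List[str]] = cfg.get("factors")

    for stage in stages:
        s_seed = _stage_seed(seed, stage)
        seeds[stage] = s_seed
        log.info("stage %s (seed %d)", stage, s_seed)

        if stage == "estimate":
            est_cfg = cfg.get("estimate", {})
            all_qual = [r for r in records if not r.is_semiquant]
            bounds_cfg = est_cfg.get("bounds")
            est = estimate_defaults(
                model,
                all_qual,
                bounds={k: tuple(v) for k, v in bounds_cfg.items()}
                if bounds_cfg
                else None,
                n_starts=int(est_cfg.get("n_starts", 20)),
                seed=s_seed,
                maxiter=int(est_cfg.get("maxiter", 60)),
                config=sim_config,
            )
            params = est.best_params
            out = outdir / "estimate.json"
            out.write_text(
                json.dumps(
                    {
                        "best_values": est.best_values,
                        "best_objective": est.best_objective,
                        "n_starts": est.n_starts,
                        "seed": s_seed,
                    },
                    indent=2,
                )
            )
            stage_outputs[stage] = str(out)
            objectives[stage] = est.best_objective

        elif stage == "validate":
            report = validate(model, params, qual, config=sim_config)
            out = outdir / "validation.csv"
            report.to_frame().to_csv(out, index=False)
            (outdir / "validation_summary.json").write_text(
                json.dumps(report.summary(), indent=2, default=str)
            )
            stage_outputs[stage] = str(out)
            objectives[stage] = report.validation_percent

        elif stage == "deletion":
            scan = deletion_scan(model, params, records_by_context, config=sim_config)
            rows = [
                {
                    "reaction": rid,
                    "category": scan.category(rid),
                    **{f"delta_{c}": d for c, d in deltas.items()},
                }
                for rid, deltas in scan.deltas.items()
            ]
            out = outdir / "deletion_scan.csv"
            pd.DataFrame(rows).to_csv(out, index=False)
            stage_outputs[stage] = str(out)

        elif stage == "morris":
            m_cfg = cfg.get("morris", {})
            objective = _make_objective(
                m_cfg, model, params, qual, None, context, sim_config
            )
            morris = morris_screen(
                objective,
                levels=int(m_cfg.get("levels", 8)),
                trajectories=int(m_cfg.get("trajectories", 16)),
                oversample=int(m_cfg.get("oversample", 300)),
                seed=s_seed,
            )
            threshold = float(m_cfg.get("threshold", 1.5))
            morris_subset = select_important(morris, threshold)
            out = outdir / "morris.csv"
            pd.DataFrame(
                {
                    "factor": morris.factor_names,
                    "mu_star": morris.mu_star,
                    "mu": morris.mu,
                    "sigma": morris.sigma,
                    "monotonic": morris.monotonic(),
                    "important": morris.important(threshold),
                }
            ).to_csv(out, index=False)
            stage_outputs[stage] = str(out)
            objectives[stage] = float(morris.mu_star.max(initial=0.0))

        elif stage == "sobol":
            if not morris_subset:
                raise ModelError(
                    "sobol stage needs a Morris-selected subset (run the "
                    "morris stage first or set 'factors' in the config)"
                )
            s_cfg = cfg.get("sobol", {})
            subset = morris_subset[
                : int(s_cfg.get("max_factors", len(morris_subset)))
            ]
            objective = _make_objective(
                s_cfg, model, params, qual, subset, context, sim_config
            )
            sob = sobol_analysis(
                objective,
                N=int(s_cfg.get("n", 256)),
                seed=s_seed,
                bootstrap_reps=int(s_cfg.get("bootstrap", 200)),
                pairs=bool(s_cfg.get("pairs", True)),
            )
            out = outdir / "sobol.csv"
            pd.DataFrame(
                {
                    "factor": sob.factor_names,
                    "S": sob.S,
                    "T": sob.T,
                    "S_lo": sob.S_ci[:, 0],
                    "S_hi": sob.S_ci[:, 1],
                    "T_lo": sob.T_ci[:, 0],
                    "T_hi": sob.T_ci[:, 1],
                }
            ).to_csv(out, index=False)
            if len(sob.pairs):
                pd.DataFrame(
                    {
                        "factor_i": [p[0] for p in sob.pairs],
                        "factor_j": [p[1] for p in sob.pairs],
                        "S2": sob.S2,
                        "synergy": sob.synergy,
                    }
                ).to_csv(outdir / "sobol_pairs.csv", index=False)
            stage_outputs[stage] = str(out)
            objectives[stage] = float(sob.T.max(initial=0.0))

        elif stage == "calibrate_ec50":
            if not morris_subset:
                raise ModelError(
                    "calibrate_ec50 stage needs a reaction subset (run the "
                    "morris stage first or set 'factors' in the config)"
                )
            c_cfg = cfg.get("calibrate_ec50", {})
            subset = morris_subset[: int(c_cfg.get("n_reactions", 12))]
            cal = calibrate_ec50(
                model,
                params,
                subset,
                qual,
                semi,
                n_starts=int(c_cfg.get("n_starts", 10)),
                seed=s_seed,
                config=sim_config,
            )
            params = cal.best_params
            out = outdir / "calibrate_ec50.json"
            out.write_text(
                json.dumps(
                    {
                        "subset": list(subset),
                        "best_values": cal.best_values,
                        "best_objective": cal.best_objective,
                        "seed": s_seed,
                    },
                    indent=2,
                )
            )
            stage_outputs[stage] = str(out)
            objectives[stage] = cal.best_objective

        elif stage == "crosstalk":
            x_cfg = cfg.get("crosstalk", {})
            gate = x_cfg.get("gate", "both")
            frames = []
            for g in ("or", "and"):
                if gate not in (g, "both"):
                    continue
                cands = (
                    enumerate_or_candidates(model)
                    if g == "or"
                    else enumerate_and_candidates(model)
                )
                if not cands:
                    continue
                ranked, summary = screen_crosstalks(
                    model, params, qual, cands, config=sim_config
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "gate": [c.gate for c in ranked],
                            "source": [c.source for c in ranked],
                            "target": [c.target for c in ranked],
                            "sign": [c.sign for c in ranked],
                            "delta": [c.delta_validation for c in ranked],
                            "corrected": [c.corrected for c in ranked],
                            "broken": [c.broken for c in ranked],
                            "duplicate": [c.duplicate for c in ranked],
                        }
                    )
                )
                (outdir / f"crosstalk_{g}_summary.json").write_text(
                    json.dumps(summary.as_dict(), indent=2)
                )
            out = outdir / "crosstalk.csv"
            pd.concat(frames, ignore_index=True).to_csv(out, index=False)
            stage_outputs[stage] = str(out)
            objectives[stage] = float(
                max(frame["delta"].max() for frame in frames)
            )

    manifest = RunManifest(
        config=cfg,
        input_hashes=input_hashes,
        seeds=seeds,
        stage_outputs=stage_outputs,
        objectives=objectives,
        version=__version__,
    )
    manifest.write(outdir / "manifest.json")
    return manifest
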