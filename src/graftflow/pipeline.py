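"""Stage orchestration: configuration, seeding, manifests, reproducibility.

Four analysis stages build on the simulator — ``morris`` (screening),
``uq`` (polynomial-chaos Sobol indices, consuming the screening ranking),
``autoreg`` (resistance-tuning experiment) and ``cohort`` (synthetic
clinical cohort + comparison statistics) — plus ``simulate``/``metrics``
utilities and a ``report`` aggregator.  Every stage derives its own seed
from the master seed by stable hashing of the stage name, writes its outputs
under the output directory, and records a manifest (config hash, seed,
inputs, outputs, wall time) so a rerun with the same config and seed is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autoreg import reference_state, tune_autoregulation
from .distributions import default_distributions, write_registry_csv
from .gpce import (
    default_uq_distributions,
    run_uq_stage,
)
from .metrics import compute_all, metrics_from_simulation, segment_beats
from .model import simulate
from .morris import build_trajectories, elementary_effects, map_to_physical
from .parameters import ModelParameters, ParameterError, build_default_parameters
from .synthclin import generate_cohort, summarize_by_class, write_cohort

__all__ = ["Config", "RunManifest", "load_config", "stage_seed", "run_stage", "STAGES"]

STAGES = ("simulate", "metrics", "morris", "uq", "autoreg", "cohort", "report")

_KNOWN_SECTIONS = {
    "seed", "parameters", "simulate", "metrics", "morris", "uq", "autoreg", "cohort",
}

_DEFAULTS: dict[str, dict] = {
    "simulate": {"n_beats": 10, "dt": None},
    "metrics": {"waveform_csv": None, "markers_csv": None, "flow_unit": "mL/min"},
    "morris": {"r": 10, "p": 4, "oversample": 60, "n_beats": 10},
    "uq": {"n": None, "max_order": 2, "collocation_factor": 2.0, "n_beats": 10,
           "n_from_morris": 4, "parameters": None},
    "autoreg": {"pcts": [20.0, 40.0, 50.0, 60.0], "rel_tol": 0.01, "max_iter": 50,
                "n_beats": 10},
    "cohort": {"n_patients": 41, "grafts_per_patient": 3,
               "class_mix": [0.5, 0.3, 0.2], "flow_noise_sd": 2.0,
               "jitter_sd": 0.010, "n_beats": 8},
}


@dataclass
class Config:
    seed: int
    parameters: ModelParameters
    stages: dict[str, dict]
    raw: dict = field(repr=False, default_factory=dict)

    def hash(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def stage(self, name: str) -> dict:
        merged = dict(_DEFAULTS.get(name, {}))
        merged.update(self.stages.get(name, {}))
        return merged


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> Config:
    """Load and validate a YAML config; unknown keys are an error."""
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ParameterError("config file must contain a mapping")
        raw = loaded
    if overrides:
        raw = {**raw, **overrides}
    unknown = sorted(set(raw) - _KNOWN_SECTIONS)
    if unknown:
        raise ParameterError(f"unknown config sections: {', '.join(unknown)}")
    for name in STAGES:
        sect = raw.get(name)
        if sect is None:
            continue
        bad = sorted(set(sect) - set(_DEFAULTS.get(name, {})))
        if bad:
            raise ParameterError(f"unknown keys in [{name}]: {', '.join(bad)}")
    params = build_default_parameters(raw.get("parameters"))
    return Config(
        seed=int(raw.get("seed", 0)),
        parameters=params,
        stages={k: dict(v) for k, v in raw.items() if k in STAGES and isinstance(v, dict)},
        raw=raw,
    )


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived by stable hashing of the stage name."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


@dataclass
class RunManifest:
    stage: str
    config_hash: str
    seed: int
    version: str
    inputs: list[str]
    outputs: list[str]
    wall_time_s: float
    warnings: list[str] = field(default_factory=list)

    def write(self, outdir: Path) -> Path:
        mdir = outdir / "manifests"
        mdir.mkdir(parents=True, exist_ok=True)
        path = mdir / f"{self.stage}.json"
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
        return path


class MissingUpstreamError(RuntimeError):
    pass


def _save_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)


def _metric_responses(X: np.ndarray, names: list[str], base: ModelParameters, n_beats: int):
    """Run the 0D model at each parameter row; NaN rows for failed runs."""
    from .model import SimulationError

    out = np.full((X.shape[0], 4), np.nan)
    for i, row in enumerate(X):
        try:
            p = base.replace(**dict(zip(names, row)))
            res = simulate(p, n_beats=n_beats)
            m = metrics_from_simulation(res).median
            out[i] = [m["q_mean"], m["pi"], m["ds_ratio"], m["dri"]]
        except (SimulationError, ValueError):
            pass
    return out


def run_stage(stage: str, config: Config, outdir: str | Path, seed: int | None = None) -> RunManifest:
    """Execute one stage; outputs + manifest land under ``outdir``."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(config.seed, stage) if seed is None else seed
    t0 = time.perf_counter()
    opts = config.stage(stage)
    inputs: list[str] = []
    outputs: list[str] = []
    warnings: list[str] = []
    base = config.parameters

    if stage == "simulate":
        res = simulate(base, n_beats=opts["n_beats"], dt=opts["dt"])
        wf, meta = outdir / "waveforms.csv", outdir / "run_metadata.json"
        res.to_csv(wf)
        res.write_metadata(meta)
        outputs += [str(wf), str(meta)]
        if not res.converged:
            warnings.append("run did not reach periodic steady state")

    elif stage == "metrics":
        if opts["waveform_csv"] is None:
            res = simulate(base, n_beats=config.stage("simulate")["n_beats"])
            pm = metrics_from_simulation(res)
        else:
            wf = pd.read_csv(opts["waveform_csv"])
            mk = pd.read_csv(opts["markers_csv"])
            inputs += [str(opts["waveform_csv"]), str(opts["markers_csv"])]
            seg = segment_beats(mk["r_peak_s"].to_numpy(), mk["systole_end_s"].dropna().to_numpy())
            flow = wf["flow_mlmin"].to_numpy() / 60.0 if opts["flow_unit"] == "mL/min" \
                else wf["flow_mls"].to_numpy()
            pressure = wf["pressure_mmhg"].to_numpy() if "pressure_mmhg" in wf else None
            pm = compute_all(wf["time_s"].to_numpy(), flow, seg, pressure=pressure)
        mj, mc = outdir / "metrics.json", outdir / "metrics_tidy.csv"
        pm.to_json(mj)
        pm.to_tidy_csv(mc)
        outputs += [str(mj), str(mc)]

    elif stage == "morris":
        dists = default_distributions()
        reg = outdir / "morris_registry.csv"
        write_registry_csv(dists, reg)
        design = build_trajectories(dists, r=opts["r"], p=opts["p"], seed=seed,
                                    oversample=max(opts["oversample"], opts["r"]))
        X = map_to_physical(design, dists)
        Y = _metric_responses(X, design.names, base, opts["n_beats"])
        pd.DataFrame(X, columns=design.names).to_csv(outdir / "morris_design.csv", index=False)
        pd.DataFrame(Y, columns=["q_mean", "pi", "ds_ratio", "dri"]).to_csv(
            outdir / "morris_responses.csv", index=False)
        results = {}
        for j, metric in enumerate(["q_mean", "pi", "ds_ratio", "dri"]):
            r = elementary_effects(design, Y[:, j])
            results[metric] = {
                "table": r.table.reset_index(names="parameter").to_dict(orient="records"),
                "ranking": r.ranking,
                "n_dropped": r.n_dropped,
            }
        combined = sum(
            (pd.DataFrame(results[m]["table"]).set_index("parameter")["score"]
             / pd.DataFrame(results[m]["table"]).set_index("parameter")["score"].max())
            for m in results
        )
        results["combined_ranking"] = list(combined.sort_values(ascending=False).index)
        rj = outdir / "morris_results.json"
        _save_json(results, rj)
        outputs += [str(reg), str(outdir / "morris_design.csv"),
                    str(outdir / "morris_responses.csv"), str(rj)]

    elif stage == "uq":
        dists = _uq_dists_from_config(config, outdir, opts, inputs)
        rep = run_uq_stage(
            n=opts["n"], seed=seed, max_order=opts["max_order"],
            collocation_factor=opts["collocation_factor"], dists=dists,
            base=base, n_beats=opts["n_beats"],
        )
        uj = outdir / "uq_results.json"
        _save_json({
            "order": rep.order,
            "cv_table": rep.cv_table.reset_index().to_dict(orient="records"),
            "sobol_main": rep.sobol.main.to_dict(),
            "sobol_total": rep.sobol.total.to_dict(),
            "kept": rep.kept,
            "filter_report": rep.filter_report,
            "most_influential": {m: rep.most_influential(m)
                                 for m in rep.sobol.total.columns},
        }, uj)
        pd.DataFrame(rep.samples, columns=[d.name for d in dists]).to_csv(
            outdir / "uq_samples.csv", index=False)
        rep.responses.to_csv(outdir / "uq_responses.csv")
        outputs += [str(uj), str(outdir / "uq_samples.csv"), str(outdir / "uq_responses.csv")]

    elif stage == "autoreg":
        target = reference_state(base, n_beats=opts["n_beats"],
                                 rel_tol=opts["rel_tol"], max_iter=opts["max_iter"])
        payload = {"reference": {"q_mean": target.q_mean, "endo_epi": target.endo_epi},
                   "severities": {}}
        for pct in opts["pcts"]:
            try:
                r = tune_autoregulation(base, float(pct), target, n_beats=opts["n_beats"])
                with_m = metrics_from_simulation(r.result).median
                without = metrics_from_simulation(
                    simulate(base.replace(stenosis_pct=float(pct)), n_beats=opts["n_beats"])
                ).median
                payload["severities"][str(pct)] = {
                    "scale_overall": r.scale_overall,
                    "scale_endo_epi": r.scale_endo_epi,
                    "iterations": r.iterations,
                    "metrics_tuned": with_m,
                    "metrics_untuned": without,
                }
            except RuntimeError as exc:
                payload["severities"][str(pct)] = {"error": str(exc)}
                warnings.append(f"severity {pct}%: {exc}")
        aj = outdir / "autoreg_results.json"
        _save_json(payload, aj)
        outputs.append(str(aj))

    elif stage == "cohort":
        records = generate_cohort(
            n_patients=opts["n_patients"], grafts_per_patient=opts["grafts_per_patient"],
            class_mix=tuple(opts["class_mix"]), seed=seed,
            flow_noise_sd=opts["flow_noise_sd"], jitter_sd=opts["jitter_sd"],
            n_beats=opts["n_beats"], base=base,
        )
        cdir = outdir / "cohort"
        write_cohort(records, cdir)
        outputs.append(str(cdir / "manifest.csv"))
        try:
            summary = summarize_by_class(records)
        except ValueError as exc:
            warnings.append(f"cohort summary skipped: {exc}")
        else:
            sj = outdir / "cohort_summary.json"
            summary.to_json(sj)
            outputs.append(str(sj))

    elif stage == "report":
        report: dict = {"version": __version__, "config_hash": config.hash()}
        for name, fname in [("morris", "morris_results.json"), ("uq", "uq_results.json"),
                            ("autoreg", "autoreg_results.json"),
                            ("cohort", "cohort_summary.json")]:
            path = outdir / fname
            if path.exists():
                inputs.append(str(path))
                with open(path) as fh:
                    report[name] = json.load(fh)
            else:
                report[name] = None
        rj = outdir / "report.json"
        _save_json(report, rj)
        outputs.append(str(rj))

    manifest = RunManifest(
        stage=stage, config_hash=config.hash(), seed=seed, version=__version__,
        inputs=inputs, outputs=outputs,
        wall_time_s=round(time.perf_counter() - t0, 3), warnings=warnings,
    )
    manifest.write(outdir)
    return manifest


def _uq_dists_from_config(config: Config, outdir: Path, opts: dict, inputs: list[str]):
    """UQ marginals: explicit list, else stenosis + screened top + surrogates."""
    explicit = opts.get("parameters")
    if explicit:
        registry = {d.name: d for d in default_distributions()}
        defaults9 = {d.name: d for d in default_uq_distributions(config.parameters)}
        dists = []
        for name in explicit:
            if name in defaults9:
                dists.append(defaults9[name])
            elif name in registry:
                dists.append(registry[name].with_truncation(1.96))
            else:
                raise ParameterError(f"unknown UQ parameter {name!r}")
        return dists

    morris_json = outdir / "morris_results.json"
    if not morris_json.exists():
        raise MissingUpstreamError(
            "uq stage needs the morris stage's ranking (morris_results.json) "
            "or an explicit uq.parameters list; run the 'morris' stage first"
        )
    inputs.append(str(morris_json))
    with open(morris_json) as fh:
        ranking = json.load(fh)["combined_ranking"]
    registry = {d.name: d for d in default_distributions()}
    surrogates = {d.name: d for d in default_uq_distributions(config.parameters)}
    picked = ["stenosis_pct"]
    for name in ranking:
        if name in ("stenosis_pct",) or len(picked) > opts["n_from_morris"]:
            continue
        picked.append(name)
    dists = [surrogates["stenosis_pct"]]
    for name in picked[1:]:
        dists.append(registry[name].with_truncation(1.96))
    # the four conduit/systemic surrogate parameters complete the set
    for name in ("C_sa", "R_sa", "graft_area_scale", "L_graft"):
        if name not in [d.name for d in dists]:
            dists.append(surrogates[name])
    return dists
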