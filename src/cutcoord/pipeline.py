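"""End-to-end orchestration: simulate -> preprocess -> veccode -> stats ->
train -> evaluate -> report.

A declarative YAML config drives the stages; every artifact lands under an
output directory, a run manifest records the config hash, seeds, stage
timings and file inventory, and reruns with the same config and seed
reproduce byte-identical curve CSVs and metrics JSON.  Stages can be run
individually (resuming from cached upstream outputs) or end to end.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import child_seed
from .features import build_direction_dataset
from .lstm import default_run_config, evaluate, save_checkpoint, train
from .preprocessing import process_trial
from .spm import CurveSample, shapiro_wilk, snpm_paired_posthoc, snpm_rm_anova
from .synthetic import (
    DIRECTIONS,
    GeneratorConfig,
    generate_dataset,
    load_dataset,
    save_dataset,
)
from .vector_coding import (
    STANDARD_COUPLINGS,
    CouplingCurveSet,
    coefficient_of_correspondence,
    summarize_variability,
)

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

DEFAULT_CONFIG: dict[str, Any] = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "outdir": "cutcoord_run",
    "dataset": {},  # GeneratorConfig overrides
    "veccode": {"summary_window": [0.0, 100.0]},
    "stats": {"n_perm": 1000, "alpha": 0.05},
    "train": {
        "enabled": True,
        "target": "veccode",
        "coupling": "ThighAA_LegFE",
        "epochs": None,  # per-direction default when None
        "plateau_patience": 40,
        "noise_sd": 0.01,
    },
}

_STAGES = ("simulate", "preprocess", "veccode", "stats", "train", "report")


class ConfigError(ValueError):
    """Raised when the run configuration violates the schema."""


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: dict[str, float] = field(default_factory=dict)  # stage -> seconds
    outputs: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "stage_timings_s": self.stages,
                "outputs": self.outputs,
                "warnings": self.warnings,
            },
            indent=2,
        )


def load_config(source: str | Path | dict) -> dict:
    """Read and validate a pipeline config (YAML path or dict)."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in raw.items():
        if key not in cfg:
            raise ConfigError(f"unknown config field: {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"field {key!r} must be a mapping")
            for sub, sval in value.items():
                cfg[key][sub] = sval
        else:
            cfg[key] = value
    if cfg["schema_version"] != SCHEMA_VERSION:
        raise ConfigError(
            f"schema_version must be {SCHEMA_VERSION}, got {cfg['schema_version']}"
        )
    if not isinstance(cfg["seed"], int):
        raise ConfigError("field 'seed' must be an integer")
    try:
        _generator_config(cfg)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid dataset block: {exc}") from exc
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _generator_config(cfg: dict) -> GeneratorConfig:
    opts = dict(cfg["dataset"])
    if "swing_variability_scale" in opts:
        opts["swing_variability_scale"] = {
            int(k): float(v) for k, v in opts["swing_variability_scale"].items()
        }
    if "swing_window" in opts:
        opts["swing_window"] = tuple(opts["swing_window"])
    opts.setdefault("seed", child_seed(cfg["seed"], "dataset"))
    return GeneratorConfig(**opts)


def _coupling_by_name(name: str):
    for c in STANDARD_COUPLINGS:
        if c.name == name:
            return c
    raise ConfigError(f"unknown coupling {name!r}")


# --- stages ---------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path) -> list[str]:
    gen = _generator_config(cfg)
    trials, manifest = generate_dataset(gen)
    save_dataset(trials, manifest, outdir / "trials",
                 seed_log={"seed": cfg["seed"], "generator_seed": gen.seed})
    return [str(p.relative_to(outdir)) for p in sorted((outdir / "trials").iterdir())]


def stage_preprocess(cfg: dict, outdir: Path) -> list[str]:
    gen = _generator_config(cfg)
    trials, manifest = load_dataset(outdir / "trials",
                                    sample_rate=gen.sample_rate)
    rows = []
    for trial in trials:
        p = process_trial(trial)
        for name, curve in p.angles.items():
            rows.append(_curve_row(p, name, curve))
        rows.append(_curve_row(p, "vgrf", p.vgrf))
        for i, ch in enumerate(p.imu_channels):
            rows.append(_curve_row(p, ch, p.imu[:, i]))
    df = pd.DataFrame(rows)
    path = outdir / "processed.csv"
    df.to_csv(path, index=False, float_format="%.10g")
    return [path.name]


def _curve_row(p, channel: str, curve: np.ndarray) -> dict:
    row = {
        "trial_id": p.trial_id,
        "subject_id": p.subject_id,
        "direction": p.direction,
        "channel": channel,
    }
    row.update({f"p{i:03d}": v for i, v in enumerate(curve)})
    return row


def _load_processed(outdir: Path) -> pd.DataFrame:
    path = outdir / "processed.csv"
    if not path.exists():
        raise FileNotFoundError(
            "processed.csv not found: run the 'preprocess' stage first"
        )
    return pd.read_csv(path)


def _subject_curves(df: pd.DataFrame, coupling) -> dict[tuple[int, int], Any]:
    value_cols = [c for c in df.columns if c.startswith("p")]
    out = {}
    for (subject, direction), grp in df.groupby(["subject_id", "direction"]):
        prox = grp[grp.channel == coupling.proximal_channel]
        dist = grp[grp.channel == coupling.distal_channel]
        prox = prox.sort_values("trial_id")[value_cols].to_numpy()
        dist = dist.sort_values("trial_id")[value_cols].to_numpy()
        cvc = coefficient_of_correspondence(
            CouplingCurveSet(prox, dist, coupling=coupling,
                             direction=int(direction))
        )
        out[(int(subject), int(direction))] = cvc
    return out


def stage_veccode(cfg: dict, outdir: Path) -> list[str]:
    df = _load_processed(outdir)
    window = tuple(cfg["veccode"]["summary_window"])
    rows, summaries = [], []
    for coupling in STANDARD_COUPLINGS:
        for (subject, direction), cvc in _subject_curves(df, coupling).items():
            for i in range(100):
                rows.append(
                    {"coupling": coupling.name, "subject_id": subject,
                     "direction": direction, "interval": i,
                     "a": cvc.a[i], "m": cvc.m[i], "r": cvc.r[i]}
                )
            mean_r, max_r = summarize_variability(cvc, window)
            summaries.append(
                {"coupling": coupling.name, "subject_id": subject,
                 "direction": direction, "mean_r": mean_r, "max_r": max_r}
            )
    curves_path = outdir / "veccode_curves.csv"
    pd.DataFrame(rows).to_csv(curves_path, index=False, float_format="%.10g")
    summary_path = outdir / "veccode_summary.csv"
    pd.DataFrame(summaries).to_csv(summary_path, index=False,
                                   float_format="%.10g")
    return [curves_path.name, summary_path.name]


def stage_stats(cfg: dict, outdir: Path) -> list[str]:
    curves = pd.read_csv(outdir / "veccode_curves.csv")
    summary = pd.read_csv(outdir / "veccode_summary.csv")
    n_perm = int(cfg["stats"]["n_perm"])
    alpha = float(cfg["stats"]["alpha"])
    seed = child_seed(cfg["seed"], "stats")

    normality = []
    for (coupling, direction), grp in summary.groupby(["coupling", "direction"]):
        values = grp["mean_r"].to_numpy()
        if len(values) >= 3 and np.ptp(values) > 0:
            w, p = shapiro_wilk(values)
        else:  # too few subjects for the W statistic
            w, p = float("nan"), float("nan")
        normality.append(
            {"coupling": coupling, "direction": int(direction), "W": w, "p": p}
        )

    results = {}
    for coupling, grp in curves.groupby("coupling"):
        samples = [
            CurveSample(int(s), int(d),
                        sub.sort_values("interval")["r"].to_numpy())
            for (s, d), sub in grp.groupby(["subject_id", "direction"])
        ]
        omni = snpm_rm_anova(samples, n_perm=n_perm, alpha=alpha, seed=seed)
        posthoc = {}
        pairs = [(90, 135), (90, 180), (135, 180)]
        for pair in pairs:
            res = snpm_paired_posthoc(samples, pair, n_perm=n_perm,
                                      alpha_adjusted=alpha / len(pairs),
                                      seed=seed)
            posthoc[f"{pair[0]}v{pair[1]}"] = _result_dict(res)
        results[coupling] = {"omnibus": _result_dict(omni), "posthoc": posthoc}

    stats_path = outdir / "stats.json"
    stats_path.write_text(
        json.dumps({"normality": normality, "snpm": results}, indent=2)
    )
    return [stats_path.name]


def _result_dict(res) -> dict:
    return {
        "stat": res.stat_name,
        "critical": res.critical,
        "n_perm": res.n_perm,
        "exhaustive": res.exhaustive,
        "significant": res.significant,
        "clusters": [
            {"start_pct": c.start_pct, "end_pct": c.end_pct, "p": c.p_value}
            for c in res.clusters
        ],
    }


def stage_train(cfg: dict, outdir: Path) -> list[str]:
    if not cfg["train"]["enabled"]:
        return []
    gen = _generator_config(cfg)
    trials, _ = load_dataset(outdir / "trials", sample_rate=gen.sample_rate)
    coupling = _coupling_by_name(cfg["train"]["coupling"])
    outputs = []
    metrics_all = {}
    for direction in DIRECTIONS:
        ds = build_direction_dataset(
            trials, int(direction), target=cfg["train"]["target"],
            coupling=coupling, noise_sd=float(cfg["train"]["noise_sd"]),
            seed=child_seed(cfg["seed"], "target", int(direction)),
        )
        overrides = {
            "seed": child_seed(cfg["seed"], "train", int(direction)),
            "plateau_patience": cfg["train"]["plateau_patience"],
        }
        if cfg["train"]["epochs"] is not None:
            overrides["epochs"] = int(cfg["train"]["epochs"])
        run_cfg = default_run_config(int(direction), **overrides)
        trained = train(run_cfg, ds.X, ds.Y)
        metrics = evaluate(trained, ds.X, ds.Y, partition="test")
        metrics_all[str(int(direction))] = {
            "cmc": metrics.cmc, "rmse": metrics.rmse, "flags": metrics.flags,
            "epochs_run": int(trained.history["epoch"].max()),
            "n_trials": int(ds.X.shape[0]),
        }
        hist_path = outdir / f"history_{int(direction)}.csv"
        trained.history.to_csv(hist_path, index=False, float_format="%.10g")
        save_checkpoint(trained, outdir / f"model_{int(direction)}.npz")
        outputs += [hist_path.name, f"model_{int(direction)}.npz",
                    f"model_{int(direction)}.json"]
    metrics_path = outdir / "metrics.json"
    metrics_path.write_text(json.dumps(metrics_all, indent=2))
    return outputs + [metrics_path.name]


def stage_report(cfg: dict, outdir: Path) -> list[str]:
    lines = ["# cutcoord run report", ""]
    stats_path = outdir / "stats.json"
    summary_path = outdir / "veccode_summary.csv"
    if summary_path.exists():
        summary = pd.read_csv(summary_path)
        lines += ["## Coordination variability (coefficient of correspondence)",
                  "", "| Coupling | Direction | Mean r (SD) | Max r (SD) |",
                  "|---|---|---|---|"]
        for (coupling, direction), grp in summary.groupby(
                ["coupling", "direction"]):
            lines.append(
                f"| {coupling} | {direction} | "
                f"{grp.mean_r.mean():.3f} ({grp.mean_r.std():.3f}) | "
                f"{grp.max_r.mean():.3f} ({grp.max_r.std():.3f}) |"
            )
        lines.append("")
    if stats_path.exists():
        stats = json.loads(stats_path.read_text())
        lines += ["## Normality screening (Shapiro-Wilk, subject mean r)", "",
                  "| Coupling | Direction | W | p |", "|---|---|---|---|"]
        for row in stats["normality"]:
            lines.append(
                f"| {row['coupling']} | {row['direction']} | "
                f"{row['W']:.4f} | {row['p']:.4g} |"
            )
        lines += ["", "## Direction comparisons (SnPM)", ""]
        for coupling, block in stats["snpm"].items():
            omni = block["omnibus"]
            lines.append(f"### {coupling}")
            lines.append(
                f"- omnibus: significant={omni['significant']}, clusters="
                + (", ".join(
                    f"{c['start_pct']:.0f}-{c['end_pct']:.0f}% (p={c['p']:.3f})"
                    for c in omni["clusters"]) or "none")
            )
            for pair, res in block["posthoc"].items():
                lines.append(
                    f"- {pair}: significant={res['significant']}, clusters="
                    + (", ".join(
                        f"{c['start_pct']:.0f}-{c['end_pct']:.0f}% "
                        f"(p={c['p']:.3f})" for c in res["clusters"]) or "none")
                )
            lines.append("")
    metrics_path = outdir / "metrics.json"
    if metrics_path.exists():
        metrics = json.loads(metrics_path.read_text())
        lines += ["## Prediction accuracy (held-out test split)", "",
                  "| Direction | CMC | RMSE | Epochs |", "|---|---|---|---|"]
        for direction, m in metrics.items():
            lines.append(
                f"| {direction} | {m['cmc']:.5f} | {m['rmse']:.5f} | "
                f"{m['epochs_run']} |"
            )
        lines.append("")
    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return [path.name]


_STAGE_FN: dict[str, Callable[[dict, Path], list[str]]] = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "veccode": stage_veccode,
    "stats": stage_stats,
    "train": stage_train,
    "report": stage_report,
}

_STAGE_DONE = {
    "simulate": "trials/manifest.csv",
    "preprocess": "processed.csv",
    "veccode": "veccode_summary.csv",
    "stats": "stats.json",
    "train": "metrics.json",
    "report": "report.md",
}


def run_pipeline(config: str | Path | dict, stages: list[str] | None = None,
                 resume: bool = False, outdir: str | Path | None = None
                 ) -> RunManifest:
    """Run (a subset of) the pipeline stages in dependency order."""
    cfg = load_config(config)
    out = Path(outdir) if outdir is not None else Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    manifest = RunManifest(config_hash=chash, seed=cfg["seed"])
    wanted = stages or list(_STAGES)
    for stage in wanted:
        if stage not in _STAGE_FN:
            raise ConfigError(f"unknown stage {stage!r}")
    log.info("run %s: stages=%s outdir=%s", chash, wanted, out)
    for stage in _STAGES:
        if stage not in wanted:
            continue
        if resume and (out / _STAGE_DONE[stage]).exists():
            log.info("[%s] %s: cached, skipping", chash, stage)
            continue
        t0 = time.perf_counter()
        outputs = _STAGE_FN[stage](cfg, out)
        dt = time.perf_counter() - t0
        manifest.stages[stage] = round(dt, 3)
        manifest.outputs[stage] = outputs
        log.info("[%s] %s: %.1fs, %d outputs", chash, stage, dt, len(outputs))
    (out / "run_manifest.json").write_text(manifest.to_json())
    return manifest
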