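"""End-to-end orchestration: simulate (or ingest) -> score -> summarize ->
analyze -> report.

The summaries mirror the analysis plan: end-of-acquisition performance is
the mean of each participant's last 10 test trials (trial counts vary under
criterion training), retention sessions contribute their 10-trial means,
and transfer contributes per-block means.  The retention model has fixed
effects of group, session (Acq, R1, R24, R7), their interaction and musical
training; the transfer model swaps session for block (1-6); the
acquisition-vs-transfer model compares blocks 1-3 of both phases.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, last10_average, simulate_study
from .fixtures import TABLE1_SHA256, TABLE2_SHA256, load_table1
from .statistics import (
    ModelResult,
    block_slopes,
    ks_normality,
    rank_mixed_model,
    two_sample_t,
    wilcoxon_rank_sum,
)

__all__ = [
    "RunConfig",
    "summarize_retention",
    "summarize_transfer",
    "summarize_acq_transfer",
    "analyze_trials",
    "run_pipeline",
    "table1_report",
    "model_to_dict",
]

RETENTION_SESSIONS = ("Acq", "R1", "R24", "R7")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one reproducible pipeline run."""

    seed: int = 0
    out_dir: str = "results/run"
    cohort: CohortConfig | None = None
    designs: tuple[str, ...] = ("retention", "transfer", "acq-vs-transfer")
    log_level: str = "INFO"

    def resolved_cohort(self) -> CohortConfig:
        if self.cohort is not None:
            return self.cohort
        return CohortConfig(seed=self.seed)


def summarize_retention(trials: pd.DataFrame) -> pd.DataFrame:
    """One row per participant x session: Acq last-10 mean + retention means."""
    meta_cols = ["group", "musical_training"]
    rows = []
    for pid, sub in trials.groupby("participant"):
        meta = {c: sub[c].iloc[0] for c in meta_cols}
        acq = sub[sub["session"] == "Acq"].sort_values(["block", "trial"])
        rows.append(
            {
                "participant": pid,
                "session": "Acq",
                "pitch_accuracy": last10_average(acq["pitch_accuracy"].tolist()),
                "rhythm_accuracy": last10_average(acq["rhythm_accuracy"].tolist()),
                **meta,
            }
        )
        for session in ("R1", "R24", "R7"):
            ret = sub[sub["session"] == session]
            if len(ret) == 0:
                continue
            rows.append(
                {
                    "participant": pid,
                    "session": session,
                    "pitch_accuracy": float(ret["pitch_accuracy"].mean()),
                    "rhythm_accuracy": float(ret["rhythm_accuracy"].mean()),
                    **meta,
                }
            )
    out = pd.DataFrame(rows)
    out["session"] = pd.Categorical(out["session"], categories=RETENTION_SESSIONS, ordered=True)
    return out.sort_values(["participant", "session"]).reset_index(drop=True)


def summarize_transfer(trials: pd.DataFrame) -> pd.DataFrame:
    """One row per participant x transfer block (1-6): block means."""
    sub = trials[trials["phase"] == "transfer"]
    out = (
        sub.groupby(["participant", "group", "block"], observed=True)
        .agg(
            pitch_accuracy=("pitch_accuracy", "mean"),
            rhythm_accuracy=("rhythm_accuracy", "mean"),
            musical_training=("musical_training", "first"),
        )
        .reset_index()
    )
    out["block"] = out["block"].astype(int)
    return out


def summarize_acq_transfer(trials: pd.DataFrame) -> pd.DataFrame:
    """Blocks 1-3 of acquisition and transfer, per participant x phase x block."""
    sub = trials[trials["phase"].isin(["acquisition", "transfer"]) & (trials["block"] <= 3)]
    out = (
        sub.groupby(["participant", "group", "phase", "block"], observed=True)
        .agg(
            pitch_accuracy=("pitch_accuracy", "mean"),
            rhythm_accuracy=("rhythm_accuracy", "mean"),
            musical_training=("musical_training", "first"),
        )
        .reset_index()
    )
    out["block"] = out["block"].astype(int)
    out["session"] = out["phase"].map({"acquisition": "Acq", "transfer": "Tran"})
    out["cell"] = out["session"].astype(str) + ":B" + out["block"].astype(str)
    return out


def analyze_trials(trials: pd.DataFrame, design: str, response: str = "pitch_accuracy") -> dict:
    """Fit the rank-based model for one design; returns a JSON-ready dict."""
    if design == "retention":
        data = summarize_retention(trials)
        model = rank_mixed_model(
            data, response, subject="participant", between="group",
            within="session", covariate="musical_training",
        )
        slopes = None
    elif design == "transfer":
        data = summarize_transfer(trials)
        model = rank_mixed_model(
            data, response, subject="participant", between="group",
            within="block", covariate="musical_training",
        )
        slopes = block_slopes(data, response, subject="participant", group="group", block="block")
    elif design == "acq-vs-transfer":
        data = summarize_acq_transfer(trials)
        model = rank_mixed_model(
            data, response, subject="participant", between="group",
            within="cell", covariate="musical_training",
        )
        slopes = {
            phase: block_slopes(
                data[data["session"] == phase], response,
                subject="participant", group="group", block="block",
            )
            for phase in ("Acq", "Tran")
        }
    else:
        raise ValueError(f"unknown design {design!r}")
    out = model_to_dict(model)
    out["design"] = design
    out["response"] = response
    out["n_obs"] = int(len(data))
    if slopes is not None:
        out["slopes"] = slopes
    return out


def model_to_dict(model: ModelResult) -> dict:
    return {
        "engine": model.engine,
        "interaction_removed": model.interaction_removed,
        "interaction": dataclasses.asdict(model.interaction_test)
        if model.interaction_test
        else None,
        "effects": [dataclasses.asdict(e) for e in model.effects],
        "contrasts": [dataclasses.asdict(c) for c in model.contrasts],
        "slopes": model.slopes,
    }


def table1_report() -> dict:
    """Between-group descriptive statistics and pooled t-tests on the
    packaged participant table (manipulation check plus demographics)."""
    t1 = load_table1()
    hi = t1[t1["group"] == "High"]
    lo = t1[t1["group"] == "Low"]
    report: dict = {"group_means": {}, "t_tests": {}}
    for col in ("age", "competitiveness", "eft", "m_train", "ipaq", "vo2peak",
                "wmax", "gxt_hrmax", "gxt_rermax", "gxt_rpemax", "iet_hrmax", "iet_rpemax"):
        report["group_means"][col] = {
            "High": round(float(hi[col].mean()), 1),
            "Low": round(float(lo[col].mean()), 1),
        }
        res = two_sample_t(hi[col], lo[col])
        report["t_tests"][col] = {
            "t": round(res.statistic, 1),
            "df": int(res.df),
            "p": res.p_value,
        }
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, score, summarize and analyze one synthetic cohort.

    Writes ``trials.csv``, ``report.json`` and a JSON-lines ``run.log`` under
    ``config.out_dir``; the report embeds the config, seed, fixture checksums
    and library versions so a run can be reproduced exactly.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    log_entries = []

    def log(stage: str, **info):
        entry = {"t": time.time(), "stage": stage, **info}
        log_entries.append(entry)
        with open(log_path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")

    cohort = config.resolved_cohort()
    config_dict = dataclasses.asdict(dataclasses.replace(config, cohort=None))
    config_dict["cohort"] = _cohort_to_dict(cohort)
    # hash the scientific configuration only: output paths do not change results
    hashed = {k: v for k, v in config_dict.items() if k not in ("out_dir", "log_level")}
    config_hash = hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str).encode()
    ).hexdigest()

    stage = "simulate"
    try:
        t0 = time.time()
        trials = simulate_study(cohort)
        trials.to_csv(out_dir / "trials.csv", index=False)
        log(stage, seconds=time.time() - t0, n_rows=len(trials))

        stage = "normality"
        normality = {}
        ret = summarize_retention(trials)
        for resp in ("pitch_accuracy", "rhythm_accuracy"):
            res = ks_normality(ret[resp])
            normality[resp] = {"D": res.statistic, "p": res.p_value, "flags": list(res.flags)}
        log(stage)

        stage = "end_of_acquisition"
        acq = ret[ret["session"] == "Acq"]
        eoa = {}
        for resp in ("pitch_accuracy", "rhythm_accuracy"):
            res = wilcoxon_rank_sum(
                acq.loc[acq["group"] == "HIIT", resp], acq.loc[acq["group"] == "LIIT", resp]
            )
            eoa[resp] = {"W": res.statistic, "p": res.p_value}
        log(stage)

        stage = "analyze"
        models = {}
        for design in config.designs:
            for resp in ("pitch_accuracy", "rhythm_accuracy"):
                t0 = time.time()
                models[f"{design}:{resp}"] = analyze_trials(trials, design, resp)
                log(stage, design=design, response=resp, seconds=time.time() - t0)
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        raise RuntimeError(
            f"pipeline stage {stage!r} failed ({exc}); reproduce with "
            f"run_pipeline(RunConfig(seed={config.seed}, out_dir={config.out_dir!r}))"
        ) from exc

    report = {
        "config": config_dict,
        "config_sha256": config_hash,
        "seed": cohort.seed,
        "fixture_checksums": {"table1": TABLE1_SHA256, "table2": TABLE2_SHA256},
        "versions": {
            "melodylearn": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "normality": normality,
        "end_of_acquisition": eoa,
        "models": models,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _cohort_to_dict(cohort: CohortConfig) -> dict:
    d = dataclasses.asdict(cohort)
    for key in ("melody", "transfer_melody"):
        if d[key] is not None:
            d[key] = {"name": cohort.__getattribute__(key).name}
    return d
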