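"""CSV schemas, run configuration and the end-to-end pipeline orchestration.

All interchange is plain CSV (UTF-8, '.' decimal): a long minute-level
activity table, a cohort covariate + PHQ-9 table, and per-stage outputs
(standardized days, pattern assignments, behavior profiles, PHQ-9 scores,
Table-1/Table-2 style summaries).  run_all executes simulate -> preprocess ->
cluster-patterns -> cluster-behaviors -> score-phq9 -> associate, clustering
on every participant that passes the activity filter while the association
uses only the complete-case subset (the two-population design), and writes a
manifest recording seeds and the filter cascade.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behaviors as bh
from . import patterns as pt
from . import phq9 as ph
from . import preprocess as pp
from . import stats as st
from . import synthetic as syn
from .errors import IntegrityError, SchemaError

logger = logging.getLogger(__name__)

ACTIVITY_COLUMNS = ["participant_id", "day_index", "minute_of_day", "count"]
COHORT_COLUMNS = ["participant_id", "age", "bmi", "gender", "work"] + ph.PHQ9_ITEMS


def read_activity(path: str | Path) -> pd.DataFrame:
    """Read and validate the long activity CSV.

    Malformed rows (bad day/minute ranges, negative or missing counts) are
    collected with their line numbers into a single error; duplicate
    (participant, day, minute) keys are an integrity error naming the first
    offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    problems = []
    day = pd.to_numeric(df["day_index"], errors="coerce")
    minute = pd.to_numeric(df["minute_of_day"], errors="coerce")
    count = pd.to_numeric(df["count"], errors="coerce")
    bad = (
        day.isna()
        | ~day.between(1, 7)
        | minute.isna()
        | ~minute.between(0, 1439)
        | count.isna()
        | (count < 0)
    )
    for idx in df.index[bad][:50]:
        problems.append(f"line {idx + 2}: {df.loc[idx].to_dict()}")  # +2: header + 1-basing
    if problems:
        raise SchemaError(f"{path.name}: {len(problems)} malformed rows; first: {problems[0]}")
    dup = df.duplicated(subset=["participant_id", "day_index", "minute_of_day"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise IntegrityError(f"{path.name}: duplicate (participant, day, minute) key at line {line}")
    df["day_index"] = day.astype(int)
    df["minute_of_day"] = minute.astype(int)
    df["count"] = count
    return df


def write_activity(df: pd.DataFrame, path: str | Path) -> None:
    df[ACTIVITY_COLUMNS].to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    if df["participant_id"].duplicated().any():
        raise IntegrityError(f"{path.name}: duplicate participant_id")
    return df


@dataclass
class RunConfig:
    """Everything one pipeline run needs; defaults reproduce the k=5/k=4 design."""

    seed: int = 0
    kernel: str = "gak"
    sigma: float | str = "auto"
    k_patterns: int = 5
    k_behaviors: int = 4
    dominance_delta: float = bh.DOMINANCE_GAP
    n_init: int = 10
    max_iter: int = 100
    memory_cap: int = pt.DEFAULT_MEMORY_CAP
    out_dir: str = "results"
    activity_csv: str | None = None
    cohort_csv: str | None = None
    simulate: bool = True
    sim: syn.SimConfig = field(default_factory=syn.SimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        cov = sim_raw.pop("covariate_params", None)
        sim = syn.SimConfig(**sim_raw) if sim_raw or cov is None else syn.SimConfig(**sim_raw)
        cfg = cls(**raw, sim=sim)
        return cfg


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts under cfg.out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "counts": {}}
    t_all = time.time()

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {"started": round(time.time() - t_all, 3)}
        return time.time()

    try:
        # --- simulate or load -------------------------------------------------
        t = stage("input")
        if cfg.simulate:
            activity, cohort, truth = syn.simulate_cohort(cfg.sim)
            write_activity(activity, out / "activity.csv")
            cohort.to_csv(out / "cohort.csv", index=False)
            truth["days"].to_csv(out / "truth_days.csv", index=False)
            truth["participants"].to_csv(out / "truth_participants.csv", index=False)
        else:
            if not (cfg.activity_csv and cfg.cohort_csv):
                raise SchemaError("simulate=False requires activity_csv and cohort_csv paths")
            activity = read_activity(cfg.activity_csv)
            cohort = read_cohort(cfg.cohort_csv)
        manifest["counts"]["input_participants"] = int(activity["participant_id"].nunique())
        manifest["stages"]["input"]["seconds"] = round(time.time() - t, 3)

        # --- preprocess -------------------------------------------------------
        t = stage("preprocess")
        std, pre_report = pp.preprocess(activity)
        std.to_csv(out / "standardized_days.csv", index=False)
        manifest["counts"].update(pre_report)
        manifest["stages"]["preprocess"]["seconds"] = round(time.time() - t, 3)

        # --- pattern clustering ----------------------------------------------
        t = stage("cluster-patterns")
        Z = std[pp.HOUR_COLUMNS].to_numpy(dtype=float)
        kcfg = pt.KernelConfig(kernel=cfg.kernel, sigma=cfg.sigma)
        K = pt.compute_gram(Z, kcfg, memory_cap=cfg.memory_cap)
        result = pt.kernel_kmeans(
            K, cfg.k_patterns, seed=cfg.seed, n_init=cfg.n_init, max_iter=cfg.max_iter
        )
        result = pt.name_pattern_clusters(result, Z, syn.default_templates())
        assign = std[["participant_id", "day_index"]].copy()
        assign["cluster"] = result.labels
        assign["pattern_name"] = result.named_labels()
        assign.to_csv(out / "pattern_assignments.csv", index=False)
        pt.cluster_profiles(Z, result.named_labels()).to_csv(
            out / "cluster_profiles.csv", index=False
        )
        manifest["counts"]["clustered_days"] = int(len(assign))
        manifest["pattern_inertia"] = result.inertia
        manifest["stages"]["cluster-patterns"]["seconds"] = round(time.time() - t, 3)

        # --- behavior clustering ---------------------------------------------
        t = stage("cluster-behaviors")
        profiles = bh.behavior_profiles(assign)
        behavior_df, b_assign = bh.cluster_behaviors(
            profiles, k=cfg.k_behaviors, seed=cfg.seed, n_init=cfg.n_init, delta=cfg.dominance_delta
        )
        behavior_df.to_csv(out / "behavior_profiles.csv", index=False)
        bh.centroid_table(b_assign).to_csv(out / "behavior_centroids.csv", index=False)
        manifest["counts"]["clustered_participants"] = int(len(behavior_df))
        manifest["stages"]["cluster-behaviors"]["seconds"] = round(time.time() - t, 3)

        # --- phq9 -------------------------------------------------------------
        t = stage("score-phq9")
        clustered_ids = set(behavior_df["participant_id"])
        cohort_clustered = cohort[cohort["participant_id"].isin(clustered_ids)]
        complete, phq_report = ph.filter_complete_cohort(cohort_clustered)
        ph.score_cohort(cohort_clustered).to_csv(out / "phq9_scores.csv", index=False)
        manifest["counts"]["associated_participants"] = phq_report["retained"]
        manifest["counts"]["excluded_incomplete"] = phq_report["excluded"]
        manifest["stages"]["score-phq9"]["seconds"] = round(time.time() - t, 3)

        # --- association ------------------------------------------------------
        t = stage("associate")
        hourly = pp.hourly_table(activity[activity["participant_id"].isin(clustered_ids)])
        totals = st.total_activity_per_participant(hourly)
        analysis = (
            complete.merge(
                behavior_df[["participant_id", "behavior_name"]], on="participant_id"
            )
            .merge(totals, on="participant_id")
            .rename(columns={"behavior_name": "behavior"})
        )
        ref = st.REFERENCE_BEHAVIOR if st.REFERENCE_BEHAVIOR in set(analysis["behavior"]) else None
        if ref is None:
            # fall back to the largest behavior as reference
            ref = analysis["behavior"].value_counts().idxmax()
        summary = st.cohort_summary(analysis)
        # adjusted models with inestimable MLEs (small strata can separate at
        # desk scale) are recorded as failed rather than aborting the run
        fits = st.sequential_models(analysis, reference_behavior=ref, on_error="skip")
        sens = st.sensitivity_models(analysis, reference_behavior=ref, on_error="skip")
        table2 = st.table2_frame(fits)
        table2.to_csv(out / "table2.csv", index=False)
        st.table2_frame(sens).to_csv(out / "sensitivity_models.csv", index=False)
        _write_json(summary, out / "table1.json")

        def _model_entry(f):
            if isinstance(f, st.FailedFit):
                return {"terms": f.terms, "converged": False, "error": f.error}
            return {
                "terms": f.terms,
                "converged": True,
                "or": f.or_.to_dict(),
                "ci_low": f.ci_low.to_dict(),
                "ci_high": f.ci_high.to_dict(),
                "p": f.p.to_dict(),
                "n": f.n,
            }

        results = {
            "reference_behavior": ref,
            "models": {f.model_id: _model_entry(f) for f in fits + sens},
        }
        _write_json(results, out / "results.json")
        manifest["stages"]["associate"]["seconds"] = round(time.time() - t, 3)
    except Exception as exc:
        manifest["failed_stage"] = [k for k in manifest["stages"]][-1] if manifest["stages"] else None
        manifest["error"] = str(exc)
        _write_json(manifest, out / "manifest.json")
        raise

    if manifest["counts"]["clustered_participants"] < manifest["counts"]["associated_participants"]:
        raise IntegrityError("associated participants exceed clustered participants")
    manifest["total_seconds"] = round(time.time() - t_all, 3)
    _write_json(manifest, out / "manifest.json")
    return {
        "manifest": manifest,
        "standardized": std,
        "patterns": assign,
        "behaviors": behavior_df,
        "analysis": analysis,
        "summary": summary,
        "fits": fits,
        "sensitivity": sens,
    }
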