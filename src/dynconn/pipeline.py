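"""Stage orchestration with provenance logging.

Each stage reads its declared upstream artifacts from the output directory
and writes its own; ``run_all`` executes the whole chain.  Per-stage seeds
are spawned deterministically from the master seed and a fixed stage index,
so individual stages can be rerun in isolation with identical results.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .containers import TimecourseSet, vec_upper
from . import connectivity, graphs, io, preprocess, states, stats, synthetic

__all__ = ["STAGES", "run_stage", "run_all", "MissingArtifactError"]

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "preprocess", "static", "dynamic",
    "states", "graphs", "stats", "report",
)


class MissingArtifactError(RuntimeError):
    """An upstream artifact is absent; names the stage that produces it."""


def _stage_seed(config: RunConfig, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(config.seed, spawn_key=(STAGES.index(stage),))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path}; run the '{producer}' stage first"
        )
    return path


def _log_event(config: RunConfig, **fields) -> None:
    with open(config.out_path("events.jsonl"), "a") as fh:
        fh.write(json.dumps(fields, sort_keys=True) + "\n")


# ---------------------------------------------------------------- stages

def stage_simulate(config: RunConfig) -> None:
    """Generate a synthetic cohort: time courses, metadata, truth record."""
    seed = int(_stage_seed(config, "simulate").generate_state(1)[0] % (2**31))
    spec = synthetic.CohortSpec(
        n_per_group={"HC": config.n_hc, "LTLE": config.n_ltle, "RTLE": config.n_rtle},
        n_components=config.n_components,
        n_timepoints=config.n_timepoints_raw,
        tr_seconds=config.tr_seconds,
        noise_sd=config.noise_sd,
        seed=seed,
    )
    tcs, meta, truth = synthetic.simulate_cohort(spec)
    tc_dir = config.out_path("timecourses", "_")
    for ts in tcs:
        io.write_timecourses(ts, tc_dir.parent / f"{ts.subject_id}.tsv")
    io.write_metadata(meta, config.out_path("metadata.tsv"))
    synthetic.truth_to_json(truth, config.out_path("truth.json"))
    np.savetxt(
        config.out_path("partition.tsv"), spec.partition, fmt="%s"
    )


def _load_cohort(config: RunConfig, subdir: str) -> list[TimecourseSet]:
    tc_dir = Path(config.output_dir) / subdir
    _require(tc_dir, "simulate" if subdir == "timecourses" else "preprocess")
    return [io.read_timecourses(p) for p in sorted(tc_dir.glob("*.tsv"))]


def stage_preprocess(config: RunConfig) -> None:
    """Discard initial volumes, condition time courses, run motion QC."""
    tcs = _load_cohort(config, "timecourses")
    meta = io.read_metadata(_require(config.out_path("metadata.tsv"), "simulate"))
    truth_path = Path(config.output_dir) / "truth.json"
    fd_traces = {}
    if truth_path.exists():
        truth = synthetic.truth_from_json(truth_path)
        fd_traces = {
            sid: np.asarray(rec["fd_trace"])
            for sid, rec in truth["subjects"].items()
        }
    qc_report = {}
    out_dir = config.out_path("conditioned", "_").parent
    for ts in tcs:
        fd = fd_traces.get(
            ts.subject_id,
            np.full(ts.n_timepoints, float(
                meta.loc[meta.subject_id == ts.subject_id, "mean_fd"].iloc[0]
            ) if (meta.subject_id == ts.subject_id).any() else 0.0),
        )
        qc = preprocess.qc_subject(
            fd, mean_fd_max=config.mean_fd_max, subject_id=ts.subject_id
        )
        qc_report[ts.subject_id] = qc.to_dict()
        if not qc.passed:
            _log_event(config, stage="preprocess", subject=ts.subject_id,
                       event="excluded", reasons=qc.reasons)
            continue
        ts = preprocess.discard_initial(ts, config.discard_volumes)
        ts, steps = preprocess.condition(
            ts, robust_z=config.despike_robust_z,
            cutoff_hz=config.lowpass_cutoff_hz,
        )
        io.write_timecourses(ts, out_dir / f"{ts.subject_id}.tsv")
    io.write_json(qc_report, config.out_path("qc_report.json"))
    io.write_json(
        {"conditioning_order": list(preprocess.CONDITIONING_ORDER)},
        config.out_path("conditioning.json"),
    )


def stage_static(config: RunConfig) -> None:
    """Static Fisher-z connectivity matrix per subject."""
    tcs = _load_cohort(config, "conditioned")
    out_dir = config.out_path("static", "_").parent
    for ts in tcs:
        conn = connectivity.static_fc(ts)
        io.write_conn_matrix(conn, out_dir / f"{ts.subject_id}_fc.tsv")


def stage_dynamic(config: RunConfig) -> None:
    """Tapered sliding-window connectivity stacks and edge variances."""
    tcs = _load_cohort(config, "conditioned")
    weights = connectivity.make_window_weights(
        config.window_length, config.window_sigma
    )
    out_dir = config.out_path("windows", "_").parent
    var_rows = []
    for ts in tcs:
        stack = connectivity.windowed_fc(
            ts, weights, step=config.window_step, sigma_tr=config.window_sigma
        )
        io.save_window_stack(stack, out_dir / ts.subject_id)
        ev = connectivity.edge_variance(stack)
        var_rows.append(
            {"subject_id": ts.subject_id,
             **{f"e{k}": v for k, v in enumerate(ev.edge_vector())}}
        )
    pd.DataFrame(var_rows).to_csv(
        config.out_path("edge_variance.tsv"), sep="\t", index=False
    )


def _load_stacks(config: RunConfig) -> list:
    win_dir = Path(config.output_dir) / "windows"
    _require(win_dir, "dynamic")
    return [
        io.load_window_stack(p.with_suffix(""))
        for p in sorted(win_dir.glob("*.npz"))
    ]


def stage_states(config: RunConfig) -> None:
    """Silhouette k-selection, state clustering, temporal metrics."""
    stacks = _load_stacks(config)
    seed = int(_stage_seed(config, "states").generate_state(1)[0] % (2**31))
    k_star, silhouettes = states.select_k(
        stacks,
        k_range=range(config.k_min, config.k_max + 1),
        max_iter=config.kmeans_max_iter,
        n_replicates=config.kmeans_replicates,
        seed=seed,
    )
    model = states.cluster_states(
        stacks, k_star,
        max_iter=config.kmeans_max_iter,
        n_replicates=config.kmeans_replicates,
        seed=seed,
    )
    model.silhouette_by_k = silhouettes
    io.save_state_model(model, config.out_path("states", "state_model"))
    metrics = states.cohort_state_metrics(
        model, tr_seconds=config.tr_seconds, step=config.window_step
    )
    metrics.to_csv(config.out_path("state_metrics.tsv"), sep="\t", index=False)


def stage_graphs(config: RunConfig) -> None:
    """Sparsity-swept graph metrics: static AUCs and dynamic AUC variance."""
    grid = graphs.default_sparsity_grid(
        config.sparsity_min, config.sparsity_max, config.sparsity_step
    )
    ss = _stage_seed(config, "graphs")
    static_dir = Path(config.output_dir) / "static"
    _require(static_dir, "static")
    fc_paths = sorted(static_dir.glob("*_fc.tsv"))
    subject_seeds = ss.spawn(2 * len(fc_paths))
    curve_rows, auc_rows = [], []
    for i, p in enumerate(fc_paths):
        conn = io.read_conn_matrix(p)
        sid = p.name.removesuffix("_fc.tsv")
        curves = graphs.metric_curves(
            conn, grid=grid, n_rand=config.n_rand_static, seed=subject_seeds[i]
        )
        row = {"subject_id": sid}
        for m, curve in curves.items():
            row[f"auc_{m}"] = curve.auc
            for s, v in zip(curve.sparsity_grid, curve.values):
                curve_rows.append(
                    {"subject_id": sid, "metric": m, "sparsity": s, "value": v}
                )
        auc_rows.append(row)
    pd.DataFrame(curve_rows).to_csv(
        config.out_path("graph_curves.tsv"), sep="\t", index=False
    )
    pd.DataFrame(auc_rows).to_csv(
        config.out_path("graph_auc.tsv"), sep="\t", index=False
    )

    stacks = _load_stacks(config)
    dyn_rows = []
    for j, stack in enumerate(stacks):
        dv = graphs.dynamic_metric_variance(
            stack, grid=grid, n_rand=config.n_rand_dynamic,
            seed=subject_seeds[len(fc_paths) + j],
        )
        dyn_rows.append(
            {"subject_id": stack.subject_id,
             **{f"var_auc_{m}": d.variance_of_window_auc for m, d in dv.items()}}
        )
    pd.DataFrame(dyn_rows).to_csv(
        config.out_path("graph_dynamic_variance.tsv"), sep="\t", index=False
    )


def _merge_meta(df: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    return df.merge(
        meta[["subject_id", "group", "age", "sex", "education", "mean_fd"]],
        on="subject_id", how="inner",
    )


def stage_stats(config: RunConfig) -> None:
    """Covariate-adjusted group tests with BH-FDR on every feature family."""
    meta = io.read_metadata(_require(config.out_path("metadata.tsv"), "simulate"))

    def run_family(df: pd.DataFrame, feature_cols: list[str], name: str) -> None:
        merged = _merge_meta(df, meta)
        cov = stats.covariate_matrix(merged)
        res = stats.group_ftest_batch(
            merged[feature_cols].to_numpy(float),
            merged["group"].to_numpy(),
            covariates=cov,
            feature_ids=feature_cols,
            q_fdr=config.q_fdr,
        )
        res.to_csv(config.out_path(f"stats_{name}.tsv"), sep="\t", index=False)

    # static edges
    static_dir = Path(config.output_dir) / "static"
    _require(static_dir, "static")
    rows = []
    for p in sorted(static_dir.glob("*_fc.tsv")):
        conn = io.read_conn_matrix(p)
        rows.append({"subject_id": p.name.removesuffix("_fc.tsv"),
                     **{f"e{k}": v for k, v in enumerate(conn.edge_vector())}})
    edges = pd.DataFrame(rows)
    run_family(edges, [c for c in edges.columns if c.startswith("e")], "static_edges")

    # edge variance
    ev_path = _require(config.out_path("edge_variance.tsv"), "dynamic")
    ev = pd.read_csv(ev_path, sep="\t")
    run_family(ev, [c for c in ev.columns if c.startswith("e")], "edge_variance")

    # graph AUCs
    auc = pd.read_csv(_require(config.out_path("graph_auc.tsv"), "graphs"), sep="\t")
    run_family(auc, [c for c in auc.columns if c.startswith("auc_")], "graph_auc")
    dyn = pd.read_csv(
        _require(config.out_path("graph_dynamic_variance.tsv"), "graphs"), sep="\t"
    )
    run_family(dyn, [c for c in dyn.columns if c.startswith("var_auc_")],
               "graph_dynamic_variance")

    # temporal state metrics: Kruskal-Wallis + Dunn/Bonferroni
    sm = pd.read_csv(_require(config.out_path("state_metrics.tsv"), "states"), sep="\t")
    merged = _merge_meta(sm, meta)
    kw_rows = []
    for col in [c for c in sm.columns
                if c.startswith(("fraction_", "mean_dwell_")) or c == "n_transitions"]:
        sub = merged[["group", col]].dropna()  # unvisited-state dwells drop listwise
        if sub["group"].nunique() < 2:
            kw_rows.append({"feature_id": col, "H": float("nan"), "p": float("nan")})
            continue
        h, p = stats.kruskal_wallis(sub[col].to_numpy(float), sub["group"].to_numpy())
        kw_rows.append({"feature_id": col, "H": h, "p": p})
    pd.DataFrame(kw_rows).to_csv(
        config.out_path("stats_state_metrics.tsv"), sep="\t", index=False
    )

    # demographics table
    stats.demographics_table(meta).to_csv(
        config.out_path("demographics.tsv"), sep="\t", index=False
    )


def stage_report(config: RunConfig) -> None:
    """Aggregate the result tables into a single JSON report."""
    report: dict = {"config_hash": config.config_hash()}
    for name in ("graph_auc", "graph_dynamic_variance", "static_edges",
                 "edge_variance"):
        p = Path(config.output_dir) / f"stats_{name}.tsv"
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            report[name] = {
                "n_features": int(len(df)),
                "n_significant": int(df["reject"].sum()),
                "significant_features": df.loc[df.reject, "feature_id"].tolist()[:50],
            }
    sm_path = Path(config.output_dir) / "stats_state_metrics.tsv"
    if sm_path.exists():
        df = pd.read_csv(sm_path, sep="\t")
        report["state_metrics"] = df.to_dict(orient="records")
    model_path = Path(config.output_dir) / "states" / "state_model.json"
    if model_path.exists():
        sidecar = io.read_json(model_path)
        report["n_states"] = sidecar["k"]
        report["silhouette_by_k"] = sidecar["silhouette_by_k"]
    io.write_json(report, config.out_path("report.json"))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "static": stage_static,
    "dynamic": stage_dynamic,
    "states": stage_states,
    "graphs": stage_graphs,
    "stats": stage_stats,
    "report": stage_report,
}


def run_stage(config: RunConfig, stage: str) -> float:
    """Run one stage; returns wall time in seconds and updates provenance."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    t0 = time.perf_counter()
    _STAGE_FUNCS[stage](config)
    elapsed = time.perf_counter() - t0
    _log_event(config, stage=stage, event="completed", seconds=round(elapsed, 3))
    _update_provenance(config, stage, elapsed)
    return elapsed


def _update_provenance(config: RunConfig, stage: str, elapsed: float) -> None:
    import scipy
    import sklearn

    path = Path(config.output_dir) / "provenance.json"
    prov = io.read_json(path) if path.exists() else {
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "versions": {
            "dynconn": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
        "stage_seconds": {},
    }
    prov["stage_seconds"][stage] = round(elapsed, 3)
    io.write_json(prov, path)


def run_all(config: RunConfig) -> dict[str, float]:
    """Execute every stage in order; returns per-stage wall times."""
    return {stage: run_stage(config, stage) for stage in STAGES}
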