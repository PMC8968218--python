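"""End-to-end pipeline orchestration.

Stages: simulate (optional) -> preprocess -> ggm (+ bootstrap) -> dag
sampling -> effects -> report.  Each stage consumes the previous stage's
artifacts by path, derives its own seed from the master seed, and registers
everything it writes in a JSON manifest; re-running with the same config and
master seed reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bge import BgeScore, ScoreConfig
from .bootstrap import case_drop_boot, nonparametric_boot
from .config import RunConfig
from .dagmcmc import convergence_diagnostics, load_samples, sample_dags, save_samples
from .effects import effects_table, mixed_graph
from .ggm import centrality, ggm_model_select
from .preprocess import cronbach_alpha, preprocess_study
from .reporting import (
    write_edge_list,
    write_mixed_graph_dot,
    write_mixed_graph_graphml,
    write_network_csv,
    write_network_dot,
    write_network_graphml,
)
from .synthetic import (
    GeneratorConfig,
    default_study_dag,
    demo_dag_small,
    generate_study,
    read_study,
    study_reliabilities,
    write_study,
)

__all__ = ["run_pipeline", "PipelineError", "STAGES",
           "stage_simulate", "stage_preprocess", "stage_ggm", "stage_boot",
           "stage_dag", "stage_effects", "stage_report"]

log = logging.getLogger("dissonet")

STAGES = ("simulate", "preprocess", "ggm", "boot", "dag", "effects", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def _require(path: Path, stage: str, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(stage, "missing_upstream",
                            f"{path} not found; run the '{producer}' stage first")
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    """Artifact registry for one output directory."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"

    def register(self, *paths: Path) -> None:
        manifest = self.read_manifest()
        for p in paths:
            rel = str(Path(p).relative_to(self.out))
            manifest["artifacts"][rel] = _sha256(Path(p))
        self.manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    def read_manifest(self) -> dict:
        if self.manifest_path.exists():
            return json.loads(self.manifest_path.read_text())
        return {
            "package_version": __version__,
            "master_seed": self.cfg.master_seed,
            "profile": self.cfg.profile,
            "settings": {s: getattr(self.cfg, s) for s in
                         ("simulate", "preprocess", "ggm", "boot", "dag", "effects")},
            "artifacts": {},
        }


def stage_simulate(cfg: RunConfig) -> dict:
    run = _Run(cfg)
    t0 = time.time()
    sim = cfg.simulate
    dag = demo_dag_small() if sim.get("battery", "study") == "small" else default_study_dag()
    gen = GeneratorConfig(
        n=sim.get("n", 6161),
        seed=cfg.seed_for("simulate"),
        reliability={k: v for k, v in study_reliabilities().items() if k in dag.nodes},
        missing_rate=sim.get("missing_rate", 0.02),
    )
    study = generate_study(gen, dag)
    data_path = run.out / "simulated_items.csv"
    sidecar_path = run.out / "simulated_config.yaml"
    write_study(study, data_path, sidecar_path)
    run.register(data_path, sidecar_path)
    log.info("simulate: n=%d, %d constructs, %.1fs", gen.n, dag.p, time.time() - t0)
    return {"data_csv": data_path, "data_sidecar": sidecar_path}


def _load_input(cfg: RunConfig):
    run = _Run(cfg)
    if cfg.data_csv is not None:
        data_csv, sidecar = Path(cfg.data_csv), Path(cfg.data_sidecar)
    else:
        data_csv = _require(run.out / "simulated_items.csv", "preprocess", "simulate")
        sidecar = _require(run.out / "simulated_config.yaml", "preprocess", "simulate")
    return read_study(data_csv, sidecar)


def stage_preprocess(cfg: RunConfig) -> dict:
    run = _Run(cfg)
    t0 = time.time()
    data, ages, _, _ = _load_input(cfg)
    pp = cfg.preprocess
    primary, all_imps = preprocess_study(
        data, ages,
        m=pp.get("m", 5), iterations=pp.get("iterations", 10),
        seed=cfg.seed_for("preprocess"),
        max_missing_frac=pp.get("max_missing_frac", 0.20),
        age_sd_mult=pp.get("age_sd_mult", 2.0),
        min_age=pp.get("min_age", 18),
    )
    pooled = np.mean([np.corrcoef(c.z.to_numpy().T) for c in all_imps], axis=0)
    totals_path = run.out / "scale_totals.csv"
    z_path = run.out / "z_scores.csv"
    log_path = run.out / "exclusion_log.csv"
    corr_path = run.out / "pooled_correlation.csv"
    alpha_path = run.out / "cronbach_alpha.csv"
    primary.totals.to_csv(totals_path, index_label="participant_id")
    primary.z.to_csv(z_path, index_label="participant_id")
    primary.exclusion_log.to_csv(log_path, index=False)
    pd.DataFrame(pooled, index=primary.z.columns, columns=primary.z.columns).to_csv(corr_path)
    # item-level alphas on one completed dataset
    alphas = {}
    from .preprocess import filter_participants, impute

    kept, _kept_ages, _ = filter_participants(
        data, ages, max_missing_frac=pp.get("max_missing_frac", 0.20),
        age_sd_mult=pp.get("age_sd_mult", 2.0), min_age=pp.get("min_age", 18))
    completed = impute(kept, m=1, iterations=pp.get("iterations", 10),
                       seed=cfg.seed_for("preprocess"))[0]
    for spec in completed.specs:
        block = completed.items[spec.item_columns()].to_numpy().copy()
        for i in spec.reverse_items:
            block[:, i - 1] = spec.item_min + spec.item_max - block[:, i - 1]
        alphas[spec.name] = cronbach_alpha(block)
    pd.Series(alphas, name="alpha").to_csv(alpha_path, index_label="scale")
    run.register(totals_path, z_path, log_path, corr_path, alpha_path)
    log.info("preprocess: kept %d rows, excluded %d, %.1fs",
             len(primary.kept_ids), len(primary.exclusion_log), time.time() - t0)
    return {"totals": totals_path, "z": z_path, "pooled_correlation": corr_path}


def _read_z(run: _Run, stage: str):
    z_path = _require(run.out / "z_scores.csv", stage, "preprocess")
    z = pd.read_csv(z_path, index_col="participant_id")
    corr_path = _require(run.out / "pooled_correlation.csv", stage, "preprocess")
    R = pd.read_csv(corr_path, index_col=0)
    return z, R


def stage_ggm(cfg: RunConfig) -> dict:
    run = _Run(cfg)
    t0 = time.time()
    z, R = _read_z(run, "ggm")
    net = ggm_model_select(R.to_numpy(), n=len(z), gamma=cfg.ggm.get("gamma", 0.5),
                           labels=list(R.columns),
                           n_penalties=cfg.ggm.get("n_penalties", 100))
    paths = {
        "matrix": run.out / "ggm_weights.csv",
        "edges": run.out / "ggm_edges.csv",
        "graphml": run.out / "ggm_network.graphml",
        "dot": run.out / "ggm_network.dot",
        "centrality": run.out / "ggm_centrality.csv",
    }
    write_network_csv(net, paths["matrix"])
    write_edge_list(net, paths["edges"])
    write_network_graphml(net, paths["graphml"])
    write_network_dot(net, paths["dot"])
    centrality(net).to_csv(paths["centrality"], index_label="node")
    run.register(*paths.values())
    log.info("ggm: %d edges, EBIC %.1f, %.1fs", len(net.edges), net.ebic, time.time() - t0)
    return paths


def stage_boot(cfg: RunConfig) -> dict:
    run = _Run(cfg)
    t0 = time.time()
    z, R = _read_z(run, "boot")
    bt = cfg.boot
    result = nonparametric_boot(
        z.to_numpy(), B=bt.get("B", 5000), seed=cfg.seed_for("boot"),
        gamma=cfg.ggm.get("gamma", 0.5), labels=list(z.columns),
        n_penalties=cfg.ggm.get("n_penalties", 100),
    )
    cs, cs_table = case_drop_boot(
        z.to_numpy(), drop_fracs=tuple(bt.get("case_drop_fracs", [0.25, 0.5, 0.75])),
        B=bt.get("case_drop_B", 50), seed=cfg.seed_for("boot_casedrop"),
        gamma=cfg.ggm.get("gamma", 0.5), labels=list(z.columns),
        n_penalties=cfg.ggm.get("n_penalties", 100),
    )
    paths = {
        "edge_summary": run.out / "boot_edge_summary.csv",
        "diff_matrix": run.out / "boot_edge_differences.csv",
        "cs": run.out / "boot_cs_coefficients.csv",
        "cs_detail": run.out / "boot_cs_detail.csv",
    }
    result.summary().to_csv(paths["edge_summary"], index=False)
    names = ["--".join(e) for e in result.edge_names]
    pd.DataFrame(result.difference_matrix(), index=names, columns=names).to_csv(
        paths["diff_matrix"])
    pd.Series(cs, name="cs_coefficient").to_csv(paths["cs"], index_label="centrality")
    cs_table.to_csv(paths["cs_detail"], index=False)
    run.register(*paths.values())
    log.info("boot: B=%d (%d failed), CS=%s, %.1fs",
             bt.get("B"), result.n_failed, cs, time.time() - t0)
    return paths


def stage_dag(cfg: RunConfig) -> dict:
    run = _Run(cfg)
    t0 = time.time()
    z, R = _read_z(run, "dag")
    n = len(z)
    dg = cfg.dag
    score_cfg = ScoreConfig(am=dg.get("am", 1.0), aw=dg.get("aw"),
                            edge_penalty=dg.get("edge_penalty", 0.0))
    # the BGe score needs only the scatter matrix: pooled correlation * n
    def chain(seed):
        score = BgeScore.from_scatter(R.to_numpy() * n, n, score_cfg, labels=list(R.columns))
        return sample_dags(
            score, iterations=dg.get("iterations", 200_000),
            burn_in=dg.get("burn_in"), thinning=dg.get("thinning"),
            seed=seed, sampler=dg.get("sampler", "partition"),
            target_samples=dg.get("target_samples", 2000),
        )
    samples = chain(cfg.seed_for("dag"))
    second = chain(cfg.seed_for("dag_chain2"))
    diag = convergence_diagnostics(samples, second)
    paths = {
        "samples": run.out / "dag_samples.txt",
        "diagnostics": run.out / "dag_diagnostics.json",
        "edge_freq": run.out / "dag_edge_frequencies.csv",
    }
    save_samples(samples, paths["samples"])
    paths["diagnostics"].write_text(json.dumps(diag, indent=2))
    F = samples.edge_frequency_matrix()
    pd.DataFrame(F, index=samples.labels, columns=samples.labels).to_csv(paths["edge_freq"])
    run.register(*paths.values())
    log.info("dag: %d retained DAGs, chain gap %.3f%s, %.1fs", len(samples),
             diag["max_edge_frequency_gap"],
             " (FLAGGED)" if diag["flagged"] else "", time.time() - t0)
    return paths


def stage_effects(cfg: RunConfig) -> dict:
    run = _Run(cfg)
    t0 = time.time()
    z, _ = _read_z(run, "effects")
    samples = load_samples(_require(run.out / "dag_samples.txt", "effects", "dag"))
    ef = cfg.effects
    paths = {}
    for focus in ef.get("focus", ["dissociation"]):
        if focus not in samples.labels:
            raise PipelineError("effects", "unknown_focus", f"{focus} not a sampled variable")
        table = effects_table(samples, z.to_numpy(), focus)
        path = run.out / f"effects_{focus}.csv"
        table.to_csv(path, index=False)
        paths[f"effects_{focus}"] = path
    mg = mixed_graph(samples, ef.get("edge_threshold", 0.50), ef.get("direction_threshold", 0.90))
    paths["mixed_graphml"] = run.out / "mixed_graph.graphml"
    paths["mixed_dot"] = run.out / "mixed_graph.dot"
    write_mixed_graph_graphml(mg, paths["mixed_graphml"])
    write_mixed_graph_dot(mg, paths["mixed_dot"])
    run.register(*paths.values())
    log.info("effects: %d directed + %d undirected mixed-graph edges, %.1fs",
             len(mg.directed_edges), len(mg.undirected_edges), time.time() - t0)
    return paths


def stage_report(cfg: RunConfig) -> dict:
    run = _Run(cfg)
    manifest = run.read_manifest()
    manifest["completed"] = sorted(manifest["artifacts"])
    run.manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("report: %d artifacts in %s", len(manifest["artifacts"]), run.manifest_path)
    return {"manifest": run.manifest_path}


def run_pipeline(cfg: RunConfig, skip_simulate: bool | None = None) -> dict:
    """Execute every stage in order; returns the manifest dictionary."""
    if skip_simulate is None:
        skip_simulate = cfg.data_csv is not None
    stages = [s for s in STAGES if not (s == "simulate" and skip_simulate)]
    for stage in stages:
        fn = globals()[f"stage_{stage}"]
        try:
            fn(cfg)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
            raise PipelineError(stage, "stage_failure", str(exc)) from exc
    return _Run(cfg).read_manifest()
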