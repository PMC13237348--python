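"""Configuration-driven orchestration of the full workflow.

Stages: simulate (or load) -> gfp (optional window detection) -> train ->
attribute (AP I / AP II) -> fc + network comparison -> behavior. Each stage
writes its artifacts under the run directory; a manifest records seeds,
configuration, and SHA-256 checksums so that reruns with identical
config + seed are verifiable bit-for-bit on deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synth
from .attribution import ap1_common, ap2_differential, attribute_epochs
from .behavior import compute_costs, rank_edge_rt_correlations, stepwise_regression, zscore
from .data import (
    Connectome,
    EpochSet,
    TrialTable,
    read_connectome,
    read_epochs,
    read_trials,
    write_connectome,
    write_epochs,
    write_trials,
)
from .fc import acm_mask, common_fc_test, differential_fc_test
from .gfp import detect_windows
from .models.train import TrainConfig, train_model
from .netcompare import spd_null_test

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_experiment", "write_report"]


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    # inputs: either paths or a simulation config
    connectome_path: str | None = None
    epochs_path: str | None = None
    trials_path: str | None = None
    simulation: synth.SimulationConfig | None = None
    # analysis window: explicit [start, end) ms or "from-gfp"
    window_ms: tuple[float, float] | str | None = None
    band: tuple[float, float] = (2.0, 13.0)
    train: TrainConfig = field(default_factory=TrainConfig)
    ig_steps: int = 64
    n_perm: int = 10000
    alpha: float = 0.05
    fc_metric: str = "plv"
    fc_n_surrogate: int = 200
    n_null: int = 5000
    run_fc: bool = True
    run_behavior: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw["simulation"]
            for key in ("osc_band", "diff_gains", "planted_common_edges",
                        "planted_diff_edges", "gfp_window_ms"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            raw["simulation"] = synth.SimulationConfig(**sim)
        if "train" in raw and raw["train"] is not None:
            raw["train"] = TrainConfig(**raw["train"])
        for key in ("band", "window_ms"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate_paths(self) -> None:
        for p in (self.connectome_path, self.epochs_path, self.trials_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file does not exist: {p}")
        if self.simulation is None and (self.connectome_path is None or self.epochs_path is None):
            raise ValueError("config needs either a simulation block or connectome+epochs paths")


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seeds: dict
    checksums: dict
    wall_clock_s: dict
    stages: list

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_experiment(config: RunConfig) -> RunManifest:
    """Execute all configured stages in dependency order.

    Any stage failure aborts with the stage name; partial outputs persist in
    the run directory.
    """
    from . import __version__

    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    wall: dict[str, float] = {}
    stages: list[str] = []
    seeds = {"master": config.seed}
    stage = "setup"

    def _finish(name: str, t0: float, *paths: Path):
        wall[name] = round(time.time() - t0, 3)
        stages.append(name)
        for p in paths:
            checksums[p.name] = _sha256(p)

    try:
        # -- simulate or load ------------------------------------------------
        stage = "simulate"
        t0 = time.time()
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            conn = synth.make_connectome(sim.n_nodes, sim.n_edges, sim.rewire_prob, seed=sim.seed)
            epochs, truth = synth.simulate_epochs(conn, sim)
            trials, rt1 = synth.simulate_trials(truth)
            write_connectome(conn, out / "connectome.tsv")
            write_epochs(epochs, out / "epochs.h5")
            write_trials(trials, out / "trials.csv")
            truth.to_json(out / "ground_truth.json")
            _finish("simulate", t0, out / "connectome.tsv", out / "epochs.h5",
                    out / "trials.csv", out / "ground_truth.json")
        else:
            conn = read_connectome(config.connectome_path)
            epochs = read_epochs(config.epochs_path)
            trials = read_trials(config.trials_path) if config.trials_path else None
            rt1 = None
            _finish("load", t0)

        # -- window selection ------------------------------------------------
        stage = "gfp"
        t0 = time.time()
        window = config.window_ms
        if window == "from-gfp":
            gfp_res = detect_windows(epochs, alpha=config.alpha)
            if not gfp_res.windows_ms:
                raise RuntimeError("GFP stage found no significant window")
            window = max(gfp_res.windows_ms, key=lambda w: w[1] - w[0])
            (out / "gfp.json").write_text(json.dumps({
                "windows_ms": gfp_res.windows_ms, "selected": list(window)}, indent=1))
            _finish("gfp", t0, out / "gfp.json")
        analysis = epochs if window is None else epochs.crop_ms(*window)

        # -- train -----------------------------------------------------------
        stage = "train"
        t0 = time.time()
        tconf = dataclasses.replace(config.train, seed=config.seed)
        seeds["train"] = tconf.seed
        folds, report = train_model(analysis, conn, tconf)
        metrics = {"per_fold": report.per_fold, "summary": report.summary()}
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))
        _finish("train", t0, out / "metrics.json")

        # -- attribute -------------------------------------------------------
        stage = "attribute"
        t0 = time.time()
        # AP I uses the true-class logit (its null never touches labels);
        # AP II uses the predicted-class logit so values stay exchangeable
        # under its label-permutation null
        attr = attribute_epochs(folds, analysis, conn, steps=config.ig_steps,
                                target="true")
        attr_pred = attribute_epochs(folds, analysis, conn, steps=config.ig_steps,
                                     target="pred")
        seeds["ap1"] = config.seed + 101
        seeds["ap2"] = config.seed + 202
        ap1 = ap1_common(attr, n_perm=config.n_perm, alpha=config.alpha, seed=seeds["ap1"])
        ap2 = ap2_differential(attr_pred, n_perm=config.n_perm, alpha=config.alpha, seed=seeds["ap2"])
        labels = conn.atlas.labels
        ap1.to_frame(labels).to_csv(out / "edges_common.tsv", sep="\t", index=False)
        ap2.to_frame(labels).to_csv(out / "edges_differential.tsv", sep="\t", index=False)
        np.save(out / "acgfc_values.npy", attr.values)
        _finish("attribute", t0, out / "edges_common.tsv", out / "edges_differential.tsv")

        # -- conventional FC + network comparison ----------------------------
        if config.run_fc:
            stage = "fc"
            t0 = time.time()
            seeds["fc"] = config.seed + 303
            fc_common = common_fc_test(analysis, config.fc_metric, config.band,
                                       config.fc_n_surrogate, config.alpha, seeds["fc"])
            fc_masked = acm_mask(fc_common, conn)
            fc_common.to_frame(labels).to_csv(out / "fc_common.tsv", sep="\t", index=False)
            comparison = None
            if ap1.significant.any() and fc_common.significant.any():
                seeds["compare"] = config.seed + 404
                comparison = spd_null_test(ap1.significant_edges, fc_common.significant_edges,
                                           conn, n_null=config.n_null, seed=seeds["compare"])
                (out / "comparison.json").write_text(json.dumps({
                    "js": comparison.js, "spd": comparison.spd, "fd": comparison.fd,
                    "p_one_sided": comparison.p_one_sided, "null_mean": comparison.null_mean,
                    "pct_below_null_mean": comparison.pct_below_null_mean,
                    "n_null": comparison.n_null, "acm_fc_count": int(fc_masked.significant.sum()),
                }, indent=1, sort_keys=True))
                _finish("fc", t0, out / "fc_common.tsv", out / "comparison.json")
            else:
                _finish("fc", t0, out / "fc_common.tsv")

        # -- behavior --------------------------------------------------------
        if config.run_behavior and trials is not None:
            stage = "behavior"
            t0 = time.time()
            costs = compute_costs(trials)
            payload = {"costs": costs.group}
            if rt1 is not None and ap2.significant.any():
                sig_cols = np.nonzero(ap2.significant)[0]
                ranked = rank_edge_rt_correlations(
                    attr.values[:, sig_cols], rt1,
                    edge_index=[attr.edge_index[c] for c in sig_cols])
                reg = stepwise_regression(
                    attr.values[:, sig_cols], zscore(rt1),
                    names=[str(attr.edge_index[c]) for c in sig_cols])
                payload["edge_rt_rank"] = ranked.to_dict(orient="records")
                payload["stepwise"] = reg.steps
            (out / "behavior.json").write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
            _finish("behavior", t0, out / "behavior.json")
    except Exception as err:
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    manifest = RunManifest(__version__, _config_hash(config), seeds, checksums, wall, stages)
    manifest.to_json(out / "manifest.json")
    return manifest


def write_report(run_dir: str | Path) -> Path:
    """Assemble machine-readable summaries of a finished run into report.json
    (diff-stable key order). Incomplete runs are flagged, not rejected."""
    run_dir = Path(run_dir)
    report: dict = {"complete": True}
    expected = ["manifest.json", "metrics.json", "edges_common.tsv", "edges_differential.tsv"]
    for name in expected:
        if not (run_dir / name).exists():
            report["complete"] = False
            report.setdefault("missing", []).append(name)
    for name in ("manifest", "metrics", "comparison", "behavior", "gfp"):
        p = run_dir / f"{name}.json"
        if p.exists():
            report[name] = json.loads(p.read_text())
    for name, key in (("edges_common.tsv", "common_edges"),
                      ("edges_differential.tsv", "differential_edges")):
        p = run_dir / name
        if p.exists():
            import pandas as pd

            df = pd.read_csv(p, sep="\t")
            report[key] = df[df["significant"] == 1].to_dict(orient="records")
    out = run_dir / "report.json"
    out.write_text(json.dumps(report, indent=1, sort_keys=True))
    return out
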