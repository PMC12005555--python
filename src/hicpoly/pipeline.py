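"""End-to-end orchestration of the two structure-estimation approaches.

The maximum-entropy route iterates simulate/compare/update before a
final full-length simulation; the network route predicts parameters in
one shot and simulates exactly once.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .gnn.model import GNNConfig, PredictionOutput, predict_params, train
from .max_entropy import LabelTracks, MEState, me_fit
from .metrics import MetricReport, evaluate_pair
from .preprocess import ContactMap, distance_normalize
from .simulator import (
    InteractionParams,
    PolymerConfig,
    StructureEnsemble,
    contact_map_from_ensemble,
    sample_ensemble,
)
from .synthetic import TrainingPair, build_dataset, build_fixture_pool, save_dataset

__all__ = [
    "RunConfig",
    "run_me_approach",
    "run_gnn_approach",
    "run_generate_and_train",
]

logger = logging.getLogger("hicpoly")


@dataclass
class RunConfig:
    """Serializable configuration for a pipeline run."""

    polymer: PolymerConfig = field(default_factory=PolymerConfig)
    gnn: GNNConfig = field(default_factory=GNNConfig)
    me_epsilon: float = 1e-2
    me_learning_rate: float = 1.0
    me_learning_rate_t: float | None = None
    me_max_iter: int = 20
    me_n_structures_opt: int = 5000
    metric_h: int = 5
    metric_K: int = 100
    metric_kappa: int = 10
    n_pool_members: int = 8
    n_training_samples: int = 128
    seed: int = 0
    output_dir: str = "runs"

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            if isinstance(x, np.generic):
                return x.item()
            return x

        return clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("polymer"), dict):
            d["polymer"] = PolymerConfig(**d["polymer"])
        if isinstance(d.get("gnn"), dict):
            d["gnn"] = GNNConfig(**d["gnn"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _archive(cfg: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "run_config.yaml")


def _evaluate(H_sim: ContactMap, H_exp: ContactMap, cfg: RunConfig) -> MetricReport:
    return evaluate_pair(
        H_sim,
        H_exp,
        distance_normalize(H_sim),
        distance_normalize(H_exp),
        h=cfg.metric_h,
        K=cfg.metric_K,
        kappa=cfg.metric_kappa,
    )


def run_me_approach(
    H_exp: ContactMap,
    Psi: LabelTracks | None,
    cfg: RunConfig,
    outdir: str | Path | None = None,
) -> tuple[ContactMap, InteractionParams, MetricReport, MEState]:
    """Maximum-entropy fit followed by a final full-length simulation."""
    poly = replace(cfg.polymer, m=H_exp.m, seed=cfg.seed)
    if Psi is None:
        from .max_entropy import default_labels

        Psi = default_labels(H_exp)
    t0 = time.time()
    params, state = me_fit(
        H_exp,
        Psi,
        epsilon=cfg.me_epsilon,
        poly_cfg=poly,
        max_iter=cfg.me_max_iter,
        learning_rate=cfg.me_learning_rate,
        learning_rate_t=cfg.me_learning_rate_t,
        n_structures_opt=cfg.me_n_structures_opt,
    )
    logger.info(
        "ME fit: %d iterations, converged=%s, %.1fs",
        state.iteration, state.converged, time.time() - t0,
    )
    final_cfg = replace(poly, seed=cfg.seed + 777_777)
    ensemble = sample_ensemble(params, final_cfg)
    H_sim = contact_map_from_ensemble(ensemble)
    report = _evaluate(H_sim, H_exp, cfg)
    if outdir is not None:
        outdir = Path(outdir)
        _archive(cfg, outdir)
        np.savez_compressed(outdir / "me_fit.npz", L=params.L, T=params.T,
                            t_diag=state.t_diag, chi=state.chi.chi, Psi=Psi.Psi)
        _write_history(state, outdir / "me_history.tsv")
        (outdir / "metrics.tsv").write_text(report.to_tsv_row())
    return H_sim, params, report, state


def _write_history(state: MEState, path: Path) -> None:
    lines = ["iteration\tresidual"]
    for i, r in enumerate(state.observable_residuals, start=1):
        lines.append(f"{i}\t{r:.6g}")
    path.write_text("\n".join(lines) + "\n")


def run_gnn_approach(
    H_exp: ContactMap,
    weights,
    cfg: RunConfig,
    outdir: str | Path | None = None,
    _sim_counter: list | None = None,
) -> tuple[ContactMap, PredictionOutput, MetricReport]:
    """Predict parameters with the trained network, then simulate once."""
    prediction = predict_params(H_exp, weights, cfg.gnn)
    poly = replace(cfg.polymer, m=H_exp.m, seed=cfg.seed)
    ensemble = sample_ensemble(prediction.as_params(), poly)
    if _sim_counter is not None:
        _sim_counter.append(1)
    H_sim = contact_map_from_ensemble(ensemble)
    report = _evaluate(H_sim, H_exp, cfg)
    if outdir is not None:
        outdir = Path(outdir)
        _archive(cfg, outdir)
        np.savez_compressed(outdir / "prediction.npz",
                            L_hat=prediction.L_hat, T_hat=prediction.T_hat)
        (outdir / "metrics.tsv").write_text(report.to_tsv_row())
    return H_sim, prediction, report


def run_generate_and_train(
    cfg: RunConfig, outdir: str | Path | None = None
) -> tuple[dict, dict, list[TrainingPair]]:
    """Fixture pool -> synthetic dataset -> network training."""
    pool = build_fixture_pool(
        m=cfg.polymer.m, k=10, n_members=cfg.n_pool_members, seed=cfg.seed
    )
    t0 = time.time()
    dataset = build_dataset(pool, cfg.n_training_samples, cfg.polymer, seed=cfg.seed + 1)
    logger.info("generated %d training pairs in %.1fs", len(dataset), time.time() - t0)
    gnn_cfg = replace(cfg.gnn, n_nodes=cfg.polymer.m // 2, seed=cfg.seed)
    weights, history = train(dataset, gnn_cfg)
    if outdir is not None:
        outdir = Path(outdir)
        _archive(cfg, outdir)
        save_dataset(dataset, outdir / "dataset")
        from .gnn.model import save_weights

        save_weights(weights, gnn_cfg, outdir / "weights.npz")
        lines = ["epoch\ttrain_loss\tval_loss"]
        for e, (tr, va) in enumerate(zip(history["train_loss"], history["val_loss"])):
            lines.append(f"{e}\t{tr:.6g}\t{va:.6g}")
        (outdir / "training_curves.tsv").write_text("\n".join(lines) + "\n")
    return weights, history, dataset
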