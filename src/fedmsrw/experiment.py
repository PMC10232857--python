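"""Experiment orchestration: configs, cross-validation, checkpoints.

An experiment is described by a YAML/JSON config with sections

* ``data`` — either a list of client profiles for the synthetic phantom
  generator, or per-client NIfTI manifest paths;
* ``network`` — architecture knobs (:class:`~fedmsrw.nn.NetworkConfig`);
* ``federation`` — protocol settings (:class:`~fedmsrw.federation.FederationConfig`);
* ``inference`` — tiling stride and binarisation threshold;
* ``cv`` — number of cross-validation folds.

Each client's cases are split into N folds (shuffled within client,
round-robin); every fold in turn is held out while the remaining folds
train the federation.  The final report averages per-case Dice over all
cases across folds and pools voxel confusion counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .federation import FederationConfig, run_federation
from .inference import evaluate_client
from .metrics import ConfusionCounts, MetricsReport, volume_metrics
from .nn import NetworkConfig, ParameterPartition
from .phantom import (
    ClientProfile,
    SyntheticCase,
    _stable_client_key,
    generate_federation,
    read_client_cases,
)

__all__ = [
    "FoldAssignment",
    "split_folds",
    "load_config",
    "build_dataset",
    "run_experiment",
    "ExperimentResult",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Per-client mapping case_id -> fold index."""

    folds: dict[str, dict[str, int]]
    n_folds: int

    def split(self, client_id: str, test_fold: int) -> tuple[list[str], list[str]]:
        """(train ids, test ids) for one client and held-out fold."""
        assign = self.folds[client_id]
        train = [c for c, f in assign.items() if f != test_fold]
        test = [c for c, f in assign.items() if f == test_fold]
        return train, test


def split_folds(
    case_ids: dict[str, list[str]], n_folds: int, seed: int
) -> FoldAssignment:
    """Shuffle each client's cases deterministically and deal round-robin.

    Fold sizes within a client differ by at most one; every case lands in
    exactly one fold.  Splitting is stratified per client only (each site
    keeps its own N-fold split).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    folds: dict[str, dict[str, int]] = {}
    for cid, ids in case_ids.items():
        if len(ids) < n_folds:
            raise ValueError(
                f"client {cid!r} has {len(ids)} cases, fewer than {n_folds} folds"
            )
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, _stable_client_key(cid)])
        )
        order = list(ids)
        rng.shuffle(order)
        folds[cid] = {case_id: i % n_folds for i, case_id in enumerate(order)}
    return FoldAssignment(folds=folds, n_folds=n_folds)


# -- config handling -------------------------------------------------------

_SECTIONS = {"data", "network", "federation", "inference", "cv"}


def load_config(path_or_dict) -> dict:
    """Load and validate an experiment config (YAML or JSON)."""
    if isinstance(path_or_dict, (str, Path)):
        cfg = yaml.safe_load(Path(path_or_dict).read_text())
    else:
        cfg = dict(path_or_dict)
    unknown = set(cfg) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    if "data" not in cfg:
        raise ValueError("config must contain a 'data' section")
    cfg.setdefault("network", {})
    cfg.setdefault("federation", {})
    cfg.setdefault("inference", {})
    cfg.setdefault("cv", {"n_folds": 2})

    def _check_fields(section: str, cls):
        allowed = {f.name for f in dataclasses.fields(cls)}
        bad = set(cfg[section]) - allowed
        if bad:
            raise ValueError(f"unknown keys in '{section}': {sorted(bad)}")

    _check_fields("network", NetworkConfig)
    _check_fields("federation", FederationConfig)
    bad_inf = set(cfg["inference"]) - {"stride", "threshold"}
    if bad_inf:
        raise ValueError(f"unknown keys in 'inference': {sorted(bad_inf)}")
    bad_cv = set(cfg["cv"]) - {"n_folds", "seed"}
    if bad_cv:
        raise ValueError(f"unknown keys in 'cv': {sorted(bad_cv)}")
    return cfg


def build_dataset(data_cfg: dict, seed: int) -> dict[str, list[SyntheticCase]]:
    """Materialise the per-client case lists a config describes."""
    if "clients" in data_cfg:
        profiles = [ClientProfile(**c) for c in data_cfg["clients"]]
        return generate_federation(profiles, rng_seed=seed)
    if "manifests" in data_cfg:
        return {
            cid: read_client_cases(path)
            for cid, path in data_cfg["manifests"].items()
        }
    raise ValueError("'data' section needs either 'clients' or 'manifests'")


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(path, state: dict[str, np.ndarray], partition: ParameterPartition):
    """Flat named-value checkpoint with the partition stored alongside."""
    np.savez(
        path,
        __bn_names__=np.array(list(partition.bn_names)),
        __rest_names__=np.array(list(partition.rest_names)),
        **state,
    )


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], ParameterPartition]:
    with np.load(path, allow_pickle=False) as npz:
        bn = tuple(str(n) for n in npz["__bn_names__"])
        rest = tuple(str(n) for n in npz["__rest_names__"])
        state = {
            k: npz[k] for k in npz.files if not k.startswith("__")
        }
    return state, ParameterPartition(bn_names=bn, rest_names=rest)


# -- the full protocol -----------------------------------------------------


@dataclass
class ExperimentResult:
    """Cross-validated federation results.

    per_client: one pooled-over-folds report per client.
    average: unweighted mean of the per-client metric columns (the "Avg"
        column of a multi-site comparison table).
    """

    per_client: dict[str, MetricsReport]
    average: dict[str, float]
    resolved_config: dict
    per_fold_metrics: list[dict] = field(default_factory=list)
    histories: list[list[dict]] = field(default_factory=list)

    def write(self, out_dir):
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        MetricsReport.write_csv(out_dir / "metrics.csv", self.per_client)
        payload = {
            "config": self.resolved_config,
            "average": self.average,
            "per_client": {c: r.as_dict() for c, r in self.per_client.items()},
            "per_fold": self.per_fold_metrics,
        }
        (out_dir / "results.json").write_text(json.dumps(payload, indent=2))
        (out_dir / "history.json").write_text(json.dumps(self.histories, indent=2))


def run_experiment(config, out_dir=None, progress: bool = False) -> ExperimentResult:
    """Run the full N-fold federated protocol a config describes."""
    cfg = load_config(config)
    fed_cfg = FederationConfig(**cfg["federation"])
    net_cfg = NetworkConfig(**cfg["network"])
    n_folds = int(cfg["cv"].get("n_folds", 2))
    data_seed = int(cfg["cv"].get("seed", fed_cfg.master_seed))
    stride = cfg["inference"].get("stride")
    threshold = float(cfg["inference"].get("threshold", 0.5))

    data = build_dataset(cfg["data"], seed=data_seed)
    by_id = {cid: {c.case_id: c for c in cases} for cid, cases in data.items()}
    assignment = split_folds(
        {cid: sorted(by_id[cid]) for cid in by_id}, n_folds, seed=data_seed
    )

    per_case_dice: dict[str, dict[str, float]] = {cid: {} for cid in data}
    counts: dict[str, ConfusionCounts] = {
        cid: ConfusionCounts(0, 0, 0) for cid in data
    }
    per_fold_metrics = []
    histories = []
    for fold in range(n_folds):
        train_data = {}
        test_data = {}
        for cid in data:
            train_ids, test_ids = assignment.split(cid, fold)
            train_data[cid] = [by_id[cid][i] for i in train_ids]
            test_data[cid] = [by_id[cid][i] for i in test_ids]
        if progress:
            print(f"fold {fold + 1}/{n_folds} [{fed_cfg.mode}]")
        result = run_federation(train_data, fed_cfg, net_cfg, progress=progress)
        histories.append(result.history)

        fold_entry = {"fold": fold, "per_client": {}}
        for cid in data:
            report = evaluate_client(
                test_data[cid],
                {k: result.client_params[cid][k] for k in result.partition.rest_names},
                {k: result.client_params[cid][k] for k in result.partition.bn_names},
                result.partition,
                net_cfg,
                patch_size=fed_cfg.patch_size,
                stride=stride,
                threshold=threshold,
            )
            per_case_dice[cid].update(report.per_case_dice)
            counts[cid] = counts[cid] + report.counts
            fold_entry["per_client"][cid] = report.as_dict()
        per_fold_metrics.append(fold_entry)

        if out_dir is not None:
            ckpt_dir = Path(out_dir) / f"fold{fold}"
            ckpt_dir.mkdir(parents=True, exist_ok=True)
            save_checkpoint(
                ckpt_dir / "server.npz", result.global_params, result.partition
            )
            for cid in data:
                save_checkpoint(
                    ckpt_dir / f"{cid}.npz",
                    result.client_params[cid],
                    result.partition,
                )

    per_client = {}
    for cid in data:
        v_dice, v_tpr, v_fpr = volume_metrics(counts[cid])
        dices = list(per_case_dice[cid].values())
        per_client[cid] = MetricsReport(
            c_dice=float(np.mean(dices)),
            v_dice=100.0 * v_dice,
            v_tpr=100.0 * v_tpr,
            v_fpr=100.0 * v_fpr,
            counts=counts[cid],
            n_cases=len(dices),
            per_case_dice=per_case_dice[cid],
        )
    average = {
        key: float(np.mean([r.as_dict()[key] for r in per_client.values()]))
        for key in ("C-Dice", "V-Dice", "V-TPR", "V-FPR")
    }
    resolved = {
        "data": cfg["data"],
        "network": dataclasses.asdict(net_cfg),
        "federation": dataclasses.asdict(fed_cfg),
        "inference": {"stride": stride, "threshold": threshold},
        "cv": {"n_folds": n_folds, "seed": data_seed},
    }
    result = ExperimentResult(
        per_client=per_client,
        average=average,
        resolved_config=resolved,
        per_fold_metrics=per_fold_metrics,
        histories=histories,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
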