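"""Balanced mixed-data training and cross-validation orchestration.

A training "iteration" performs N online gradient steps (N = number of
training instances). When both data types are present, each step first draws
the data type uniformly at random and then an instance uniformly within that
type, so on average the same number of binding-affinity and eluted-ligand
examples is used per iteration regardless of set sizes. The first iteration
is the burn-in: core selection is restricted to hydrophobic P1 residues.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .data import common_motif_partition
from .encoding import (
    EncodedDataset,
    EncoderConfig,
    PeptideInstance,
    encode_dataset,
)
from .network import NetworkConfig, NetworkModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainRunConfig:
    """Configuration of a full cross-validated ensemble run.

    The trained ensemble has ``len(seeds) * len(hidden_sizes) * n_partitions``
    members (250 under the defaults).
    """

    seeds: tuple = tuple(range(10))
    hidden_sizes: tuple = (2, 10, 20, 40, 60)
    n_partitions: int = 5
    context_mode: bool = False
    iterations: int = 400
    burn_in_iterations: int = 1
    learning_rate: float = 0.05
    lr_final_fraction: float = 1.0
    initial_weight_range: float = 0.1

    @property
    def ensemble_size(self) -> int:
        return len(self.seeds) * len(self.hidden_sizes) * self.n_partitions

    def network_config(self, seed: int, hidden: int) -> NetworkConfig:
        return NetworkConfig(
            hidden_units=hidden, seed=seed, iterations=self.iterations,
            burn_in_iterations=self.burn_in_iterations,
            learning_rate=self.learning_rate,
            lr_final_fraction=self.lr_final_fraction,
            initial_weight_range=self.initial_weight_range,
        )


def draw_iteration(rng: np.random.Generator, el_idx: np.ndarray,
                   ba_idx: np.ndarray, n_steps: int) -> np.ndarray:
    """Draw the balanced instance sequence for one training iteration."""
    has_el = len(el_idx) > 0
    has_ba = len(ba_idx) > 0
    if not (has_el or has_ba):
        raise ValueError("empty training set")
    if has_el and has_ba:
        pick_el = rng.integers(0, 2, size=n_steps).astype(bool)
        el_pick = el_idx[rng.integers(0, len(el_idx), size=n_steps)]
        ba_pick = ba_idx[rng.integers(0, len(ba_idx), size=n_steps)]
        return np.where(pick_el, el_pick, ba_pick)
    pool = el_idx if has_el else ba_idx
    return pool[rng.integers(0, len(pool), size=n_steps)]


def train_network(ds: EncodedDataset, cfg: NetworkConfig) -> NetworkModel:
    """Train one network on a pre-encoded dataset.

    Deterministic given ``cfg.seed``: weight initialization and the balanced
    draw sequence both derive from it.
    """
    if len(ds) == 0:
        raise ValueError("empty training set")
    model = NetworkModel(cfg, ds.config)
    w_in = model.w_in.astype(np.float32)
    b_in = model.b_in.astype(np.float32)
    w_ba = model.w_out_ba.astype(np.float32)
    b_ba = np.array([model.b_out_ba], dtype=np.float32)
    w_el = model.w_out_el.astype(np.float32)
    b_el = np.array([model.b_out_el], dtype=np.float32)

    el_idx = np.flatnonzero(ds.is_el)
    ba_idx = np.flatnonzero(~ds.is_el)
    n_steps = len(ds)
    draws = np.random.default_rng([cfg.seed, 1])

    for it in range(cfg.iterations):
        inst_seq = draw_iteration(draws, el_idx, ba_idx, n_steps)
        _kernels.train_steps(
            ds.X, ds.row_start, ds.row_count, ds.p1_hydro, ds.has_hydro,
            ds.targets, ds.is_el, w_in, b_in, w_ba, b_ba, w_el, b_el,
            inst_seq, np.float32(cfg.learning_rate_at(it)),
            it < cfg.burn_in_iterations,
        )

    model.w_in = w_in.astype(np.float64)
    model.b_in = b_in.astype(np.float64)
    model.w_out_ba = w_ba.astype(np.float64)
    model.b_out_ba = float(b_ba[0])
    model.w_out_el = w_el.astype(np.float64)
    model.b_out_el = float(b_el[0])
    return model


def train_fold(instances: list[PeptideInstance], cfg: NetworkConfig,
               encoder: EncoderConfig) -> NetworkModel:
    """Encode ``instances`` and train a single network on them."""
    return train_network(encode_dataset(instances, encoder), cfg)


# -- batch prediction -----------------------------------------------------


def batch_select(ds: EncodedDataset, model: NetworkModel, head: str):
    """Scores and core offsets of every instance in ``ds`` under one model.

    The core is the arg-max offset (smallest offset on ties); no burn-in
    restriction applies at prediction time.
    """
    y = model.forward_batch(ds.X, head)
    starts = ds.row_start
    n_rows = len(y)
    seg = np.repeat(np.arange(len(ds)), ds.row_count)
    maxs = np.maximum.reduceat(y, starts)
    idx = np.where(y == maxs[seg], np.arange(n_rows), n_rows)
    first = np.minimum.reduceat(idx, starts)
    offsets = first - starts
    return maxs, offsets


def ensemble_batch_predict(ds: EncodedDataset, models: list[NetworkModel], head: str):
    """Mean score over an ensemble plus the core offset of the best member."""
    if not models:
        raise ValueError("empty ensemble")
    total = np.zeros(len(ds))
    best = np.full(len(ds), -np.inf)
    best_off = np.zeros(len(ds), dtype=np.int64)
    for m in models:
        s, off = batch_select(ds, m, head)
        total += s
        upd = s > best
        best_off[upd] = off[upd]
        best[upd] = s[upd]
    return total / len(models), best_off


@dataclass
class CVResult:
    """Out-of-fold predictions and the trained fold models."""

    models: list  # list of (fold, seed, hidden, NetworkModel)
    partition_labels: np.ndarray
    oof_el: np.ndarray
    oof_ba: np.ndarray
    oof_offset: np.ndarray  # core offsets from the EL head
    run_config: TrainRunConfig

    def fold_models(self, fold: int) -> list[NetworkModel]:
        return [m for f, _, _, m in self.models if f == fold]

    @property
    def all_models(self) -> list[NetworkModel]:
        return [m for _, _, _, m in self.models]


def cross_validate(instances: list[PeptideInstance], run_cfg: TrainRunConfig,
                   encoder: EncoderConfig | None = None) -> CVResult:
    """Train ``len(seeds) x len(hidden_sizes)`` networks per fold and collect
    out-of-fold predictions for every instance on both heads.

    Partition labels are taken from the instances when present, otherwise
    computed with the common-motif (shared 9mer) clustering.
    """
    if encoder is None:
        encoder = EncoderConfig(context_mode=run_cfg.context_mode)
    elif encoder.context_mode != run_cfg.context_mode:
        encoder = replace(encoder, context_mode=run_cfg.context_mode)

    if any(p.partition is None for p in instances):
        labels = common_motif_partition(instances, run_cfg.n_partitions)
    else:
        labels = np.array([p.partition for p in instances], dtype=np.int64)

    for f in range(run_cfg.n_partitions):
        if not (labels == f).any():
            raise ValueError(f"partition {f} is empty")

    ds = encode_dataset(instances, encoder)
    n = len(instances)
    oof_el = np.full(n, np.nan)
    oof_ba = np.full(n, np.nan)
    oof_offset = np.zeros(n, dtype=np.int64)
    models = []

    for fold in range(run_cfg.n_partitions):
        train_idx = np.flatnonzero(labels != fold)
        test_idx = np.flatnonzero(labels == fold)
        ds_train = ds.subset(train_idx)
        ds_test = ds.subset(test_idx)
        fold_nets = []
        for seed in run_cfg.seeds:
            for hidden in run_cfg.hidden_sizes:
                cfg = run_cfg.network_config(int(seed), int(hidden))
                net = train_network(ds_train, cfg)
                models.append((fold, int(seed), int(hidden), net))
                fold_nets.append(net)
        el_score, el_off = ensemble_batch_predict(ds_test, fold_nets, "EL")
        ba_score, _ = ensemble_batch_predict(ds_test, fold_nets, "BA")
        oof_el[test_idx] = el_score
        oof_ba[test_idx] = ba_score
        oof_offset[test_idx] = el_off
        logger.info("fold %d: trained %d networks on %d instances",
                    fold, len(fold_nets), len(train_idx))

    return CVResult(models=models, partition_labels=labels, oof_el=oof_el,
                    oof_ba=oof_ba, oof_offset=oof_offset, run_config=run_cfg)
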