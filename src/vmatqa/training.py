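"""Training protocol and evaluation for the GPR prediction network.

Protocol: data split 3:1 into training and test, 20% of the training portion
held out for validation, four-fold cross-validation; Adam at learning rate
0.001, batch size 4, 200 epochs, mean-squared-error loss averaged uniformly
over the nine unit-scaled GPR outputs; the weights reported for a run are
those of the epoch with the smallest validation loss (earliest epoch on
ties).  Evaluation reports, per criterion, the mean absolute error, the
Pearson correlation between measured and predicted GPR of the pooled test
cases of each fold, and the fraction of predictions within +/-3% of the
measurement, each as mean +/- SD across folds.

Given a dataset and a seed the full pipeline (folds -> training ->
report) is bit-reproducible on one machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError, TrainingDivergedError
from .gamma import NINE_CRITERIA
from .mlpm import build_mlpm, find_always_closed_pairs
from .network import MultiBranchGprNet, NetworkConfig, build_network, make_optimizer
from .synthetic import SyntheticDataset


@dataclass(frozen=True)
class TrainConfig:
    """Printed training protocol: 200 epochs, batch 4, Adam at 1e-3."""

    epochs: int = 200
    batch_size: int = 4
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint, exhaustive test folds plus per-fold validation subsets."""

    test_folds: tuple[tuple[str, ...], ...]
    val_folds: tuple[tuple[str, ...], ...]
    all_ids: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.test_folds)

    @property
    def assignments(self) -> dict[str, int]:
        return {pid: f for f, fold in enumerate(self.test_folds) for pid in fold}

    def train_ids(self, fold: int) -> tuple[str, ...]:
        test = set(self.test_folds[fold])
        val = set(self.val_folds[fold])
        return tuple(pid for pid in self.all_ids if pid not in test and pid not in val)


@dataclass
class TrainingLog:
    """Per-epoch train/validation loss and the adopted epoch."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def make_folds(
    ids: Sequence[str], k: int = 4, val_fraction: float = 0.2, seed: int = 0
) -> FoldPlan:
    """Seeded shuffle split into ``k`` test folds with per-fold validation.

    With 96 plans and k=4 each fold holds 24 test plans; of the remaining 72,
    ``round(0.2 * 72) = 14`` are validation and 58 training.
    """
    ids = list(ids)
    if len(ids) < k:
        raise ParameterError(f"need at least {k} ids for {k} folds")
    if len(set(ids)) != len(ids):
        raise ParameterError("ids must be unique")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    test_folds = tuple(tuple(part) for part in np.array_split(shuffled, k))

    val_folds = []
    for f in range(k):
        pool = [pid for pid in shuffled if pid not in set(test_folds[f])]
        n_val = int(round(val_fraction * len(pool)))
        perm = rng.permutation(len(pool))
        val_folds.append(tuple(pool[i] for i in perm[:n_val]))
    return FoldPlan(test_folds=test_folds, val_folds=tuple(val_folds), all_ids=tuple(ids))


def _take(inputs: Mapping[str, np.ndarray], idx: np.ndarray) -> dict[str, np.ndarray]:
    return {name: arr[idx] for name, arr in inputs.items()}


def train_model(
    network: MultiBranchGprNet,
    train_data: tuple[Mapping[str, np.ndarray], np.ndarray],
    val_data: tuple[Mapping[str, np.ndarray], np.ndarray],
    cfg: TrainConfig,
) -> TrainingLog:
    """Train in place; on return the network carries the best-epoch weights.

    Labels are expected on the unit (GPR/100) scale.  The adopted state is
    that of the epoch minimizing validation loss, earliest epoch on ties;
    a non-finite loss aborts with :class:`TrainingDivergedError`.
    """
    train_inputs, train_y = train_data
    val_inputs, val_y = val_data
    n = train_y.shape[0]
    if n == 0 or val_y.shape[0] == 0:
        raise ParameterError("train and validation sets must be non-empty")

    rng = np.random.default_rng(cfg.seed)
    optimizer = make_optimizer(network, learning_rate=cfg.learning_rate)
    log = TrainingLog()
    best_val = np.inf
    best_state = None

    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb = _take(train_inputs, idx)
            yb = train_y[idx]
            optimizer.zero_grad()
            pred = network.forward(xb, train=True)
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite training loss at epoch {epoch}")
            network.backward((2.0 / err.size) * err.astype(pred.dtype))
            optimizer.step()
            epoch_loss += loss * len(idx)
        log.train_loss.append(epoch_loss / n)

        val_pred = network.forward(val_inputs, train=False)
        val_loss = float(np.mean((val_pred - val_y) ** 2))
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(f"non-finite validation loss at epoch {epoch}")
        log.val_loss.append(val_loss)
        if val_loss < best_val:  # strict: ties keep the earlier epoch
            best_val = val_loss
            best_state = network.get_state()
            log.best_epoch = epoch

    network.set_state(best_state)
    return log


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-criterion MAE / Pearson r / +/-3% fraction, mean +/- SD over folds.

    ``r_defined`` flags criteria whose correlation was computable in every
    fold; a fold with zero variance in either vector contributes no r (it is
    reported as undefined rather than propagating NaN).
    """

    mae_folds: np.ndarray          # (k, 9)
    r_folds: np.ndarray            # (k, 9), NaN where undefined
    within3_folds: np.ndarray      # (k, 9)
    fold_pairs: list[tuple[np.ndarray, np.ndarray]]

    @property
    def criteria(self):
        return NINE_CRITERIA

    @property
    def mae_mean(self) -> np.ndarray:
        return self.mae_folds.mean(axis=0)

    @property
    def mae_sd(self) -> np.ndarray:
        return self.mae_folds.std(axis=0, ddof=1) if self.mae_folds.shape[0] > 1 else np.zeros(9)

    @property
    def r_defined(self) -> np.ndarray:
        return np.all(np.isfinite(self.r_folds), axis=0)

    @property
    def r_mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.r_folds, axis=0)

    @property
    def r_sd(self) -> np.ndarray:
        if self.r_folds.shape[0] <= 1:
            return np.zeros(9)
        with np.errstate(invalid="ignore"):
            return np.nanstd(self.r_folds, axis=0, ddof=1)

    @property
    def within3_mean(self) -> np.ndarray:
        return self.within3_folds.mean(axis=0)

    @property
    def within3_sd(self) -> np.ndarray:
        return (
            self.within3_folds.std(axis=0, ddof=1)
            if self.within3_folds.shape[0] > 1
            else np.zeros(9)
        )

    def as_dict(self) -> dict:
        out = {}
        for i, crit in enumerate(NINE_CRITERIA):
            out[str(crit)] = {
                "mae_pct": float(self.mae_mean[i]),
                "mae_sd": float(self.mae_sd[i]),
                "r": float(self.r_mean[i]) if self.r_defined[i] else None,
                "r_sd": float(self.r_sd[i]) if self.r_defined[i] else None,
                "r_defined": bool(self.r_defined[i]),
                "within_3pct": float(self.within3_mean[i]),
                "within_3pct_sd": float(self.within3_sd[i]),
            }
        return out


def evaluate(fold_pairs: Sequence[tuple[np.ndarray, np.ndarray]]) -> EvalReport:
    """Aggregate (measured, predicted) GPR pairs (%) across folds.

    Each element of ``fold_pairs`` holds the pooled test cases of one fold as
    ``(measured, predicted)`` arrays of shape (n_cases, 9).  At least two
    cases per fold are required for the correlation to be meaningful.
    """
    if not fold_pairs:
        raise ParameterError("need at least one fold")
    k = len(fold_pairs)
    mae = np.zeros((k, 9))
    r = np.full((k, 9), np.nan)
    within3 = np.zeros((k, 9))
    for f, (meas, pred) in enumerate(fold_pairs):
        meas = np.asarray(meas, dtype=float)
        pred = np.asarray(pred, dtype=float)
        if meas.shape != pred.shape or meas.ndim != 2 or meas.shape[1] != 9:
            raise ParameterError("each fold needs (n, 9) measured and predicted arrays")
        if meas.shape[0] < 2:
            raise ParameterError("need at least 2 cases per fold")
        err = pred - meas
        mae[f] = np.abs(err).mean(axis=0)
        within3[f] = np.mean(np.abs(err) <= 3.0, axis=0)
        for i in range(9):
            if np.ptp(meas[:, i]) > 0 and np.ptp(pred[:, i]) > 0:
                r[f, i] = stats.pearsonr(meas[:, i], pred[:, i]).statistic
    return EvalReport(mae_folds=mae, r_folds=r, within3_folds=within3,
                      fold_pairs=[(np.asarray(m), np.asarray(p)) for m, p in fold_pairs])


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------

def _dataset_inputs(
    dataset: SyntheticDataset, variant: str, train_ids: Sequence[str]
) -> dict[str, np.ndarray]:
    """Branch input stacks; the MLPM exclusion set is re-derived on the
    training plans only (and must reproduce the configured map height)."""
    inputs = dict(dataset.branch_inputs(variant))
    if "mlpm" in inputs:
        id_to_pos = {pid: i for i, pid in enumerate(dataset.ids)}
        train_matrices = [dataset.leaf_matrices[id_to_pos[pid]] for pid in train_ids]
        excluded = find_always_closed_pairs(train_matrices)
        if excluded != dataset.excluded_pairs:
            shape = dataset.mlpm.shape[1:]
            maps = [build_mlpm(m, excluded, shape) for m in dataset.leaf_matrices]
            inputs["mlpm"] = (
                np.stack([m.values for m in maps]) / dataset.mlpm_norm_mm
            ).astype(np.float32)
    return inputs


def _fit_and_predict(
    dataset: SyntheticDataset,
    variant: str,
    cfg: TrainConfig,
    train_ids: Sequence[str],
    val_ids: Sequence[str],
    test_ids: Sequence[str],
    net_seed: int,
) -> tuple[np.ndarray, np.ndarray, TrainingLog, MultiBranchGprNet]:
    id_to_pos = {pid: i for i, pid in enumerate(dataset.ids)}
    inputs = _dataset_inputs(dataset, variant, train_ids)
    y_unit = (dataset.labels / 100.0).astype(np.float32)

    def subset(ids_):
        idx = np.array([id_to_pos[pid] for pid in ids_])
        return _take(inputs, idx), y_unit[idx]

    config = NetworkConfig(
        variant=variant,
        input_shapes={name: arr.shape[1:] for name, arr in inputs.items()},
        seed=net_seed,
    )
    network = build_network(config)
    log = train_model(network, subset(train_ids), subset(val_ids), cfg)
    test_inputs, _ = subset(test_ids)
    idx = np.array([id_to_pos[pid] for pid in test_ids])
    predicted = network.predict(test_inputs)
    measured = dataset.labels[idx]
    return measured, predicted, log, network


@dataclass
class CrossValResult:
    report: EvalReport
    logs: list[TrainingLog]
    folds: FoldPlan


def run_cross_validation(
    dataset: SyntheticDataset,
    variant: str = "model1",
    cfg: TrainConfig = TrainConfig(),
    k: int = 4,
    val_fraction: float = 0.2,
) -> CrossValResult:
    """Full protocol: k-fold split, per-fold training, pooled-test evaluation."""
    folds = make_folds(dataset.ids, k=k, val_fraction=val_fraction, seed=cfg.seed)
    pairs = []
    logs = []
    for f in range(k):
        measured, predicted, log, _ = _fit_and_predict(
            dataset,
            variant,
            cfg,
            train_ids=folds.train_ids(f),
            val_ids=folds.val_folds[f],
            test_ids=folds.test_folds[f],
            net_seed=cfg.seed * 1000 + f,
        )
        pairs.append((measured, predicted))
        logs.append(log)
    return CrossValResult(report=evaluate(pairs), logs=logs, folds=folds)


def train_single_split(
    dataset: SyntheticDataset,
    variant: str = "model1",
    cfg: TrainConfig = TrainConfig(),
    test_fraction: float = 0.25,
    val_fraction: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, TrainingLog]:
    """One 3:1 train/test split (20% of training as validation).

    Returns (measured, predicted, log) for the held-out test plans, both in
    GPR percent.
    """
    rng = np.random.default_rng(cfg.seed)
    n = dataset.n
    order = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test_idx = order[:n_test]
    pool = order[n_test:]
    n_val = int(round(val_fraction * pool.size))
    val_idx = pool[:n_val]
    train_idx = pool[n_val:]
    ids = np.array(dataset.ids)
    measured, predicted, log, _ = _fit_and_predict(
        dataset,
        variant,
        cfg,
        train_ids=ids[train_idx],
        val_ids=ids[val_idx],
        test_ids=ids[test_idx],
        net_seed=cfg.seed,
    )
    return measured, predicted, log
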