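"""Sample-count-weighted multitask loss, AdamW optimisation and cross-validation.

The objective is

    L = sum_task (n / n_task) * sum_{i observed} CE(y_hat_i, y_i)
        + sum_i CE(y_hat_disease,i, y_disease,i)

where n is the number of training samples and n_task the number with that
metadata observed; gender uses binary cross-entropy, all other tasks
categorical cross-entropy.  Per-task sums are plain sums (not means) and the
weights n/n_task are computed once from the optimisation split, so tasks
with scarce labels are not drowned out.  Gradients are computed analytically
and the trunk gradient is masked, so weights outside the prior-knowledge
mask stay exactly zero throughout training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from microkpnn_mt.dataio import Dataset, EncodedData, stratified_folds
from microkpnn_mt.network import (
    ModelConfig,
    ModelState,
    PredictionBundle,
    forward,
    init_state,
    predict,
)
from microkpnn_mt import evaluation

__all__ = [
    "TrainConfig",
    "TrainLogEntry",
    "compute_task_weights",
    "multitask_loss",
    "loss_and_grads",
    "train",
    "cross_validate",
]

_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    weight_decay: float = 1e-2
    max_epochs: int = 200
    patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate and batch size must be positive")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


def compute_task_weights(
    observed: Mapping[str, np.ndarray],
    tasks: Sequence[str] | None = None,
) -> dict[str, float]:
    """w_task = n / n_task over the training split; tasks with no observed
    labels are dropped (their loss term would be empty anyway)."""
    tasks = list(tasks) if tasks is not None else list(observed)
    if not tasks:
        return {}
    n = len(observed[tasks[0]])
    if n < 1:
        raise ValueError("empty training split")
    weights: dict[str, float] = {}
    for task in tasks:
        n_task = int((observed[task] >= 0).sum())
        if n_task == 0:
            warnings.warn(f"task {task!r} has no observed labels; dropped from the loss", stacklevel=2)
            continue
        weights[task] = n / n_task
    return weights


def _ce(probs: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(labels)), labels], _EPS, 1.0)
    return float(-np.log(p).sum())


def multitask_loss(
    bundle: PredictionBundle,
    y_disease: np.ndarray,
    weights: Mapping[str, float],
) -> tuple[float, dict[str, float]]:
    """Total weighted loss and its per-task decomposition.

    Metadata cross-entropies run only over samples with that value observed;
    the disease term is an unweighted sum over all samples.
    """
    terms: dict[str, float] = {}
    for task, w in weights.items():
        obs = bundle.observed[task]
        sel = obs >= 0
        if not sel.any():
            terms[task] = 0.0
            continue
        P = bundle.task_probs[task][sel]
        y = obs[sel]
        if task == "gender":
            p = np.clip(P[:, 0], _EPS, 1.0 - _EPS)
            bce = -(y * np.log(p) + (1 - y) * np.log(1.0 - p)).sum()
            terms[task] = w * float(bce)
        else:
            terms[task] = w * _ce(P, y)
    terms["disease"] = _ce(bundle.disease_probs, np.asarray(y_disease))
    return sum(terms.values()), terms


def loss_and_grads(
    state: ModelState,
    X: np.ndarray,
    y_disease: np.ndarray,
    observed: Mapping[str, np.ndarray],
    weights: Mapping[str, float],
) -> tuple[float, dict[str, np.ndarray]]:
    """Analytic gradients of the multitask loss for one batch.

    The trunk gradient is multiplied by the mask, so masked positions never
    receive updates.  When predicted (missing) metadata are fused as
    probabilities, the disease loss backpropagates through the metadata
    decoders into the trunk unless the config disables it.
    """
    cfg = state.config
    bundle = forward(X, state, observed)
    loss, _ = multitask_loss(bundle, y_disease, weights)

    n, H = bundle.h.shape
    Yd = np.zeros_like(bundle.disease_probs)
    Yd[np.arange(n), y_disease] = 1.0
    dlogits_d = bundle.disease_probs - Yd                      # (n, n_disease)

    u_parts = [bundle.h] + [bundle.fused[t] for t in cfg.metadata_tasks]
    u = np.concatenate(u_parts, axis=1)
    grads: dict[str, np.ndarray] = {
        "B": u.T @ dlogits_d,
        "d": dlogits_d.sum(axis=0),
    }
    du = dlogits_d @ state.params["B"].T
    dh = du[:, :H].copy()

    offset = H
    for task in cfg.metadata_tasks:
        k = cfg.task_width(task)
        dF = du[:, offset : offset + k]
        offset += k
        P = bundle.task_probs[task]
        obs = bundle.observed[task]
        sel = obs >= 0
        dlogits_t = np.zeros((n, k))
        # supervised metadata term (observed samples only)
        if task in weights and sel.any():
            w = weights[task]
            if task == "gender":
                dlogits_t[sel, 0] += w * (P[sel, 0] - obs[sel])
            else:
                Yt = np.zeros((int(sel.sum()), k))
                Yt[np.arange(int(sel.sum())), obs[sel]] = 1.0
                dlogits_t[sel] += w * (P[sel] - Yt)
        # disease loss flowing back through predicted (fused) metadata
        if cfg.gradient_through_predicted_metadata and cfg.fusion == "probabilities":
            miss = ~sel
            if miss.any():
                dP = dF[miss]
                if task == "gender":
                    p = P[miss, 0]
                    dlogits_t[miss, 0] += dP[:, 0] * p * (1.0 - p)
                else:
                    Pm = P[miss]
                    dlogits_t[miss] += Pm * (dP - (dP * Pm).sum(axis=1, keepdims=True))
        grads[f"A_{task}"] = bundle.h.T @ dlogits_t
        grads[f"c_{task}"] = dlogits_t.sum(axis=0)
        dh += dlogits_t @ state.params[f"A_{task}"].T

    dZ = dh * (bundle.Z > 0)
    grads["W"] = (bundle.X.T @ dZ) * state.mask
    grads["b"] = dZ.sum(axis=0)
    return loss, grads


class AdamW:
    """Decoupled-weight-decay adaptive-moment optimiser."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.lr, self.wd, self.betas, self.eps = lr, weight_decay, betas, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            params[k] -= self.lr * (update + self.wd * params[k])


@dataclass
class TrainLogEntry:
    epoch: int
    train_loss: float
    val_loss: float


def validation_monitor(state: ModelState, enc: EncodedData) -> float:
    """Early-stopping criterion: mean disease cross-entropy on the held-out
    split.

    The disease task is the primary endpoint.  Monitoring the full weighted
    objective instead would let a scarce metadata task (few observed labels,
    large n/n_task weight, fast to overfit) raise the monitor and stop
    training long before the disease head has converged.
    """
    tasks = state.config.metadata_tasks
    bundle = forward(enc.X, state, {t: enc.observed[t] for t in tasks})
    _, terms = multitask_loss(bundle, enc.y_disease, {})
    return float(terms["disease"] / max(len(enc.y_disease), 1))


def _stratified_holdout(y: np.ndarray, fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Index split (fit_idx, val_idx), stratified by label."""
    if fraction <= 0:
        return np.arange(len(y)), np.array([], dtype=np.int64)
    k = max(2, int(round(1.0 / fraction)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assignment = stratified_folds(y.astype(str), k=k, seed=seed)
    val = assignment == 0
    return np.nonzero(~val)[0], np.nonzero(val)[0]


def default_model_config(enc: EncodedData, n_hidden: int,
                         metadata_tasks: tuple[str, ...] | None = None) -> ModelConfig:
    return ModelConfig(
        n_species=enc.X.shape[1],
        n_hidden=n_hidden,
        n_disease=len(enc.vocabs["disease"]),
        n_body_site=max(2, len(enc.vocabs["body_site"])),
        metadata_tasks=tuple(metadata_tasks) if metadata_tasks is not None else ("age", "gender", "bmi", "body_site"),
    )


def train(
    enc: EncodedData,
    mask: np.ndarray,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    node_names: Sequence[str] = (),
    node_groups: Sequence[str] = (),
) -> tuple[ModelState, list[TrainLogEntry]]:
    """Fit the model with AdamW and early stopping on a held-out split.

    A stratified 10% of the training data (by phenotype) is held out to
    monitor the total loss; the returned state is the one with the best
    validation loss seen.  Task weights are computed on the 90% optimisation
    split.  Deterministic given the config seed.
    """
    tc = train_config or TrainConfig()
    mask = np.asarray(mask, dtype=np.float64)
    if model_config is None:
        model_config = default_model_config(enc, n_hidden=mask.shape[1])
    if enc.n_samples == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(tc.seed)
    state = init_state(
        model_config, mask, rng,
        node_names=node_names, node_groups=node_groups, vocabs=enc.vocabs,
    )
    if tc.max_epochs == 0:
        return state, []

    fit_idx, val_idx = _stratified_holdout(enc.y_disease, tc.validation_fraction, tc.seed)
    fit = enc.take(fit_idx)
    val = enc.take(val_idx) if len(val_idx) else None
    weights = compute_task_weights(
        {t: fit.observed[t] for t in model_config.metadata_tasks},
        tasks=model_config.metadata_tasks,
    )

    opt = AdamW(state.params, lr=tc.learning_rate, weight_decay=tc.weight_decay)
    best = state.copy()
    best_val = np.inf
    stale = 0
    log: list[TrainLogEntry] = []
    n = fit.n_samples
    for epoch in range(tc.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            loss, grads = loss_and_grads(
                state, fit.X[idx], fit.y_disease[idx],
                {t: fit.observed[t][idx] for t in model_config.metadata_tasks},
                weights,
            )
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            epoch_loss += loss
            opt.step(state.params, grads)
            state.apply_mask()  # exact zero at masked positions after weight decay
        if val is not None:
            val_loss = validation_monitor(state, val)
        else:
            val_loss = epoch_loss
        log.append(TrainLogEntry(epoch=epoch, train_loss=epoch_loss / n, val_loss=val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best = state.copy()
            stale = 0
        else:
            stale += 1
            if stale >= tc.patience:
                break
    return best, log


@dataclass
class CVResult:
    per_fold: list[dict[str, "evaluation.MetricReport"]]
    folds: np.ndarray
    states: list[ModelState]

    def aggregate(self) -> pd.DataFrame:
        """Mean and standard deviation of every metric across folds."""
        rows = []
        for fold, reports in enumerate(self.per_fold):
            for task, rep in reports.items():
                rows.append(
                    dict(fold=fold, task=task, accuracy=rep.accuracy, macro_f1=rep.macro_f1,
                         macro_auc=rep.macro_auc, macro_auprc=rep.macro_auprc)
                )
        df = pd.DataFrame(rows)
        return df.groupby("task")[["accuracy", "macro_f1", "macro_auc", "macro_auprc"]].agg(["mean", "std"])


def cross_validate(
    ds: Dataset,
    mask: np.ndarray,
    k: int = 5,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    node_names: Sequence[str] = (),
    node_groups: Sequence[str] = (),
) -> CVResult:
    """Stratified k-fold cross-validation: one model per fold, seeded as
    base seed + fold index; metrics per task on the held-out fold."""
    if k < 2:
        raise ValueError("k must be at least 2")
    enc = ds.encode()
    folds = stratified_folds(ds.metadata["phenotype"].tolist(), k=k, seed=seed)
    per_fold: list[dict[str, evaluation.MetricReport]] = []
    states: list[ModelState] = []
    base_tc = train_config or TrainConfig()
    for fold in range(k):
        test_sel = folds == fold
        fit_enc = enc.take(np.nonzero(~test_sel)[0])
        test_enc = enc.take(np.nonzero(test_sel)[0])
        tc = TrainConfig(
            learning_rate=base_tc.learning_rate, batch_size=base_tc.batch_size,
            weight_decay=base_tc.weight_decay, max_epochs=base_tc.max_epochs,
            patience=base_tc.patience, validation_fraction=base_tc.validation_fraction,
            seed=base_tc.seed + fold,
        )
        state, _ = train(fit_enc, mask, model_config=model_config, train_config=tc,
                         node_names=node_names, node_groups=node_groups)
        per_fold.append(evaluate_on(state, test_enc))
        states.append(state)
    return CVResult(per_fold=per_fold, folds=folds, states=states)


def evaluate_on(state: ModelState, enc: EncodedData) -> dict[str, "evaluation.MetricReport"]:
    """Metric reports for the disease task and every enabled metadata task.

    Metadata metrics are computed on the samples whose true value is known;
    disease predictions use observed metadata where available (fusion)."""
    obs = {t: enc.observed[t] for t in state.config.metadata_tasks}
    bundle = forward(enc.X, state, obs)
    labels = predict(bundle)
    n_dis = state.config.n_disease
    reports = {
        "disease": evaluation.evaluate_task(
            labels["disease"], enc.y_disease, bundle.disease_probs, classes=range(n_dis)
        )
    }
    for task in state.config.metadata_tasks:
        truth = enc.observed[task]
        sel = truth >= 0
        if not sel.any():
            continue
        P = bundle.task_probs[task]
        if task == "gender":
            P = np.concatenate([1.0 - P, P], axis=1)
        reports[task] = evaluation.evaluate_task(
            labels[task][sel], truth[sel], P[sel], classes=range(P.shape[1])
        )
    return reports
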