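"""Attribution-based interpretation of trained models.

Two path-attribution methods are provided:

* Integrated Gradients (IG): for a differentiable scalar output F and a
  baseline x', IG_i = (x_i - x'_i) * mean over path points of dF/dx_i along
  the straight line from x' to x.  Exact for linear F; satisfies the
  completeness property sum_i IG_i -> F(x) - F(x') as the number of path
  steps grows.
* Layer Conductance (LC): the analogous attribution evaluated at the hidden
  layer, LC_j ~ sum over path segments of dF/dh_j * (segment change in h_j);
  the per-node scores sum to F(x) - F(x') (layer completeness).

Attributions are turned into importance scores by taking absolute values,
averaged over samples, then over the classes of the target task, then over
models retrained from random restarts.  The default attribution baseline is
the zero-abundance sample with all metadata missing.

The path integral uses the midpoint Riemann rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from microkpnn_mt.dataio import EncodedData
from microkpnn_mt.network import ModelState, decode_metadata, forward

__all__ = [
    "AttributionConfig",
    "ImportanceReport",
    "integrated_gradients",
    "layer_conductance",
    "metadata_impact",
    "node_importance_for_metadata",
]


@dataclass(frozen=True)
class AttributionConfig:
    steps: int = 50
    restarts: int = 20
    baseline: np.ndarray | None = None  # default: zero abundance, metadata missing

    def __post_init__(self) -> None:
        if self.steps < 8:
            raise ValueError("need at least 8 path steps")
        if self.restarts < 1:
            raise ValueError("need at least one restart")


@dataclass
class ImportanceReport:
    """Aggregated importance scores plus the per-restart raw values."""

    summary: pd.DataFrame        # entity, group, score (sorted descending)
    raw: np.ndarray              # (restarts, n_classes, n_entities) absolute scores
    task: str

    def top(self, k: int) -> pd.DataFrame:
        return self.summary.head(k)


# -- generic integrated gradients ---------------------------------------------


def integrated_gradients(
    f: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 50,
) -> np.ndarray:
    """IG attributions for a scalar function of a feature vector.

    ``f`` maps a batch of inputs to (values, gradients); ``x`` may be a
    single vector or a batch.  Gradients are averaged at the midpoints of
    ``steps`` equal path segments from the baseline (default: zeros) to x.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    baseline = np.zeros_like(x) if baseline is None else np.broadcast_to(
        np.asarray(baseline, dtype=np.float64), x.shape
    )
    delta = x - baseline
    total = np.zeros_like(x)
    for k in range(steps):
        alpha = (k + 0.5) / steps
        _, grad = f(baseline + alpha * delta)
        if not np.isfinite(grad).all():
            raise FloatingPointError("non-finite gradient on the integration path")
        total += grad
    return delta * total / steps


# -- model-specific gradients -------------------------------------------------


def _metadata_grad_h(state: ModelState, h: np.ndarray, task: str, target_class: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Value and dF/dh for F = probability of ``target_class`` of a metadata task."""
    P = decode_metadata(h, state, task)
    A = state.params[f"A_{task}"]
    if task == "gender":
        p = P[:, 0]
        sign = 1.0 if target_class == 1 else -1.0
        value = p if target_class == 1 else 1.0 - p
        dlogit = sign * p * (1.0 - p)          # (n,)
        return value, dlogit[:, None] * A[:, 0][None, :]
    value = P[:, target_class]
    e = np.zeros(P.shape[1])
    e[target_class] = 1.0
    dlogits = P * (e - P[:, target_class : target_class + 1])  # d p_c / d logits
    return value, dlogits @ A.T


def _disease_grad_u(state: ModelState, u: np.ndarray, target_class: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Value and gradient of the disease class probability w.r.t. the disease
    decoder input u = [h ; fused metadata]."""
    B, d = state.params["B"], state.params["d"]
    logits = u @ B + d
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    P = e / e.sum(axis=1, keepdims=True)
    value = P[:, target_class]
    ec = np.zeros(P.shape[1])
    ec[target_class] = 1.0
    dlogits = P * (ec - P[:, target_class : target_class + 1])
    return value, dlogits @ B.T


def _disease_grad_h(
    state: ModelState,
    h: np.ndarray,
    observed: Mapping[str, np.ndarray],
    target_class: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Value and dF/dh for the disease class probability, including the path
    through predicted (missing) metadata; observed metadata are constants."""
    cfg = state.config
    h = np.atleast_2d(h)
    n, H = h.shape
    probs = {t: decode_metadata(h, state, t) for t in cfg.metadata_tasks}
    from microkpnn_mt.network import fuse_metadata, disease_input

    fused = fuse_metadata(probs, observed, cfg)
    u = disease_input(h, fused, cfg)
    value, du = _disease_grad_u(state, u, target_class)
    dh = du[:, :H].copy()
    offset = H
    for task in cfg.metadata_tasks:
        k = cfg.task_width(task)
        dF = du[:, offset : offset + k]
        offset += k
        miss = np.asarray(observed.get(task, np.full(n, -1))) < 0
        if not miss.any():
            continue
        P = probs[task]
        A = state.params[f"A_{task}"]
        dlogits = np.zeros((n, k))
        if task == "gender":
            p = P[miss, 0]
            dlogits[miss, 0] = dF[miss, 0] * p * (1.0 - p)
        else:
            Pm = P[miss]
            dPm = dF[miss]
            dlogits[miss] = Pm * (dPm - (dPm * Pm).sum(axis=1, keepdims=True))
        dh += dlogits @ A.T
    return value, dh


def _trunk_points(state: ModelState, X: np.ndarray, baseline: np.ndarray, alpha: float
                  ) -> np.ndarray:
    Xa = baseline + alpha * (X - baseline)
    Z = Xa @ (state.params["W"] * state.mask) + state.params["b"]
    return np.maximum(Z, 0.0)


def layer_conductance(
    state: ModelState,
    X: np.ndarray,
    baseline: np.ndarray | None = None,
    task: str = "disease",
    target_class: int = 0,
    steps: int = 50,
    observed: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-hidden-node conductance for one output class.

    For each straight-line path segment in input space, the output gradient
    with respect to the hidden activations (at the segment midpoint) is
    multiplied by the segment's change in those activations; summing over
    segments gives scores whose total approximates F(x) - F(baseline).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[0]
    baseline = np.zeros_like(X) if baseline is None else np.broadcast_to(
        np.asarray(baseline, dtype=np.float64), X.shape
    )
    observed = dict(observed or {})
    for t in state.config.metadata_tasks:
        observed.setdefault(t, np.full(n, -1, dtype=np.int64))

    cond = np.zeros((n, state.config.n_hidden))
    h_left = _trunk_points(state, X, baseline, 0.0)
    for k in range(steps):
        h_right = _trunk_points(state, X, baseline, (k + 1) / steps)
        h_mid = _trunk_points(state, X, baseline, (k + 0.5) / steps)
        if task == "disease":
            _, dh = _disease_grad_h(state, h_mid, observed, target_class)
        else:
            _, dh = _metadata_grad_h(state, h_mid, task, target_class)
        cond += dh * (h_right - h_left)
        h_left = h_right
    return cond


def model_gradient_fn(
    state: ModelState,
    task: str = "disease",
    target_class: int = 0,
    observed: Mapping[str, np.ndarray] | None = None,
) -> Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Closure returning (output values, gradients w.r.t. the input species
    vector) for one output class, suitable for ``integrated_gradients``."""
    Wm = state.params["W"] * state.mask

    def f(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        n = X.shape[0]
        obs = dict(observed or {})
        for t in state.config.metadata_tasks:
            obs.setdefault(t, np.full(n, -1, dtype=np.int64))
        Z = X @ Wm + state.params["b"]
        h = np.maximum(Z, 0.0)
        if task == "disease":
            value, dh = _disease_grad_h(state, h, obs, target_class)
        else:
            value, dh = _metadata_grad_h(state, h, task, target_class)
        dZ = dh * (Z > 0)
        return value, dZ @ Wm.T

    return f


# -- aggregated reports -------------------------------------------------------


def metadata_impact(
    states: Sequence[ModelState],
    enc: EncodedData,
    config: AttributionConfig | None = None,
) -> pd.DataFrame:
    """Impact of each metadata block on disease prediction.

    IG is computed with respect to the fused metadata vectors (the quantity
    the disease decoder actually consumes) along the joint path from the
    baseline's disease-decoder input to each sample's.  Absolute
    attributions are summed within each metadata block, averaged over
    samples, then over disease classes ("overall" row), then over restarts.

    Returns a (n_disease_classes + 1) x n_tasks table.
    """
    config = config or AttributionConfig()
    cfg = states[0].config
    tasks = cfg.metadata_tasks
    n_classes = cfg.n_disease
    X = enc.X
    n, H = X.shape[0], cfg.n_hidden
    observed = {t: enc.observed[t] for t in tasks}
    missing = {t: np.full(n, -1, dtype=np.int64) for t in tasks}

    per_restart = np.zeros((len(states), n_classes, len(tasks)))
    for r, state in enumerate(states):
        bundle = forward(X, state, observed)
        u = np.concatenate([bundle.h] + [bundle.fused[t] for t in tasks], axis=1)
        base_bundle = forward(np.zeros((1, X.shape[1])), state, {t: missing[t][:1] for t in tasks})
        u0 = np.concatenate([base_bundle.h] + [base_bundle.fused[t] for t in tasks], axis=1)
        delta = u - u0
        for c in range(n_classes):
            grad_total = np.zeros_like(u)
            for k in range(config.steps):
                alpha = (k + 0.5) / config.steps
                _, du = _disease_grad_u(state, u0 + alpha * delta, c)
                grad_total += du
            ig = np.abs(delta * grad_total / config.steps)
            offset = H
            for j, task in enumerate(tasks):
                w = cfg.task_width(task)
                per_restart[r, c, j] = ig[:, offset : offset + w].sum(axis=1).mean()
                offset += w
    mean = per_restart.mean(axis=0)
    table = np.vstack([mean, mean.mean(axis=0, keepdims=True)])
    index = [str(c) for c in states[0].vocabs.get("disease", range(n_classes))] + ["overall"]
    return pd.DataFrame(table, index=index, columns=list(tasks))


def node_importance_for_metadata(
    states: Sequence[ModelState],
    enc: EncodedData,
    task: str,
    config: AttributionConfig | None = None,
) -> ImportanceReport:
    """Hidden-node importance for one metadata task via Layer Conductance.

    |conductance| per node, averaged over samples, then over the task's
    classes, then over the restart models.  Nodes are reported with their
    schema names and knowledge groups.
    """
    config = config or AttributionConfig()
    cfg = states[0].config
    n_classes = 2 if task == "gender" else cfg.task_width(task)
    H = cfg.n_hidden
    raw = np.zeros((len(states), n_classes, H))
    for r, state in enumerate(states):
        for c in range(n_classes):
            cond = layer_conductance(
                state, enc.X, task=task, target_class=c, steps=config.steps,
                baseline=config.baseline,
            )
            raw[r, c] = np.abs(cond).mean(axis=0)
    scores = raw.mean(axis=(0, 1))
    names = list(states[0].node_names) or [f"node_{j}" for j in range(H)]
    groups = list(states[0].node_groups) or ["?"] * H
    summary = (
        pd.DataFrame({"entity": names, "group": groups, "score": scores})
        .sort_values("score", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return ImportanceReport(summary=summary, raw=raw, task=task)
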