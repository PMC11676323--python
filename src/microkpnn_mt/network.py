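"""Forward computation of the knowledge-primed multitask network.

Architecture, per sample:

    x (species abundances)
      -> MaskedLinear trunk:  h = relu((W * M)^T x + b)
      -> four metadata decoders (age, gender, BMI, body site): one affine
         map each from h to task logits; softmax for categorical tasks,
         sigmoid for the single gender unit
      -> metadata fusion: the true one-hot label when a metadata value is
         observed, the decoder's probability vector otherwise
      -> disease decoder: affine map + softmax over [h ; fused metadata]

The binary mask M freezes all species -> hidden-node connections that are
not backed by prior knowledge; masked weights are exactly zero before,
during and after training.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ModelConfig",
    "ModelState",
    "PredictionBundle",
    "init_state",
    "masked_linear",
    "decode_metadata",
    "fuse_metadata",
    "decode_disease",
    "forward",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

ALL_TASKS = ("age", "gender", "bmi", "body_site")


@dataclass(frozen=True)
class ModelConfig:
    n_species: int
    n_hidden: int
    n_disease: int
    n_body_site: int = 2
    n_age: int = 6
    n_bmi: int = 4
    metadata_tasks: tuple[str, ...] = ALL_TASKS   # empty tuple -> abundance-only model
    fusion: str = "probabilities"                 # or "hard_one_hot"
    gradient_through_predicted_metadata: bool = True

    def __post_init__(self) -> None:
        for t in self.metadata_tasks:
            if t not in ALL_TASKS:
                raise ValueError(f"unknown metadata task {t!r}")
        if self.fusion not in ("probabilities", "hard_one_hot"):
            raise ValueError(f"unknown fusion mode {self.fusion!r}")
        if self.n_disease < 2:
            raise ValueError("disease task needs at least 2 classes")

    def task_width(self, task: str) -> int:
        return {"age": self.n_age, "gender": 1, "bmi": self.n_bmi, "body_site": self.n_body_site}[task]

    @property
    def fused_width(self) -> int:
        return sum(self.task_width(t) for t in self.metadata_tasks)


@dataclass
class ModelState:
    """All learnable weights plus the frozen mask and label vocabularies."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    mask: np.ndarray                      # (n_species, n_hidden), read-only
    node_names: tuple[str, ...] = ()
    node_groups: tuple[str, ...] = ()
    vocabs: dict[str, list[str]] = field(default_factory=dict)

    def copy(self) -> "ModelState":
        return ModelState(
            config=self.config,
            params={k: v.copy() for k, v in self.params.items()},
            mask=self.mask,
            node_names=self.node_names,
            node_groups=self.node_groups,
            vocabs={k: list(v) for k, v in self.vocabs.items()},
        )

    def apply_mask(self) -> None:
        self.params["W"] *= self.mask


@dataclass
class PredictionBundle:
    """Per-sample outputs plus the intermediates needed for backprop."""

    X: np.ndarray                          # model input (batch, n_species)
    Z: np.ndarray                          # trunk pre-activation
    h: np.ndarray                          # trunk activations (batch, H)
    task_probs: dict[str, np.ndarray]      # decoder probability vectors
    fused: dict[str, np.ndarray]           # vectors fed to the disease decoder
    observed: dict[str, np.ndarray]        # int labels, -1 = missing
    disease_logits: np.ndarray
    disease_probs: np.ndarray              # (batch, n_disease)


def init_state(
    config: ModelConfig,
    mask: np.ndarray,
    rng: np.random.Generator,
    node_names: Sequence[str] = (),
    node_groups: Sequence[str] = (),
    vocabs: Mapping[str, Sequence[str]] | None = None,
) -> ModelState:
    """He-initialise the trunk (masked) and Glorot-initialise the decoders."""
    mask = np.asarray(mask, dtype=np.float64)
    if mask.shape != (config.n_species, config.n_hidden):
        raise ValueError(
            f"mask shape {mask.shape} does not match config "
            f"({config.n_species}, {config.n_hidden})"
        )
    S, H = mask.shape
    params: dict[str, np.ndarray] = {}
    fan_in = np.maximum(mask.sum(axis=0), 1.0)  # per-node effective fan-in
    params["W"] = rng.normal(0.0, 1.0, size=(S, H)) * np.sqrt(2.0 / fan_in) * mask
    params["b"] = np.zeros(H)
    for task in config.metadata_tasks:
        k = config.task_width(task)
        limit = np.sqrt(6.0 / (H + k))
        params[f"A_{task}"] = rng.uniform(-limit, limit, size=(H, k))
        params[f"c_{task}"] = np.zeros(k)
    d_in = H + config.fused_width
    limit = np.sqrt(6.0 / (d_in + config.n_disease))
    params["B"] = rng.uniform(-limit, limit, size=(d_in, config.n_disease))
    params["d"] = np.zeros(config.n_disease)
    mask = mask.copy()
    mask.setflags(write=False)
    return ModelState(
        config=config,
        params=params,
        mask=mask,
        node_names=tuple(node_names),
        node_groups=tuple(node_groups),
        vocabs={k: list(v) for k, v in (vocabs or {}).items()},
    )


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def masked_linear(X: np.ndarray, state: ModelState) -> np.ndarray:
    """Trunk activations h = relu((W * M)^T x + b); masked weights have no effect."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != state.config.n_species:
        raise ValueError(f"expected {state.config.n_species} species, got {X.shape[1]}")
    Z = X @ (state.params["W"] * state.mask) + state.params["b"]
    return np.maximum(Z, 0.0)


def decode_metadata(h: np.ndarray, state: ModelState, task: str) -> np.ndarray:
    """One affine map from the trunk output to task probabilities."""
    if task not in state.config.metadata_tasks:
        raise ValueError(f"unknown or disabled task {task!r}")
    h = np.atleast_2d(h)
    logits = h @ state.params[f"A_{task}"] + state.params[f"c_{task}"]
    if task == "gender":
        return 1.0 / (1.0 + np.exp(-logits))
    return softmax(logits)


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(labels), k))
    valid = labels >= 0
    out[np.nonzero(valid)[0], labels[valid]] = 1.0
    return out


def fuse_metadata(
    predicted: Mapping[str, np.ndarray],
    observed: Mapping[str, np.ndarray],
    config: ModelConfig,
) -> dict[str, np.ndarray]:
    """Per task: the true one-hot (gender: 0/1 scalar) where observed, the
    decoder's probability vector otherwise.  Fusion is per-sample: one
    sample's observedness never affects another's."""
    fused: dict[str, np.ndarray] = {}
    for task in config.metadata_tasks:
        P = np.atleast_2d(predicted[task])
        obs = np.asarray(observed.get(task, np.full(P.shape[0], -1)), dtype=np.int64)
        k = config.task_width(task)
        n_labels = 2 if task == "gender" else k
        if ((obs >= n_labels) | (obs < -1)).any():
            raise ValueError(f"invalid observed label index for task {task!r}")
        if config.fusion == "hard_one_hot":
            if task == "gender":
                P = (P > 0.5).astype(np.float64)
            else:
                P = _one_hot(P.argmax(axis=1), k)
        F = P.copy()
        is_obs = obs >= 0
        if task == "gender":
            F[is_obs, 0] = obs[is_obs].astype(np.float64)
        else:
            F[is_obs] = _one_hot(obs[is_obs], k)
        fused[task] = F
    return fused


def disease_input(h: np.ndarray, fused: Mapping[str, np.ndarray], config: ModelConfig) -> np.ndarray:
    parts = [np.atleast_2d(h)] + [np.atleast_2d(fused[t]) for t in config.metadata_tasks]
    return np.concatenate(parts, axis=1)


def decode_disease(h: np.ndarray, fused: Mapping[str, np.ndarray], state: ModelState) -> np.ndarray:
    u = disease_input(h, fused, state.config)
    logits = u @ state.params["B"] + state.params["d"]
    return softmax(logits)


def forward(
    X: np.ndarray,
    state: ModelState,
    observed: Mapping[str, np.ndarray] | None = None,
) -> PredictionBundle:
    """Full forward pass: trunk -> metadata decoders -> fusion -> disease."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[0]
    observed = dict(observed or {})
    for task in state.config.metadata_tasks:
        observed.setdefault(task, np.full(n, -1, dtype=np.int64))
    Z = X @ (state.params["W"] * state.mask) + state.params["b"]
    h = np.maximum(Z, 0.0)
    task_probs = {t: decode_metadata(h, state, t) for t in state.config.metadata_tasks}
    fused = fuse_metadata(task_probs, observed, state.config)
    u = disease_input(h, fused, state.config)
    logits = u @ state.params["B"] + state.params["d"]
    return PredictionBundle(
        X=X,
        Z=Z,
        h=h,
        task_probs=task_probs,
        fused=fused,
        observed={t: np.asarray(observed[t], dtype=np.int64) for t in state.config.metadata_tasks},
        disease_logits=logits,
        disease_probs=softmax(logits),
    )


def predict(bundle: PredictionBundle) -> dict[str, np.ndarray]:
    """Hard labels per task: argmax (lowest index on ties); gender uses a 0.5
    threshold with ties going to class 0."""
    out = {"disease": bundle.disease_probs.argmax(axis=1)}
    for task, P in bundle.task_probs.items():
        if task == "gender":
            out[task] = (P[:, 0] > 0.5).astype(np.int64)
        else:
            out[task] = P.argmax(axis=1)
    return out


# -- checkpoints --------------------------------------------------------------


def save_checkpoint(state: ModelState, path: str | Path) -> None:
    """Single-file archive: weights + mask (npz) and config/schema/vocabs (json)."""
    meta = {
        "config": asdict(state.config),
        "node_names": list(state.node_names),
        "node_groups": list(state.node_groups),
        "vocabs": state.vocabs,
    }
    buf = io.BytesIO()
    np.savez(buf, mask=state.mask, **state.params)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("arrays.npz", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta))


def load_checkpoint(path: str | Path) -> ModelState:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = np.load(io.BytesIO(zf.read("arrays.npz")))
        params = {k: arrays[k] for k in arrays.files if k != "mask"}
        mask = arrays["mask"]
    cfg = meta["config"]
    cfg["metadata_tasks"] = tuple(cfg["metadata_tasks"])
    config = ModelConfig(**cfg)
    mask.setflags(write=False)
    return ModelState(
        config=config,
        params=params,
        mask=mask,
        node_names=tuple(meta["node_names"]),
        node_groups=tuple(meta["node_groups"]),
        vocabs=meta["vocabs"],
    )
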