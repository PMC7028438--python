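"""Full model assembly, training, evaluation and the lead-count ablation.

The network encodes each lead with a residual convolutional group, runs the
grouped Bi-LSTM (one global + n per-lead recurrences with global-context
access), pools every hidden sequence with its own attention instance, and
feeds the concatenation of all n+1 pooled features into two softmax heads:
a 5-class coarse diagnosis and a 15-class fine diagnosis.  Training
minimizes the λ-interpolated joint objective with per-batch dynamic class
weights under Adam.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from . import autodiff as ad
from .attention import AttentionPooling
from .autodiff import Tensor
from .datasets import ECGRecord, WindowedBatch, make_batches, select_leads
from .encoder import GroupedEncoder, ResGCNNConfig
from .losses import LossConfig, batch_class_weights, joint_loss, weighted_cross_entropy
from .nn import Adam, BatchNorm, Linear, Module
from .recurrent import GroupBiLSTM, RecurrentConfig
from .taxonomy import (
    LEAD_PRESETS,
    STANDARD_LEADS,
    TASK1_CLASSES,
    TASK2_CLASSES,
)

__all__ = ["ModelConfig", "MultiTaskECGModel", "TrainingError", "TaskMetrics",
           "EvalReport", "build_model", "train", "evaluate", "predict",
           "lead_ablation", "split_records", "save_checkpoint", "load_checkpoint"]


class TrainingError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the iteration index."""

    def __init__(self, iteration: int):
        super().__init__(f"non-finite loss at iteration {iteration}")
        self.iteration = iteration


@dataclass(frozen=True)
class ModelConfig:
    lead_names: tuple[str, ...] = STANDARD_LEADS
    l_win: int = 1900
    window_policy: str = "decimate"
    encoder: ResGCNNConfig = field(default_factory=ResGCNNConfig)
    recurrent: RecurrentConfig = field(default_factory=RecurrentConfig)
    n_classes_task1: int = len(TASK1_CLASSES)
    n_classes_task2: int = len(TASK2_CLASSES)
    loss: LossConfig = field(default_factory=LossConfig)
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 10
    seed: int = 0

    def __post_init__(self):
        if len(self.lead_names) < 2:
            raise ValueError("need at least 2 leads")
        if self.n_classes_task1 != len(TASK1_CLASSES) \
                or self.n_classes_task2 != len(TASK2_CLASSES):
            raise ValueError("head sizes must match the 5/15-class taxonomy")

    @property
    def n_leads(self) -> int:
        return len(self.lead_names)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["lead_names"] = tuple(d["lead_names"])
        enc = dict(d["encoder"])
        for key in ("bottleneck_kernels", "dilation_rates", "stride_schedule"):
            enc[key] = tuple(enc[key])
        d["encoder"] = ResGCNNConfig(**enc)
        d["recurrent"] = RecurrentConfig(**d["recurrent"])
        d["loss"] = LossConfig(**d["loss"])
        return cls(**d)


class MultiTaskECGModel(Module):
    """Encoder groups → grouped Bi-LSTM → attention pooling → two heads."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        n = cfg.n_leads
        dh = cfg.recurrent.hidden_size
        self.encoder = GroupedEncoder(cfg.encoder, n, rng)
        self.group = GroupBiLSTM(cfg.encoder.out_channels, n, cfg.recurrent, rng)
        self.attn_global = AttentionPooling(dh, rng)
        self.attn_intra = [AttentionPooling(dh, rng) for _ in range(n)]
        rep = (n + 1) * dh
        self.head1 = Linear(rep, cfg.n_classes_task1, rng)
        self.head2 = Linear(rep, cfg.n_classes_task2, rng)

    @property
    def n_attention_instances(self) -> int:
        return 1 + len(self.attn_intra)

    def forward(self, inputs: np.ndarray | Tensor
                ) -> tuple[Tensor, Tensor, np.ndarray]:
        """Windowed batch [M, n, L] → (probs [M,5], probs [M,15], attention).

        The attention array has shape [M, n+1, T']: the global Bi-LSTM's
        distribution first, then one per lead.
        """
        x = inputs if isinstance(inputs, Tensor) else Tensor(inputs)
        if x.ndim != 3:
            raise ValueError("inputs must be [M, n_leads, L]")
        if x.shape[1] != self.cfg.n_leads:
            raise ValueError(
                f"model expects {self.cfg.n_leads} leads, got {x.shape[1]}")
        feats = self.encoder(x)                       # [M, n, T', D]
        outs = self.group(feats)
        pooled = [self.attn_global(outs.global_forward, outs.global_backward)]
        for i, attn in enumerate(self.attn_intra):
            pooled.append(attn(outs.intra_forward[:, i], outs.intra_backward[:, i]))
        rep = ad.concat([p.pooled for p in pooled], axis=1)
        probs1 = ad.softmax(self.head1(rep), axis=-1)
        probs2 = ad.softmax(self.head2(rep), axis=-1)
        attention = np.stack([p.weights.data for p in pooled], axis=1)
        return probs1, probs2, attention

    __call__ = forward


def build_model(config: ModelConfig) -> MultiTaskECGModel:
    """Deterministically instantiate the model from its configuration."""
    return MultiTaskECGModel(config)


# -- training ------------------------------------------------------------------

def _batch_losses(model: MultiTaskECGModel, batch: WindowedBatch,
                  cfg: ModelConfig) -> tuple[Tensor, Tensor, Tensor]:
    probs1, probs2, _ = model.forward(batch.inputs)
    loss_cfg = cfg.loss
    w1 = w2 = None
    if loss_cfg.dynamic_weights:
        w1 = batch_class_weights(batch.labels1, cfg.n_classes_task1, loss_cfg.xi)
        w2 = batch_class_weights(batch.labels2, cfg.n_classes_task2, loss_cfg.xi)
    l1 = weighted_cross_entropy(probs1, batch.labels1, w1)
    l2 = weighted_cross_entropy(probs2, batch.labels2, w2)
    total = joint_loss(l1, l2, loss_cfg.task_lambda)
    if loss_cfg.l2_lambda > 0:
        reg = Tensor(0.0)
        for w in model.weight_parameters():
            reg = reg + (w ** 2).sum()
        total = total + loss_cfg.l2_lambda * reg
    return total, l1, l2


def train(model: MultiTaskECGModel, records: Sequence[ECGRecord],
          config: ModelConfig | None = None, verbose: bool = False) -> dict:
    """Train in place; returns the per-iteration loss history."""
    if not records:
        raise ValueError("empty training set")
    cfg = config or model.cfg
    model.train()
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history: dict[str, list[float]] = {"joint": [], "task1": [], "task2": []}
    iteration = 0
    for epoch in range(cfg.epochs):
        batches = make_batches(records, cfg.batch_size, l_win=cfg.l_win,
                               policy=cfg.window_policy, shuffle=True,
                               seed=cfg.seed + epoch)
        for batch in batches:
            model.zero_grad()
            total, l1, l2 = _batch_losses(model, batch, cfg)
            if not np.isfinite(total.data):
                raise TrainingError(iteration)
            total.backward()
            opt.step()
            history["joint"].append(total.item())
            history["task1"].append(l1.item())
            history["task2"].append(l2.item())
            iteration += 1
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}  "
                  f"joint={history['joint'][-1]:.4f}")
    model.eval()
    return history


# -- evaluation ----------------------------------------------------------------

@dataclass
class TaskMetrics:
    """Accuracy plus per-class and aggregate precision/recall/F1."""

    class_names: tuple[str, ...]
    accuracy: float
    precision: np.ndarray        # per class
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    defined: np.ndarray          # classes present in truth or prediction
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    confusion: np.ndarray        # counts, rows = truth
    confusion_percent: np.ndarray  # row-normalized percentages

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "per_class": {
                name: {"precision": float(p), "recall": float(r),
                       "f1": float(f), "support": int(s)}
                for name, p, r, f, s in zip(
                    self.class_names, self.precision, self.recall,
                    self.f1, self.support)
            },
        }


@dataclass
class EvalReport:
    task1: TaskMetrics
    task2: TaskMetrics
    record_ids: list[str]

    def to_dict(self) -> dict:
        return {"task1": self.task1.to_dict(), "task2": self.task2.to_dict()}


def _task_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                  class_names: tuple[str, ...]) -> TaskMetrics:
    k = len(class_names)
    labels = np.arange(k)
    conf = _sk_confusion(y_true, y_pred, labels=labels)
    support = conf.sum(axis=1)
    pred_count = conf.sum(axis=0)
    tp = np.diag(conf).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_count > 0, tp / pred_count, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
        percent = np.where(support[:, None] > 0,
                           100.0 * conf / np.maximum(support[:, None], 1), 0.0)
    # classes absent from both truth and prediction have no defined metrics
    # and are excluded from the macro averages
    defined = (support > 0) | (pred_count > 0)
    weights = support / support.sum()
    return TaskMetrics(
        class_names=class_names,
        accuracy=float((y_true == y_pred).mean()),
        precision=precision, recall=recall, f1=f1, support=support,
        defined=defined,
        macro_precision=float(precision[defined].mean()),
        macro_recall=float(recall[defined].mean()),
        macro_f1=float(f1[defined].mean()),
        weighted_precision=float((weights * precision).sum()),
        weighted_recall=float((weights * recall).sum()),
        weighted_f1=float((weights * f1).sum()),
        confusion=conf, confusion_percent=percent)


def predict(model: MultiTaskECGModel, records: Sequence[ECGRecord],
            batch_size: int = 32, return_attention: bool = False):
    """Evaluation-mode predictions → (pred1, pred2[, attention]) arrays."""
    cfg = model.cfg
    model.eval()
    pred1, pred2, attn = [], [], []
    for batch in make_batches(records, batch_size, l_win=cfg.l_win,
                              policy=cfg.window_policy, shuffle=False):
        p1, p2, a = model.forward(batch.inputs)
        pred1.append(p1.data.argmax(axis=1))
        pred2.append(p2.data.argmax(axis=1))
        if return_attention:
            attn.append(a)
    pred1, pred2 = np.concatenate(pred1), np.concatenate(pred2)
    if return_attention:
        return pred1, pred2, np.concatenate(attn)
    return pred1, pred2


def evaluate(model: MultiTaskECGModel, records: Sequence[ECGRecord],
             batch_size: int = 32) -> EvalReport:
    """Compute accuracy/precision/recall/F1 and confusion matrices."""
    if not records:
        raise ValueError("empty evaluation set")
    from .taxonomy import TASK1_INDEX, TASK2_INDEX
    y1 = np.array([TASK1_INDEX[r.labels.task1] for r in records])
    y2 = np.array([TASK2_INDEX[r.labels.task2] for r in records])
    p1, p2 = predict(model, records, batch_size=batch_size)
    return EvalReport(
        task1=_task_metrics(y1, p1, TASK1_CLASSES),
        task2=_task_metrics(y2, p2, TASK2_CLASSES),
        record_ids=[r.record_id for r in records])


# -- splits and the lead ablation ----------------------------------------------

def split_records(records: Sequence[ECGRecord], seed: int = 0,
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
                  ) -> tuple[list[ECGRecord], list[ECGRecord], list[ECGRecord]]:
    """Disjoint train/validation/test split, stratified by fine label."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_class.setdefault(r.labels.task2, []).append(i)
    train_idx, val_idx, test_idx = [], [], []
    for idxs in by_class.values():
        idxs = rng.permutation(idxs)
        n = len(idxs)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        train_idx.extend(idxs[:n_train])
        val_idx.extend(idxs[n_train:n_train + n_val])
        test_idx.extend(idxs[n_train + n_val:])
    pick = lambda ix: [records[i] for i in sorted(ix)]
    return pick(train_idx), pick(val_idx), pick(test_idx)


def lead_ablation(records: Sequence[ECGRecord], presets: Sequence[str] | dict,
                  config: ModelConfig) -> dict[str, EvalReport]:
    """Train and evaluate the same records under different lead subsets.

    ``presets`` is a list of preset names (``"3-lead"``, ``"8-lead"``,
    ``"12-lead"``) or a mapping name → lead tuple.  Splits and seeds are
    identical across presets; only the lead selection differs.
    """
    if isinstance(presets, dict):
        preset_map = {k: tuple(v) for k, v in presets.items()}
    else:
        preset_map = {}
        for name in presets:
            if name not in LEAD_PRESETS:
                raise ValueError(f"unknown preset {name!r}")
            preset_map[name] = LEAD_PRESETS[name]
    reports: dict[str, EvalReport] = {}
    for name, leads in preset_map.items():
        subset = [select_leads(r, leads) for r in records]
        cfg = replace(config, lead_names=tuple(leads))
        tr, va, te = split_records(subset, seed=cfg.seed)
        model = build_model(cfg)
        train(model, tr, cfg)
        reports[name] = evaluate(model, te, batch_size=cfg.batch_size)
    return reports


# -- checkpointing -------------------------------------------------------------

def save_checkpoint(model: MultiTaskECGModel, path: str | Path) -> Path:
    """Single-file archive: parameters, normalization statistics, config."""
    path = Path(path)
    if path.suffix != ".npz":                 # np.savez appends it anyway
        path = path.with_suffix(path.suffix + ".npz")
    arrays = {f"param:{name}": p.data for name, p in model.named_parameters()}
    for i, mod in enumerate(m for m in model.modules() if isinstance(m, BatchNorm)):
        arrays[f"bn:{i}:mean"] = mod.running_mean
        arrays[f"bn:{i}:var"] = mod.running_var
    arrays["config_json"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path: str | Path) -> MultiTaskECGModel:
    with np.load(Path(path)) as archive:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(archive["config_json"]).decode()))
        model = build_model(cfg)
        params = dict(model.named_parameters())
        for key in archive.files:
            if key.startswith("param:"):
                name = key[len("param:"):]
                if name not in params:
                    raise KeyError(f"checkpoint parameter {name!r} not in model")
                params[name].data = archive[key].copy()
        norms = [m for m in model.modules() if isinstance(m, BatchNorm)]
        for i, mod in enumerate(norms):
            mod.running_mean = archive[f"bn:{i}:mean"].copy()
            mod.running_var = archive[f"bn:{i}:var"].copy()
    model.eval()
    return model
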