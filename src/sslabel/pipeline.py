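"""Training, prediction and evaluation orchestration.

``SequenceLabeler`` assembles the full model: fused input features
(PLM embedding rows and/or the learned token + sinusoidal sequence
encoding), the Transformer/CNN/BiLSTM backbone, and either a linear-chain
CRF head (Viterbi decoding, NLL training) or a per-position softmax
(argmax decoding, cross-entropy training) when the CRF is ablated.

Training minimizes the mean per-sequence CRF negative log-likelihood
(or masked cross-entropy) with Adam; every source of randomness — the
validation split, batch order, parameter init, dropout — derives from
``RunConfig.seed``, so a run is exactly reproducible.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax as sp_softmax

from . import crf as crf_mod
from .alphabets import SS3, SS8, LabelAlphabet, get_alphabet
from .autodiff import Tensor, concat
from .backbone import Backbone, BackboneConfig
from .encoding import positional_encoding, residue_indices
from .metrics import dataset_sov, q_accuracy, sov
from .seq_io import LabelSequence, ResidueSequence
from .synthetic import CorpusRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig", "SequenceLabeler", "PredictionRecord", "TrainResult",
    "train", "predict", "evaluate", "save_checkpoint", "load_checkpoint",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    The ablation flags mirror the model's components: at least one input
    feature family must stay on; with ``use_crf`` off, training switches
    to per-position cross-entropy and decoding to argmax.
    """

    task: str = "ss3"               # "ss3" or "ss8"
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    val_fraction: float = 0.1
    grad_clip: float = 5.0
    use_plm: bool = True
    use_seqenc: bool = True
    use_transformer: bool = True
    use_cnn: bool = True
    use_bilstm: bool = True
    use_crf: bool = True
    crf_boundary: bool = True       # learnable start/stop scores
    backbone: BackboneConfig = field(default_factory=BackboneConfig)

    def __post_init__(self) -> None:
        if isinstance(self.backbone, dict):
            self.backbone = BackboneConfig(**self.backbone)
        if not (self.use_plm or self.use_seqenc):
            raise ValueError("at least one of use_plm/use_seqenc must be true")
        K = 3 if self.task == "ss3" else 8 if self.task == "ss8" else None
        if K is None:
            raise ValueError(f"unknown task {self.task!r}")
        if self.backbone.emission_dim != K:
            self.backbone = replace(self.backbone, emission_dim=K)

    @property
    def alphabet(self) -> LabelAlphabet:
        return SS3 if self.task == "ss3" else SS8

    @classmethod
    def desk_scale(cls, task: str = "ss3", **kw) -> "RunConfig":
        """CPU-friendly profile used by the tests and synthetic studies."""
        K = 3 if task == "ss3" else 8
        kw.setdefault("epochs", 30)
        kw.setdefault("backbone", BackboneConfig.desk_scale(emission_dim=K))
        return cls(task=task, **kw)

    @classmethod
    def full_scale(cls, task: str = "ss3", **kw) -> "RunConfig":
        """The published operating point (for full-size runs)."""
        K = 3 if task == "ss3" else 8
        kw.setdefault("epochs", 100)
        kw.setdefault("backbone", BackboneConfig(emission_dim=K))
        return cls(task=task, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


@dataclass(frozen=True)
class PredictionRecord:
    """A decoded prediction for one sequence."""

    id: str
    residues: str
    labels: LabelSequence


class SequenceLabeler:
    """The full model: feature fusion + backbone + CRF/softmax head."""

    def __init__(self, config: RunConfig, plm_dim: Optional[int]):
        self.config = config
        self.alphabet = config.alphabet
        if config.use_plm and not plm_dim:
            raise ValueError("use_plm requires the PLM feature dimension")
        self.plm_dim = int(plm_dim) if config.use_plm else 0
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
        d_in = self.plm_dim
        self.token_table: Optional[Tensor] = None
        if config.use_seqenc:
            self.token_table = Tensor(
                0.1 * rng.standard_normal((21, config.backbone.d_model)),
                requires_grad=True,
            )
            d_in += config.backbone.d_model
        self.backbone = Backbone(
            rng, config.backbone, d_in,
            use_transformer=config.use_transformer,
            use_cnn=config.use_cnn,
            use_bilstm=config.use_bilstm,
        )
        K = config.backbone.emission_dim
        # zero transition init: the chain starts out behaving like a softmax
        self.crf_transitions = Tensor(np.zeros((K, K)), requires_grad=True)
        self.crf_start = Tensor(np.zeros(K), requires_grad=True)
        self.crf_stop = Tensor(np.zeros(K), requires_grad=True)

    # -- parameters --------------------------------------------------------

    def named_parameters(self) -> Dict[str, Tensor]:
        out: Dict[str, Tensor] = {}
        if self.token_table is not None:
            out["token_table"] = self.token_table
        out.update(self.backbone.named_parameters())
        out["crf.transitions"] = self.crf_transitions
        out["crf.start"] = self.crf_start
        out["crf.stop"] = self.crf_stop
        return out

    def trainable_parameters(self) -> List[Tensor]:
        params = []
        if self.token_table is not None:
            params.append(self.token_table)
        params.extend(self.backbone.parameters())
        if self.config.use_crf:
            params.append(self.crf_transitions)
            if self.config.crf_boundary:
                params.extend([self.crf_start, self.crf_stop])
        return params

    def crf_parameters(self) -> crf_mod.CrfParameters:
        return crf_mod.CrfParameters(
            self.crf_transitions.data, self.crf_start.data, self.crf_stop.data
        )

    # -- forward -----------------------------------------------------------

    def _assemble_batch(self, records: Sequence[CorpusRecord]):
        lengths = np.array([len(r.seq) for r in records], dtype=np.intp)
        L = int(lengths.max())
        B = len(records)
        feats = None
        if self.config.use_plm:
            feats = np.zeros((B, L, self.plm_dim))
            for b, r in enumerate(records):
                if r.features is None:
                    raise ValueError(f"record {r.seq.id!r} has no feature matrix")
                if r.features.shape != (lengths[b], self.plm_dim):
                    raise ValueError(
                        f"record {r.seq.id!r}: features {r.features.shape} do not "
                        f"match (L={lengths[b]}, D={self.plm_dim})"
                    )
                feats[b, : lengths[b]] = r.features
        idx = np.zeros((B, L), dtype=np.intp)
        for b, r in enumerate(records):
            idx[b, : lengths[b]] = residue_indices(r.seq)
        return feats, idx, lengths

    def emissions(self, records: Sequence[CorpusRecord], *,
                  training: bool = False, rng=None) -> Tuple[Tensor, np.ndarray]:
        """Emission scores (B, L_max, K) and lengths for a padded batch."""
        feats, idx, lengths = self._assemble_batch(records)
        parts = []
        if self.config.use_plm:
            parts.append(Tensor(feats))
        if self.config.use_seqenc:
            tok = self.token_table[idx]  # (B, L, d_model)
            pe = positional_encoding(idx.shape[1], self.config.backbone.d_model)
            parts.append(tok + pe[None, :, :])
        fused = parts[0] if len(parts) == 1 else concat(parts, axis=-1)
        return self.backbone(fused, lengths, training=training, rng=rng), lengths

    def loss(self, records: Sequence[CorpusRecord], *,
             training: bool = False, rng=None) -> Tuple[Tensor, float]:
        """Batch loss node and per-residue NLL (for logging)."""
        em, lengths = self.emissions(records, training=training, rng=rng)
        L = em.shape[1]
        labels = np.zeros((len(records), L), dtype=np.intp)
        for b, r in enumerate(records):
            labels[b, : lengths[b]] = r.labels.indices()
        if self.config.use_crf:
            node = crf_mod.crf_nll_batch(
                em, self.crf_transitions, self.crf_start, self.crf_stop,
                labels, lengths,
            )
            per_residue = node.item() * len(records) / lengths.sum()
        else:
            node = _masked_cross_entropy(em, labels, lengths)
            per_residue = node.item()
        return node, per_residue

    def decode(self, records: Sequence[CorpusRecord],
               batch_size: int = 16) -> List[PredictionRecord]:
        """Viterbi decoding (argmax of emissions when the CRF is off)."""
        out: List[PredictionRecord] = []
        params = self.crf_parameters()
        for i in range(0, len(records), batch_size):
            chunk = records[i : i + batch_size]
            em, lengths = self.emissions(chunk, training=False)
            for b, r in enumerate(chunk):
                e = em.data[b, : lengths[b]]
                if self.config.use_crf:
                    path, _ = crf_mod.viterbi_decode(e, params)
                else:
                    path = list(np.argmax(e, axis=1))
                labels = "".join(self.alphabet.symbol(int(s)) for s in path)
                out.append(
                    PredictionRecord(
                        id=r.seq.id, residues=r.seq.residues,
                        labels=LabelSequence(self.alphabet, labels),
                    )
                )
        return out

    # -- state -------------------------------------------------------------

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"checkpoint is missing parameters {sorted(missing)}")
        for k, t in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(
                    f"parameter {k!r}: checkpoint shape {arr.shape} vs "
                    f"model {t.data.shape}"
                )
            t.data = arr


def _masked_cross_entropy(emissions: Tensor, labels: np.ndarray,
                          lengths: np.ndarray) -> Tensor:
    """Mean per-residue softmax cross-entropy over real positions."""
    e = emissions.data
    B, L, K = e.shape
    mask = (np.arange(L)[None, :] < lengths[:, None])
    lse = logsumexp(e, axis=-1)
    gold = np.take_along_axis(e, labels[:, :, None], axis=2)[:, :, 0]
    n = mask.sum()
    value = ((lse - gold) * mask).sum() / n

    def vjp(g):
        probs = sp_softmax(e, axis=-1)
        onehot = np.zeros_like(e)
        np.put_along_axis(onehot, labels[:, :, None], 1.0, axis=2)
        return (float(g) * (probs - onehot) * mask[:, :, None] / n,)

    return Tensor(value, _parents=(emissions,), _vjp=vjp)


class Adam:
    """Adam optimizer over tape tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_gradients(params: Sequence[Tensor], max_norm: float) -> None:
    total = np.sqrt(sum((p.grad**2).sum() for p in params if p.grad is not None))
    if total > max_norm > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


@dataclass
class TrainResult:
    model: SequenceLabeler
    history: pd.DataFrame
    best_val_q: float
    best_state: Dict[str, np.ndarray]


def _token_accuracy(model: SequenceLabeler,
                    records: Sequence[CorpusRecord]) -> float:
    preds = model.decode(records)
    total = hits = 0
    for r, p in zip(records, preds):
        total += len(r.labels)
        hits += sum(a == b for a, b in zip(r.labels.labels, p.labels.labels))
    return 100.0 * hits / total if total else float("nan")


def train(
    config: RunConfig,
    train_records: Sequence[CorpusRecord],
    val_records: Optional[Sequence[CorpusRecord]] = None,
) -> TrainResult:
    """Fit the model; fully reproducible from ``config.seed``.

    With no explicit validation corpus, a seeded by-sequence split of
    ``val_fraction`` is held out.  The best-validation-Q parameter state
    is kept alongside the final one.
    """
    if not train_records:
        raise ValueError("empty training corpus")
    if val_records is None:
        rng_split = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        order = rng_split.permutation(len(train_records))
        n_val = max(1, int(round(config.val_fraction * len(train_records))))
        if len(train_records) > 1:
            val_records = [train_records[i] for i in order[:n_val]]
            train_records = [train_records[i] for i in order[n_val:]]
        else:
            val_records = list(train_records)

    plm_dim = None
    if config.use_plm:
        for r in train_records:
            if r.features is None:
                raise ValueError(f"record {r.seq.id!r} has no features but use_plm=true")
        plm_dim = train_records[0].features.shape[1]

    model = SequenceLabeler(config, plm_dim)
    params = model.trainable_parameters()
    if config.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer {config.optimizer!r}")
    opt = Adam(params, lr=config.learning_rate)
    rng_epoch = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))

    rows = []
    best_q, best_state = -np.inf, model.state_dict()
    for epoch in range(config.epochs):
        order = rng_epoch.permutation(len(train_records))
        drop_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 17, epoch])
        )
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = [train_records[i] for i in order[start : start + config.batch_size]]
            opt.zero_grad()
            node, per_res = model.loss(batch, training=True, rng=drop_rng)
            if not np.isfinite(node.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: "
                    f"{node.item()} — lower the learning rate or check inputs"
                )
            node.backward()
            _clip_gradients(params, config.grad_clip)
            opt.step()
            epoch_loss += per_res
            n_batches += 1
        val_q = _token_accuracy(model, val_records)
        rows.append(
            {"epoch": epoch, "train_nll_per_residue": epoch_loss / max(n_batches, 1),
             "val_q": val_q}
        )
        logger.info("epoch %d: train NLL/residue %.4f, val Q %.2f",
                    epoch, rows[-1]["train_nll_per_residue"], val_q)
        if val_q > best_q:
            best_q, best_state = val_q, model.state_dict()

    if config.epochs == 0:
        best_q = _token_accuracy(model, val_records)
        best_state = model.state_dict()
    history = pd.DataFrame(rows)
    return TrainResult(model=model, history=history,
                       best_val_q=float(best_q), best_state=best_state)


def predict(model: SequenceLabeler,
            records: Sequence[CorpusRecord]) -> List[PredictionRecord]:
    """Decode a list of records, preserving order."""
    if not records:
        return []
    return model.decode(records)


def evaluate(
    predictions: Sequence[PredictionRecord],
    truth: Sequence[Tuple[str, LabelSequence]],
    sov_variant: str = "literal",
) -> pd.DataFrame:
    """Per-protein and total Q/Sov report.

    One row per protein (id, L, Q, Sov) plus a TOTAL row: micro-averaged
    Q over all residues and micro/macro Sov.  Ids present on only one
    side are warned about and skipped.
    """
    truth_by_id = dict(truth)
    rows = []
    pairs = []
    for p in predictions:
        if p.id not in truth_by_id:
            logger.warning("no truth labels for id %s; skipping", p.id)
            continue
        t = truth_by_id.pop(p.id)
        rows.append(
            {"id": p.id, "L": len(t), "Q": q_accuracy(t, p.labels),
             "Sov": sov(t, p.labels, variant=sov_variant)}
        )
        pairs.append((t, p.labels))
    for missing in truth_by_id:
        logger.warning("no prediction for id %s; skipping", missing)
    if not pairs:
        raise ValueError("no overlapping ids between predictions and truth")
    total_len = sum(r["L"] for r in rows)
    total_q = sum(r["Q"] * r["L"] for r in rows) / total_len
    micro_sov, macro_sov = dataset_sov(pairs, variant=sov_variant)
    rows.append({"id": "TOTAL", "L": total_len, "Q": total_q, "Sov": micro_sov,
                 "Sov_macro": macro_sov})
    return pd.DataFrame(rows)


# -- checkpoints ------------------------------------------------------------


def save_checkpoint(path: str, model: SequenceLabeler,
                    state: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Serialize parameters + RunConfig (+ alphabet) to an .npz file."""
    meta = {
        "config": model.config.to_dict(),
        "plm_dim": model.plm_dim,
        "alphabet": model.alphabet.name,
    }
    arrays = state if state is not None else model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> SequenceLabeler:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = RunConfig.from_dict(meta["config"])
    model = SequenceLabeler(config, meta["plm_dim"] or None)
    model.load_state_dict(state)
    return model
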