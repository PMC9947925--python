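"""Attention encoder-decoder models for peptide sequence design.

Two model variants share one encoder architecture:

* :class:`SingleDesigner` emits one 6-residue sequence per complex. The
  encoder runs two convolutional blocks — 8 layers over the intermolecular
  distance maps and 4 layers over the intramolecular maps, with embedded
  site sequence/secondary-structure/oligomeric context — and concatenates
  them into a feature tensor F whose second dimension equals the number of
  residues to predict (6). The decoder processes F with forward and reverse
  LSTM passes and decodes six amino-acid distributions with Bahdanau-style
  additive attention over the concatenated hidden states.
* :class:`MultiDesigner` reuses the trained encoder with frozen weights and
  runs its own decoder five times, each pass seeded with the final hidden
  state of the previous pass; the single-output model's prediction is
  appended as the sixth design.

Everything runs on the package's numpy autodiff; all randomness flows from
explicit seeds, so training is bit-reproducible.
"""

from __future__ import annotations

import copy
import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AA_ALPHABET, N_AA, PEPTIDE_LEN, SITE_MAX, aa_index_array
from .featurize import FeatureTensors
from .nn import (Adam, Conv2d, Embedding, Linear, LSTMCell, Module, Tensor,
                 concat, cross_entropy_logits, softmax)


@dataclass
class ModelConfig:
    """Architecture hyperparameters (desk-scale defaults)."""

    feature_depth: int = 128
    conv_channels_a: tuple = (16, 16, 32, 32, 64, 64, 64, 64)
    conv_strides_a: tuple = ((1, 1), (2, 1), (1, 1), (2, 1),
                             (1, 1), (2, 1), (1, 1), (1, 1))
    conv_channels_b: tuple = (16, 16, 32, 32)
    site_embed_dim: int = 16
    token_embed_dim: int = 16
    enc_hidden: int = 64
    dec_hidden: int = 96
    attn_dim: int = 64
    seed: int = 0

    def validate(self) -> None:
        if len(self.conv_channels_a) != 8:
            raise ValueError("block A must have exactly 8 convolutional layers")
        if len(self.conv_channels_b) != 4:
            raise ValueError("block B must have exactly 4 convolutional layers")
        if len(self.conv_strides_a) != len(self.conv_channels_a):
            raise ValueError("one stride per block-A layer required")
        if min(self.feature_depth, self.site_embed_dim, self.token_embed_dim,
               self.enc_hidden, self.dec_hidden, self.attn_dim) <= 0:
            raise ValueError("all model dimensions must be positive")
        h = SITE_MAX
        for sh, _ in self.conv_strides_a:
            h = -(-h // sh)
        if h < 1:
            raise ValueError("block A strides collapse the site axis")


@dataclass
class TrainConfig:
    """Staged optimization schedule (epochs, learning rate) with Adam."""

    stages: tuple = ((5, 1e-3), (5, 1e-4), (2, 2e-5))
    batch_size: int = 8
    seed: int = 0
    loss: str = "min_ce"          # multi-output: "min_ce" or "mse"
    diversity_weight: float = 0.1

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("schedule must contain at least one stage")
        if any(lr <= 0 for _, lr in self.stages):
            raise ValueError("learning rates must be positive")
        if self.loss not in ("min_ce", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")


# Extended schedule used to memorize small planted-mapping datasets.
OVERFIT_STAGES = ((60, 2e-3), (30, 5e-4), (10, 1e-4))


@dataclass
class SequencePrediction:
    probs: np.ndarray       # (6, 20) row-stochastic
    sequence: str           # argmax decode
    attention: np.ndarray   # (6, 6) decode-step x feature-position weights

    def validate(self) -> None:
        assert self.probs.shape == (PEPTIDE_LEN, N_AA)
        assert np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-5)
        decoded = "".join(AA_ALPHABET[i] for i in self.probs.argmax(axis=1))
        assert decoded == self.sequence


@dataclass
class DesignSet:
    """Six designs; the last entry is the single-output model's prediction."""

    designs: list[SequencePrediction]

    def __post_init__(self) -> None:
        if len(self.designs) != 6:
            raise ValueError(f"a design set holds 6 entries, got "
                             f"{len(self.designs)}")

    @property
    def sequences(self) -> list[str]:
        return [d.sequence for d in self.designs]

    @property
    def single_output(self) -> SequencePrediction:
        return self.designs[5]


def stack_batch(tensors: list[FeatureTensors]) -> dict[str, np.ndarray]:
    """Stack per-complex tensors into batched model inputs."""
    return {
        "inter": np.stack([t.inter_maps for t in tensors]).astype(np.float64),
        "site_aa": np.stack([t.site_aa for t in tensors]),
        "site_ss": np.stack([t.site_ss for t in tensors]),
        "intra": np.stack([t.intra_maps for t in tensors]).astype(np.float64),
        "oligo": np.array([t.oligo for t in tensors], dtype=np.float64),
        "site_size": np.array([t.site_size for t in tensors], dtype=np.int64),
    }


class Encoder(Module):
    """Two convolutional blocks -> feature tensor F of shape (B, 6, D)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        convs_a, c_prev = [], 2
        for c_out, stride in zip(cfg.conv_channels_a, cfg.conv_strides_a):
            convs_a.append(Conv2d(c_prev, c_out, rng, stride=tuple(stride)))
            c_prev = c_out
        self.convs_a = convs_a
        convs_b, c_prev = [], 2
        for c_out in cfg.conv_channels_b:
            convs_b.append(Conv2d(c_prev, c_out, rng))
            c_prev = c_out
        self.convs_b = convs_b
        self.emb_aa = Embedding(N_AA + 1, cfg.site_embed_dim, rng)
        self.emb_ss = Embedding(4, cfg.site_embed_dim, rng)
        ctx_dim = 2 * cfg.site_embed_dim + 1
        f_in = cfg.conv_channels_a[-1] + cfg.conv_channels_b[-1] + ctx_dim
        self.proj = Linear(f_in, cfg.feature_depth, rng)

    def __call__(self, batch: dict[str, np.ndarray]) -> Tensor:
        bsz = batch["inter"].shape[0]
        mask = (np.arange(SITE_MAX)[None, :]
                < batch["site_size"][:, None]).astype(np.float64)

        # Block A over intermolecular maps; the input and every layer's
        # activations are masked so predictions depend only on real residues.
        x = Tensor(batch["inter"]) * Tensor(mask[:, :, None, None])
        m = mask
        for conv in self.convs_a:
            x = conv(x).relu()
            m = m[:, ::conv.stride[0]]
            x = x * Tensor(m[:, :, None, None])
        counts = np.maximum(m.sum(axis=1), 1.0)
        feat_a = x.sum(axis=1) * Tensor(1.0 / counts[:, None, None])

        # Block B over intramolecular maps.
        y = Tensor(batch["intra"])
        for conv in self.convs_b:
            y = conv(y).relu()
        feat_b = y.mean(axis=2)

        # Site sequence/secondary-structure context (masked mean) + label.
        n_real = np.maximum(mask.sum(axis=1), 1.0)[:, None]
        ea = (self.emb_aa(batch["site_aa"]) * Tensor(mask[:, :, None])
              ).sum(axis=1) * Tensor(1.0 / n_real)
        es = (self.emb_ss(batch["site_ss"]) * Tensor(mask[:, :, None])
              ).sum(axis=1) * Tensor(1.0 / n_real)
        ctx = concat([ea, es, Tensor(batch["oligo"][:, None])], axis=-1)
        ctx6 = ctx.reshape((bsz, 1, -1)) + Tensor(
            np.zeros((bsz, PEPTIDE_LEN, ctx.shape[-1])))

        f = concat([feat_a, feat_b, ctx6], axis=-1)
        return self.proj(f).relu()


class AttnDecoder(Module):
    """Bidirectional LSTM context + additive-attention LSTM decoder."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        d, h = cfg.feature_depth, cfg.enc_hidden
        self.fwd = LSTMCell(d, h, rng)
        self.bwd = LSTMCell(d, h, rng)
        self.attn_feat = Linear(2 * h, cfg.attn_dim, rng)
        self.attn_state = Linear(cfg.dec_hidden, cfg.attn_dim, rng)
        self.attn_v = Linear(cfg.attn_dim, 1, rng)
        self.tok_emb = Embedding(N_AA + 1, cfg.token_embed_dim, rng)
        self.cell = LSTMCell(cfg.token_embed_dim + 2 * h, cfg.dec_hidden, rng)
        self.out = Linear(cfg.dec_hidden + 2 * h, N_AA, rng)

    def _bilstm(self, f: Tensor) -> Tensor:
        bsz = f.shape[0]
        hf, cf = self.fwd.init_state(bsz)
        hb, cb = self.bwd.init_state(bsz)
        fwd_states: list[Tensor] = []
        bwd_states: list[Tensor] = [None] * PEPTIDE_LEN  # type: ignore
        for t in range(PEPTIDE_LEN):
            hf, cf = self.fwd(f[:, t, :], (hf, cf))
            fwd_states.append(hf)
        for t in reversed(range(PEPTIDE_LEN)):
            hb, cb = self.bwd(f[:, t, :], (hb, cb))
            bwd_states[t] = hb
        rows = [concat([fw, bw], axis=-1).reshape((bsz, 1, -1))
                for fw, bw in zip(fwd_states, bwd_states)]
        return concat(rows, axis=1)  # (B, 6, 2h)

    def decode(self, f: Tensor, targets: np.ndarray | None = None,
               init_state: tuple[Tensor, Tensor] | None = None,
               ) -> tuple[Tensor, np.ndarray, tuple[Tensor, Tensor]]:
        """Run one full 6-step decode.

        ``targets`` (B, 6) of amino-acid indices 1-20 enables teacher
        forcing; otherwise decoding is greedy. ``init_state`` injects the
        final hidden state of a previous pass. Returns stacked logits
        (B, 6, 20), attention weights (B, 6, 6) and the final LSTM state.
        """
        bsz = f.shape[0]
        h_feat = self._bilstm(f)
        keys = self.attn_feat(h_feat)  # (B, 6, A)
        state = init_state if init_state is not None else \
            self.cell.init_state(bsz)
        y_prev = np.zeros(bsz, dtype=np.int64)  # start token = pad index
        logit_rows, attn_rows = [], []
        for _t in range(PEPTIDE_LEN):
            query = self.attn_state(state[0]).reshape((bsz, 1, -1))
            scores = self.attn_v((keys + query).tanh())       # (B, 6, 1)
            alpha = softmax(scores, axis=1)
            context = (alpha * h_feat).sum(axis=1)            # (B, 2h)
            x = concat([self.tok_emb(y_prev), context], axis=-1)
            h, c = self.cell(x, state)
            state = (h, c)
            logits_t = self.out(concat([h, context], axis=-1))
            logit_rows.append(logits_t.reshape((bsz, 1, N_AA)))
            attn_rows.append(alpha.data[:, :, 0])
            if targets is not None:
                y_prev = np.asarray(targets)[:, _t]
            else:
                y_prev = logits_t.data.argmax(axis=-1) + 1
        logits = concat(logit_rows, axis=1)
        attention = np.stack(attn_rows, axis=1)  # (B, 6 steps, 6 positions)
        return logits, attention, state


def _prediction_from_logits(logits: np.ndarray, attention: np.ndarray
                            ) -> SequencePrediction:
    z = logits - logits.max(axis=-1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=-1, keepdims=True)
    seq = "".join(AA_ALPHABET[i] for i in p.argmax(axis=-1))
    return SequencePrediction(probs=p, sequence=seq, attention=attention)


class SingleDesigner(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng)
        self.decoder = AttnDecoder(cfg, rng)

    def encode(self, batch: dict[str, np.ndarray]) -> Tensor:
        return self.encoder(batch)

    def forward(self, batch: dict[str, np.ndarray],
                targets: np.ndarray | None = None):
        f = self.encoder(batch)
        return self.decoder.decode(f, targets=targets)

    def predict(self, ft: FeatureTensors) -> SequencePrediction:
        logits, attention, _ = self.forward(stack_batch([ft]))
        return _prediction_from_logits(logits.data[0], attention[0])

    def predict_batch(self, tensors: list[FeatureTensors]
                      ) -> list[SequencePrediction]:
        logits, attention, _ = self.forward(stack_batch(tensors))
        return [_prediction_from_logits(logits.data[i], attention[i])
                for i in range(len(tensors))]


class MultiDesigner(Module):
    """Six-output variant: frozen encoder copy + its own chained decoder."""

    def __init__(self, single: SingleDesigner, rng: np.random.Generator):
        self.cfg = single.cfg
        self.encoder = copy.deepcopy(single.encoder)
        for _, p in self.encoder.named_parameters():
            p.requires_grad = False  # gradients blocked; weights frozen
        # Warm-start the multi-output decoder from the single-output one.
        self.decoder = copy.deepcopy(single.decoder)
        self.single = single

    def trainable_parameters(self) -> list[Tensor]:
        return self.decoder.parameters()

    def forward_passes(self, batch: dict[str, np.ndarray],
                       targets: np.ndarray | None = None):
        """Five chained decoder passes over the frozen encoder's features."""
        f = self.encoder(batch)
        state = None
        passes = []
        for _k in range(5):
            logits, attention, state = self.decoder.decode(
                f, targets=targets, init_state=state)
            passes.append((logits, attention))
        return passes

    def predict(self, ft: FeatureTensors) -> DesignSet:
        passes = self.forward_passes(stack_batch([ft]))
        designs = [_prediction_from_logits(lg.data[0], at[0])
                   for lg, at in passes]
        designs.append(self.single.predict(ft))
        return DesignSet(designs)


def build_single_designer(cfg: ModelConfig | None = None, seed: int = 0
                          ) -> SingleDesigner:
    cfg = cfg or ModelConfig(seed=seed)
    cfg.validate()
    return SingleDesigner(cfg, np.random.default_rng(cfg.seed if cfg.seed
                                                     else seed))


def build_multi_designer(single: SingleDesigner, seed: int = 0
                         ) -> MultiDesigner:
    if not isinstance(single, SingleDesigner):
        raise TypeError("a trained single-output model is required")
    return MultiDesigner(single, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Training


def _dataset_arrays(dataset: list[tuple[FeatureTensors, str]]):
    tensors = [ft for ft, _ in dataset]
    targets = np.stack([aa_index_array(seq) for _, seq in dataset])  # 1-20
    return stack_batch(tensors), targets


def _batch_slice(batch: dict[str, np.ndarray], idx: np.ndarray):
    return {k: v[idx] for k, v in batch.items()}


def train_single(model: SingleDesigner,
                 dataset: list[tuple[FeatureTensors, str]],
                 tc: TrainConfig) -> list[dict]:
    """Staged Adam training with teacher forcing; returns the loss history."""
    tc.validate()
    if not dataset:
        raise ValueError("empty training dataset")
    batch_all, targets_all = _dataset_arrays(dataset)
    rng = np.random.default_rng(tc.seed)
    opt = Adam(model.parameters(), lr=tc.stages[0][1])
    history: list[dict] = []
    n = len(dataset)
    for stage_i, (epochs, lr) in enumerate(tc.stages):
        opt.lr = lr
        for epoch in range(epochs):
            order = rng.permutation(n)
            total, count = 0.0, 0
            for start in range(0, n, tc.batch_size):
                idx = order[start:start + tc.batch_size]
                batch = _batch_slice(batch_all, idx)
                targets = targets_all[idx]
                logits, _, _ = model.forward(batch, targets=targets)
                loss = cross_entropy_logits(logits, targets - 1).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data) * len(idx)
                count += len(idx)
            history.append({"stage": stage_i, "epoch": epoch, "lr": lr,
                            "loss": total / count})
    return history


def train_multi(model: MultiDesigner,
                dataset: list[tuple[FeatureTensors, str]],
                tc: TrainConfig) -> list[dict]:
    """Train the five-pass decoder; encoder gradients are blocked.

    Default loss: per-sample minimum over the five outputs of the summed
    categorical cross-entropy, plus a pairwise probability-overlap diversity
    penalty. ``tc.loss = "mse"`` switches to mean squared error between
    output probabilities and the one-hot target.
    """
    tc.validate()
    if not dataset:
        raise ValueError("empty training dataset")
    batch_all, targets_all = _dataset_arrays(dataset)
    rng = np.random.default_rng(tc.seed)
    opt = Adam(model.trainable_parameters(), lr=tc.stages[0][1])
    history: list[dict] = []
    n = len(dataset)
    for stage_i, (epochs, lr) in enumerate(tc.stages):
        opt.lr = lr
        for epoch in range(epochs):
            order = rng.permutation(n)
            total, count = 0.0, 0
            for start in range(0, n, tc.batch_size):
                idx = order[start:start + tc.batch_size]
                batch = _batch_slice(batch_all, idx)
                targets = targets_all[idx]
                bsz = len(idx)
                passes = model.forward_passes(batch, targets=targets)
                if tc.loss == "mse":
                    onehot = np.zeros((bsz, PEPTIDE_LEN, N_AA))
                    np.put_along_axis(onehot, (targets - 1)[..., None], 1.0,
                                      axis=-1)
                    terms = [( (softmax(lg, axis=-1) - Tensor(onehot))
                               * (softmax(lg, axis=-1) - Tensor(onehot))
                               ).mean() for lg, _ in passes]
                    loss = terms[0]
                    for t in terms[1:]:
                        loss = loss + t
                    loss = loss * (1.0 / len(terms))
                else:
                    ces = [cross_entropy_logits(lg, targets - 1).sum(
                        axis=1).reshape((bsz, 1)) for lg, _ in passes]
                    ce_mat = concat(ces, axis=1)  # (B, 5)
                    pick = np.zeros_like(ce_mat.data)
                    pick[np.arange(bsz), ce_mat.data.argmin(axis=1)] = 1.0
                    loss = (ce_mat * Tensor(pick)).sum() * (1.0 / bsz)
                    if tc.diversity_weight > 0:
                        probs = [softmax(lg, axis=-1) for lg, _ in passes]
                        overlaps = []
                        for a in range(5):
                            for b in range(a + 1, 5):
                                overlaps.append(
                                    (probs[a] * probs[b]).sum(axis=-1).mean())
                        pen = overlaps[0]
                        for t in overlaps[1:]:
                            pen = pen + t
                        loss = loss + pen * (tc.diversity_weight
                                             / len(overlaps))
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data) * bsz
                count += bsz
            history.append({"stage": stage_i, "epoch": epoch, "lr": lr,
                            "loss": total / count})
    return history


def training_recovery(model: SingleDesigner | MultiDesigner,
                      dataset: list[tuple[FeatureTensors, str]],
                      best_of_n: bool = False) -> float:
    """Mean per-complex sequence recovery of the model on a dataset."""
    from .evaluation import best_of_n_recovery, sequence_recovery

    scores = []
    if isinstance(model, MultiDesigner):
        for ft, target in dataset:
            ds = model.predict(ft)
            if best_of_n:
                scores.append(best_of_n_recovery(target, ds))
            else:
                scores.append(np.mean([sequence_recovery(target, s)
                                       for s in ds.sequences]))
    else:
        preds = model.predict_batch([ft for ft, _ in dataset])
        scores = [sequence_recovery(target, p.sequence)
                  for (_, target), p in zip(dataset, preds)]
    return float(np.mean(scores))


def select_best_model(candidates: list[SingleDesigner],
                      hetero_subsets: list[list[tuple[FeatureTensors, str]]],
                      ) -> SingleDesigner:
    """Candidate with the highest summed recovery over hetero validation
    subsets; ties resolved to the first listed."""
    if not candidates:
        raise ValueError("no candidate models")
    scores = [sum(training_recovery(m, subset) for subset in hetero_subsets)
              for m in candidates]
    return candidates[int(np.argmax(scores))]


# ---------------------------------------------------------------------------
# PSSM export


def export_pssm(pred: SequencePrediction | DesignSet
                ) -> tuple[pd.DataFrame, dict[int, list[list[str]]]]:
    """Per-position amino-acid probability table plus top-k allowed lists.

    For a :class:`DesignSet` the single-output entry (entry 6) supplies the
    probabilities. Top-k lists are provided for k = 3, 5 and 20 (the
    restricted-redesign alphabets); ties break alphabetically.
    """
    if isinstance(pred, DesignSet):
        pred = pred.single_output
    table = pd.DataFrame(pred.probs, columns=list(AA_ALPHABET),
                         index=[f"pos{i + 1}" for i in range(PEPTIDE_LEN)])
    topk: dict[int, list[list[str]]] = {}
    for k in (3, 5, 20):
        rows = []
        for i in range(PEPTIDE_LEN):
            order = sorted(range(N_AA),
                           key=lambda j: (-pred.probs[i, j], AA_ALPHABET[j]))
            rows.append([AA_ALPHABET[j] for j in order[:k]])
        topk[k] = rows
    return table, topk


def write_pssm(pred: SequencePrediction | DesignSet, path: str | Path) -> Path:
    table, _ = export_pssm(pred)
    path = Path(path)
    table.to_csv(path, sep="\t", float_format="%.6f")
    return path


# ---------------------------------------------------------------------------
# Checkpoints


def save_model(model: SingleDesigner | MultiDesigner, path: str | Path) -> Path:
    path = Path(path)
    kind = "multi" if isinstance(model, MultiDesigner) else "single"
    arrays = {f"param::{k}": v for k, v in model.state_dict().items()}
    meta = {"kind": kind, "config": asdict(model.cfg)}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)
    return path


def load_model(path: str | Path) -> SingleDesigner | MultiDesigner:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param::"):]: data[k] for k in data.files
                 if k.startswith("param::")}
    cfg_dict = meta["config"]
    for key in ("conv_channels_a", "conv_channels_b"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg_dict["conv_strides_a"] = tuple(tuple(s)
                                       for s in cfg_dict["conv_strides_a"])
    cfg = ModelConfig(**cfg_dict)
    single = build_single_designer(cfg)
    if meta["kind"] == "single":
        single.load_state_dict(state)
        return single
    model = build_multi_designer(single)
    model.load_state_dict(state)
    for _, p in model.encoder.named_parameters():
        p.requires_grad = False
    return model
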