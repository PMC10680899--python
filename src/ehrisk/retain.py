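"""Interpretable two-level attention recurrent classifier (RETAIN-style).

Each medical code is embedded as a learned vector; the codes of one
encounter are summed into a visit vector.  Two GRU streams run over the
visit sequence in reverse chronological order (most recent visit first, so
recent history dominates the recurrent state): one stream yields a scalar
per visit, softmax-normalized into encounter-level attention ``alpha``; the
other yields a vector per visit, tanh-bounded into variable-level attention
``beta``.  The patient context vector is ``c = sum_i alpha_i (beta_i * v_i)``
and a fully connected softmax head maps it to the class probability.

Because the context is linear in the visit vectors, the positive-class
logit decomposes exactly into per-(encounter, code) contribution scores

    omega(i, k) = alpha_i * w_pos . (beta_i * E[code_k]),

with ``sum omega + b_pos`` equal to the logit — the property that makes the
model's predictions attributable to individual code occurrences.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import _nn
from .masking import MaskedRecord
from .records import PatientRecord

logger = logging.getLogger(__name__)

UNK_TOKEN = "<UNK>"


class CodeDictionary:
    """Bijection between code strings and contiguous integer ids.

    Id 0 is reserved for the unknown token.  Once frozen (as required when
    a pretrained model is finetuned on a new cohort with a shared
    dictionary), unseen codes map to the UNK id instead of growing the
    vocabulary.
    """

    def __init__(self) -> None:
        self._code_to_id: dict[str, int] = {UNK_TOKEN: 0}
        self._id_to_code: list[str] = [UNK_TOKEN]
        self.frozen = False

    def __len__(self) -> int:
        return len(self._id_to_code)

    def add(self, code: str) -> int:
        if code in self._code_to_id:
            return self._code_to_id[code]
        if self.frozen:
            return 0
        idx = len(self._id_to_code)
        self._code_to_id[code] = idx
        self._id_to_code.append(code)
        return idx

    def get(self, code: str) -> int:
        return self._code_to_id.get(code, 0)

    def code(self, idx: int) -> str:
        return self._id_to_code[idx]

    def freeze(self) -> None:
        self.frozen = True

    @classmethod
    def from_codes(cls, codes) -> "CodeDictionary":
        d = cls()
        for c in codes:
            d.add(c)
        return d


@dataclass
class ModelConfig:
    embedding_dim: int = 24
    recurrent_hidden_dim: int = 24
    dropout: float = 0.0  # reserved; 0 keeps training deterministic
    learning_rate: float = 1e-3
    epochs: int = 25
    batch_size: int = 32
    max_sequence_length: int = 128
    class_weight: Optional[str] = None  # None | "balanced"
    val_fraction: float = 0.0
    early_stopping_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.embedding_dim, self.recurrent_hidden_dim,
               self.epochs, self.batch_size, self.max_sequence_length) <= 0:
            raise ValueError("all dims/epochs/batch sizes must be > 0")


@dataclass
class AttentionOutputs:
    """Per-patient attention read-out, indexed in chronological order."""

    alpha: np.ndarray          # (n_enc,), non-negative, sums to 1
    beta: np.ndarray           # (n_enc, embedding_dim), in [-1, 1]
    risk_probability: float    # P(positive)
    positive_logit: float


def demographic_codes(record: PatientRecord, date) -> list[str]:
    """Demographics injected into each encounter's code set."""
    age_decade = (record.age_at(date) // 10) * 10
    sex = "DEMO:SEX_M" if record.sex == "male" else "DEMO:SEX_F"
    return [sex, f"DEMO:AGE_{age_decade}s"]


def featurize_record(
    record: Union[PatientRecord, MaskedRecord],
    dictionary: CodeDictionary,
    max_sequence_length: int = 10**9,
    add: bool = False,
) -> list[list[int]]:
    """Convert a record into chronological visits of code ids.

    Each visit is the encounter's type-prefixed codes plus injected
    demographic codes (age decade at the encounter, sex).  Sequences longer
    than ``max_sequence_length`` keep only the most recent encounters (with
    a warning).  With ``add=True`` unseen codes are added to an unfrozen
    dictionary instead of mapping to UNK.
    """
    rec = record.record if isinstance(record, MaskedRecord) else record
    lookup = dictionary.add if add else dictionary.get
    visits = []
    for enc in rec.encounters:
        codes = [f"{e.code_type}:{e.code}" for e in enc.events]
        codes.extend(demographic_codes(rec, enc.date))
        visits.append([lookup(c) for c in codes])
    if len(visits) > max_sequence_length:
        logger.warning(
            "%s: sequence of %d truncated to the most recent %d encounters",
            rec.patient_id, len(visits), max_sequence_length,
        )
        visits = visits[-max_sequence_length:]
    return visits


def build_dictionary(
    records: Sequence[Union[PatientRecord, MaskedRecord]]
) -> CodeDictionary:
    d = CodeDictionary()
    for rec in records:
        featurize_record(rec, d, add=True)
    return d


def embed_encounter(code_ids: Sequence[int], embedding: np.ndarray) -> np.ndarray:
    """Visit vector: the sum of its code embeddings (order-invariant,
    duplicates count twice)."""
    if len(code_ids) == 0:
        raise ValueError("encounter has no codes")
    return embedding[list(code_ids)].sum(axis=0)


class RetainClassifier:
    """The attention sequence model with a scikit-learn-like surface."""

    def __init__(self, dictionary: CodeDictionary, config: ModelConfig = None):
        self.dictionary = dictionary
        self.config = config or ModelConfig()
        rng = np.random.default_rng(self.config.seed)
        m, p = self.config.embedding_dim, self.config.recurrent_hidden_dim
        V = len(dictionary)
        self.params: dict[str, np.ndarray] = {
            "E": rng.normal(0, 0.1, size=(V, m)),
            "w_a": _nn.glorot(rng, (p, 1)).ravel(),
            "b_a": np.zeros(1),
            "W_b": _nn.glorot(rng, (p, m)),
            "b_b": np.zeros(m),
            "W_o": _nn.glorot(rng, (m, 2)),
            "b_o": np.zeros(2),
        }
        self.params.update(_nn.gru_init(rng, m, p, "gruA."))
        self.params.update(_nn.gru_init(rng, m, p, "gruB."))
        self.training_log: list[dict] = []

    # -- forward machinery ---------------------------------------------------

    def _pack(self, batch: list[list[list[int]]]):
        """Pad a batch of visit sequences, most recent visit first."""
        B = len(batch)
        T = max(len(v) for v in batch)
        mask = np.zeros((T, B))
        pos_t, pos_b, emb_rows = [], [], []
        for b, visits in enumerate(batch):
            for t, ids in enumerate(reversed(visits)):  # reverse chronological
                mask[t, b] = 1.0
                pos_t.extend([t] * len(ids))
                pos_b.extend([b] * len(ids))
                emb_rows.extend(ids)
        return (np.array(pos_t), np.array(pos_b), np.array(emb_rows)), mask

    def _forward(self, batch, compute_cache: bool = True):
        (pos_t, pos_b, emb_rows), mask = self._pack(batch)
        T, B = mask.shape
        m = self.config.embedding_dim
        V = np.zeros((T, B, m))
        np.add.at(V, (pos_t, pos_b), self.params["E"][emb_rows])
        Ha, cache_a = _nn.gru_forward(V, mask, self.params, "gruA.")
        Hb, cache_b = _nn.gru_forward(V, mask, self.params, "gruB.")
        e = Ha @ self.params["w_a"] + self.params["b_a"][0]
        alpha = _nn.masked_softmax(e, mask, axis=0)
        beta = np.tanh(Hb @ self.params["W_b"] + self.params["b_b"])
        ctx = np.einsum("tb,tbm->bm", alpha, beta * V)
        logits = ctx @ self.params["W_o"] + self.params["b_o"]
        fwd = dict(V=V, mask=mask, Ha=Ha, Hb=Hb, alpha=alpha, beta=beta,
                   ctx=ctx, logits=logits, idx=(pos_t, pos_b, emb_rows))
        if compute_cache:
            fwd["cache_a"], fwd["cache_b"] = cache_a, cache_b
        return fwd

    def _loss_and_grads(self, batch, y, sample_weight=None):
        fwd = self._forward(batch)
        loss, dlogits, probs = _nn.softmax_cross_entropy(
            fwd["logits"], y, sample_weight
        )
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["W_o"] = fwd["ctx"].T @ dlogits
        grads["b_o"] = dlogits.sum(axis=0)
        dctx = dlogits @ p["W_o"].T                         # (B, m)
        alpha, beta, V, mask = fwd["alpha"], fwd["beta"], fwd["V"], fwd["mask"]
        dalpha = np.einsum("bm,tbm->tb", dctx, beta * V)
        dbeta = alpha[:, :, None] * V * dctx[None, :, :]
        dV = alpha[:, :, None] * beta * dctx[None, :, :]
        # softmax backward (alpha is 0 at padded steps)
        de = alpha * (dalpha - np.sum(alpha * dalpha, axis=0, keepdims=True))
        dHa = de[:, :, None] * p["w_a"][None, None, :]
        grads["w_a"] = np.einsum("tb,tbp->p", de, fwd["Ha"])
        grads["b_a"] = np.array([de.sum()])
        da_b = dbeta * (1.0 - beta * beta)
        dHb = da_b @ p["W_b"].T
        grads["W_b"] = np.einsum("tbp,tbm->pm", fwd["Hb"], da_b)
        grads["b_b"] = da_b.sum(axis=(0, 1))
        dV_a, g_a = _nn.gru_backward(dHa, fwd["cache_a"], p, "gruA.")
        dV_b, g_b = _nn.gru_backward(dHb, fwd["cache_b"], p, "gruB.")
        grads.update(g_a)
        grads.update(g_b)
        dV_total = dV + dV_a + dV_b
        pos_t, pos_b, emb_rows = fwd["idx"]
        np.add.at(grads["E"], emb_rows, dV_total[pos_t, pos_b])
        return loss, grads, probs

    # -- public API ----------------------------------------------------------

    def fit(
        self,
        records: Sequence[Union[PatientRecord, MaskedRecord]],
        labels: Sequence[int],
    ) -> "RetainClassifier":
        """Train with seeded minibatch Adam; deterministic for a fixed seed."""
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        cfg = self.config
        seqs = [
            featurize_record(r, self.dictionary, cfg.max_sequence_length)
            for r in records
        ]
        weights = np.ones(len(y))
        if cfg.class_weight == "balanced":
            freq = np.bincount(y, minlength=2) / len(y)
            weights = 0.5 / freq[y]
        rng = np.random.default_rng(cfg.seed + 1)
        n = len(seqs)
        idx = rng.permutation(n)
        n_val = int(round(cfg.val_fraction * n))
        val_idx, train_idx = idx[:n_val], idx[n_val:]
        # length-bucketed minibatches: padding cost tracks each bucket's own
        # longest sequence instead of the cohort maximum
        by_len = sorted(train_idx, key=lambda i: (len(seqs[i]), i))
        batches = [
            np.array(by_len[s : s + cfg.batch_size])
            for s in range(0, len(by_len), cfg.batch_size)
        ]
        opt = _nn.Adam(self.params, lr=cfg.learning_rate)
        best_val, best_params, patience = np.inf, None, 0
        self.training_log = []
        for epoch in range(cfg.epochs):
            epoch_loss, n_batches = 0.0, 0
            for b in rng.permutation(len(batches)):
                sel = batches[b]
                loss, grads, _ = self._loss_and_grads(
                    [seqs[i] for i in sel], y[sel], weights[sel]
                )
                opt.step(grads)
                epoch_loss += loss
                n_batches += 1
            entry = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
            if n_val:
                fwd = self._forward([seqs[i] for i in val_idx], compute_cache=False)
                val_loss, _, _ = _nn.softmax_cross_entropy(
                    fwd["logits"], y[val_idx], weights[val_idx]
                )
                entry["val_loss"] = val_loss
                if val_loss < best_val - 1e-6:
                    best_val, patience = val_loss, 0
                    best_params = {k: v.copy() for k, v in self.params.items()}
                else:
                    patience += 1
                    if patience >= cfg.early_stopping_patience:
                        self.training_log.append(entry)
                        break
            self.training_log.append(entry)
        if best_params is not None:
            self.params = best_params
        return self

    def predict_proba(
        self, records: Sequence[Union[PatientRecord, MaskedRecord]]
    ) -> np.ndarray:
        """P(positive) per record, evaluated in batches."""
        out = np.empty(len(records))
        bs = self.config.batch_size
        for s in range(0, len(records), bs):
            chunk = records[s : s + bs]
            seqs = [
                featurize_record(r, self.dictionary, self.config.max_sequence_length)
                for r in chunk
            ]
            fwd = self._forward(seqs, compute_cache=False)
            logits = fwd["logits"]
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            out[s : s + len(chunk)] = (e / e.sum(axis=1, keepdims=True))[:, 1]
        return out

    def forward(
        self, record: Union[PatientRecord, MaskedRecord]
    ) -> AttentionOutputs:
        """Attention read-out for one record, in chronological visit order."""
        seq = featurize_record(record, self.dictionary, self.config.max_sequence_length)
        if not seq:
            raise ValueError("record has no encounters after masking/truncation")
        fwd = self._forward([seq], compute_cache=False)
        n = len(seq)
        alpha = fwd["alpha"][:n, 0][::-1].copy()   # back to chronological order
        beta = fwd["beta"][:n, 0][::-1].copy()
        logits = fwd["logits"][0]
        z = logits - logits.max()
        probs = np.exp(z) / np.exp(z).sum()
        return AttentionOutputs(alpha, beta, float(probs[1]), float(logits[1]))

    def code_contributions(self, record: Union[PatientRecord, MaskedRecord]):
        """Per-(encounter, code) contribution scores to the positive logit.

        Returns a list of :class:`ehrisk.attention.AttentionRecord`; the sum
        of all scores plus the positive-class bias equals the positive
        logit exactly.
        """
        from .attention import AttentionRecord

        rec = record.record if isinstance(record, MaskedRecord) else record
        seq = featurize_record(record, self.dictionary, self.config.max_sequence_length)
        out_att = self.forward(record)
        w_pos = self.params["W_o"][:, 1]
        E = self.params["E"]
        records_out = []
        for i, ids in enumerate(seq):
            scale = out_att.alpha[i] * out_att.beta[i] * w_pos
            for k in ids:
                omega = float(scale @ E[k])
                records_out.append(
                    AttentionRecord(
                        patient_id=rec.patient_id,
                        encounter_index=i,
                        code=self.dictionary.code(k),
                        score=omega,
                    )
                )
        return records_out

    # -- persistence ---------------------------------------------------------

    def clone_with_weights(self) -> "RetainClassifier":
        """Deep copy sharing nothing; used to warm-start finetuning."""
        new = RetainClassifier.__new__(RetainClassifier)
        new.dictionary = self.dictionary
        new.config = copy.deepcopy(self.config)
        new.params = {k: v.copy() for k, v in self.params.items()}
        new.training_log = []
        return new

    def save(self, path) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = {
            "config": self.config.__dict__,
            "codes": self.dictionary._id_to_code,
            "frozen": self.dictionary.frozen,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "RetainClassifier":
        import json
        from pathlib import Path

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        d = CodeDictionary()
        for code in meta["codes"][1:]:
            d.add(code)
        if meta["frozen"]:
            d.freeze()
        model = cls(d, ModelConfig(**meta["config"]))
        with np.load(path.with_suffix(".npz")) as data:
            model.params = {k: data[k] for k in data.files}
        return model
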