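"""SDP-CNN relation classifier.

Architecture: each input channel -- the indicator-augmented sentence and
the left/right shortest-dependency-path subpaths -- is embedded per token
as the concatenation [word, P1 position, P2 position, POS] and convolved
with filter windows of sizes 3/4/5 (100 feature maps each by default,
separate filter banks per channel).  The highest value of every feature
map is max-pooled, pooled features are concatenated, dropout (rate 0.5)
is applied, and a softmax layer produces a distribution over the four
relation labels (or two, after binary relabelling).

The network is implemented directly on numpy arrays with hand-derived
gradients and a seeded Adam optimizer, so training and prediction are
fully deterministic under a fixed seed.  Word vectors may be initialized
from a textual word2vec file and optionally frozen ("static" mode);
position and POS embeddings are always random-initialized and trained.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .evaluation import EvaluationReport, PredictionSet, evaluate
from .sdp import RelationInstance

__all__ = [
    "EmbeddingConfig",
    "ModelConfig",
    "Vocabulary",
    "SDPCNN",
    "init_model",
    "train",
    "predict",
    "relabel_binary",
    "cross_validate",
    "CrossValidationResult",
    "read_word2vec",
]

PAD, UNK = 0, 1
DEFAULT_LABELS = ("ToD", "CoD", "Association", "Negative")


@dataclass(frozen=True)
class EmbeddingConfig:
    """Embedding dimensions; the per-token vector is d = word + 2*pe + pos."""

    word_dim: int = 200
    pe_dim: int = 10
    pos_dim: int = 10
    static: bool = False
    pretrained: "Mapping[str, np.ndarray] | str | Path | None" = None

    @property
    def token_dim(self) -> int:
        return self.word_dim + 2 * self.pe_dim + self.pos_dim

    def __post_init__(self) -> None:
        if min(self.word_dim, self.pe_dim, self.pos_dim) < 1:
            raise ValueError("all embedding dimensions must be >= 1")


@dataclass(frozen=True)
class ModelConfig:
    filter_windows: tuple[int, ...] = (3, 4, 5)
    filters_per_window: int = 100
    dropout: float = 0.5
    labels: tuple[str, ...] = DEFAULT_LABELS
    channels: str = "sentence+sdp"  # sentence_only | sdp_only | sentence+sdp
    seed: int = 0
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    position_clip: int = 30

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if any(w < 1 for w in self.filter_windows):
            raise ValueError("filter windows must be >= 1")
        if self.channels not in ("sentence_only", "sdp_only", "sentence+sdp"):
            raise ValueError(f"unknown channel configuration {self.channels!r}")

    @property
    def channel_names(self) -> tuple[str, ...]:
        if self.channels == "sentence_only":
            return ("sentence",)
        if self.channels == "sdp_only":
            return ("sdp_left", "sdp_right")
        return ("sentence", "sdp_left", "sdp_right")


@dataclass(frozen=True)
class Vocabulary:
    word2id: dict[str, int]
    pos2id: dict[str, int]
    n_positions: int  # 2*clip + 1 real offsets + 1 PAD row

    @classmethod
    def build(
        cls, instances: Sequence[RelationInstance], clip: int
    ) -> "Vocabulary":
        words: set[str] = set()
        tags: set[str] = set()
        for inst in instances:
            words.update(t.lower() for t in inst.tokens)
            words.update(t.lower() for t in inst.left_tokens)
            words.update(t.lower() for t in inst.right_tokens)
            tags.update(inst.pos_tags)
            tags.update(inst.left_pos)
            tags.update(inst.right_pos)
        word2id = {"<pad>": PAD, "<unk>": UNK}
        for w in sorted(words):
            word2id.setdefault(w, len(word2id))
        pos2id = {"<pad>": PAD, "<unk>": UNK}
        for t in sorted(tags):
            pos2id.setdefault(t, len(pos2id))
        return cls(word2id, pos2id, 2 * clip + 2)


def read_word2vec(path: str | Path) -> dict[str, np.ndarray]:
    """Read textual word2vec: header "count dim", then "token v1 .. vd"."""
    vectors: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("word2vec file must start with 'count dim' header")
        dim = int(header[1])
        for line in fh:
            parts = line.rstrip().split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"bad vector line for token {parts[0]!r}")
            vectors[parts[0]] = np.asarray(parts[1:], dtype=np.float64)
    return vectors


class SDPCNN:
    """A trained (or freshly initialized) SDP-CNN model.

    Prediction is a pure function of (instance, parameters); all sampling
    (init, dropout, batch order) flows from the config seed.
    """

    def __init__(
        self,
        mconfig: ModelConfig,
        econfig: EmbeddingConfig,
        vocab: Vocabulary,
        params: dict[str, np.ndarray],
    ):
        self.mconfig = mconfig
        self.econfig = econfig
        self.vocab = vocab
        self.params = params
        self.history: list[float] = []

    @property
    def n_features(self) -> int:
        return (
            len(self.mconfig.channel_names)
            * len(self.mconfig.filter_windows)
            * self.mconfig.filters_per_window
        )

    # -- encoding -----------------------------------------------------------

    def encode(self, inst: RelationInstance) -> dict[str, np.ndarray]:
        """Integer id sequences per channel: (4, length) rows w/p1/p2/pos."""
        w2i, p2i = self.vocab.word2id, self.vocab.pos2id
        out = {}
        streams = {
            "sentence": (inst.tokens, inst.p1_indices, inst.p2_indices, inst.pos_tags),
            "sdp_left": (inst.left_tokens, inst.left_p1, inst.left_p2, inst.left_pos),
            "sdp_right": (inst.right_tokens, inst.right_p1, inst.right_p2, inst.right_pos),
        }
        for name in self.mconfig.channel_names:
            toks, p1, p2, pos = streams[name]
            out[name] = np.array(
                [
                    [w2i.get(t.lower(), UNK) for t in toks],
                    list(p1),
                    list(p2),
                    [p2i.get(t, UNK) for t in pos],
                ],
                dtype=np.int64,
            )
        return out


def init_model(
    mconfig: ModelConfig,
    econfig: EmbeddingConfig,
    vocab: Vocabulary,
    pretrained: Mapping[str, np.ndarray] | None = None,
) -> SDPCNN:
    """Seeded parameter initialization.

    Word rows default to uniform(-0.25, 0.25); rows present in the
    pretrained map are copied instead (a dimension mismatch is an error).
    Position/POS/indicator rows are always random.
    """
    if not vocab.word2id:
        raise ValueError("empty vocabulary")
    rng = np.random.default_rng(mconfig.seed)
    d = econfig.token_dim
    params: dict[str, np.ndarray] = {
        "E_word": rng.uniform(-0.25, 0.25, (len(vocab.word2id), econfig.word_dim)),
        "E_p1": rng.uniform(-0.25, 0.25, (vocab.n_positions, econfig.pe_dim)),
        "E_p2": rng.uniform(-0.25, 0.25, (vocab.n_positions, econfig.pe_dim)),
        "E_pos": rng.uniform(-0.25, 0.25, (len(vocab.pos2id), econfig.pos_dim)),
    }
    if pretrained is None and econfig.pretrained is not None:
        pretrained = (
            econfig.pretrained
            if isinstance(econfig.pretrained, Mapping)
            else read_word2vec(econfig.pretrained)
        )
    if pretrained:
        some = next(iter(pretrained.values()))
        if len(some) != econfig.word_dim:
            raise ValueError(
                f"pretrained dimension {len(some)} != word_dim {econfig.word_dim}"
            )
        for word, idx in vocab.word2id.items():
            vec = pretrained.get(word)
            if vec is not None:
                params["E_word"][idx] = vec
    F = mconfig.filters_per_window
    for c in mconfig.channel_names:
        for h in mconfig.filter_windows:
            scale = np.sqrt(2.0 / (h * d))
            params[f"W_{c}_{h}"] = rng.normal(0.0, scale, (F, h * d))
            params[f"b_{c}_{h}"] = np.zeros(F)
    n_feats = len(mconfig.channel_names) * len(mconfig.filter_windows) * F
    params["W_out"] = rng.normal(0.0, np.sqrt(1.0 / n_feats), (n_feats, len(mconfig.labels)))
    params["b_out"] = np.zeros(len(mconfig.labels))
    return SDPCNN(mconfig, econfig, vocab, params)


# ---------------------------------------------------------------------------
# forward / backward

def _pad_channel(
    encoded: Sequence[dict[str, np.ndarray]], name: str, min_len: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    lengths = np.array([e[name].shape[1] for e in encoded])
    L = max(int(lengths.max(initial=0)), min_len)
    B = len(encoded)
    ids = np.zeros((4, B, L), dtype=np.int64)
    for b, e in enumerate(encoded):
        n = e[name].shape[1]
        ids[:, b, :n] = e[name]
    return ids[0], ids[1], ids[2], ids[3], lengths


def _forward(
    model: SDPCNN,
    encoded: Sequence[dict[str, np.ndarray]],
    train_mode: bool,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    p = model.params
    mc, ec = model.mconfig, model.econfig
    B = len(encoded)
    cache: dict = {"channels": {}}
    feats = []
    max_h = max(mc.filter_windows)
    for name in mc.channel_names:
        w_ids, p1_ids, p2_ids, pos_ids, lengths = _pad_channel(encoded, name, max_h)
        X = np.concatenate(
            [p["E_word"][w_ids], p["E_p1"][p1_ids], p["E_p2"][p2_ids], p["E_pos"][pos_ids]],
            axis=2,
        )
        L = X.shape[1]
        ch_cache = {"ids": (w_ids, p1_ids, p2_ids, pos_ids), "L": L, "windows": {}}
        for h in mc.filter_windows:
            Z = sliding_window_view(X, (h, X.shape[2]), axis=(1, 2)).reshape(
                B, L - h + 1, -1
            )
            C = Z @ p[f"W_{name}_{h}"].T + p[f"b_{name}_{h}"]
            A = np.maximum(C, 0.0)
            n_valid = np.maximum(lengths - h + 1, 1)
            pos_grid = np.arange(L - h + 1)[None, :]
            invalid = pos_grid >= n_valid[:, None]
            A_masked = np.where(invalid[:, :, None], -1.0, A)
            pstar = A_masked.argmax(axis=1)  # (B, F)
            pooled = np.take_along_axis(A_masked, pstar[:, None, :], axis=1)[:, 0, :]
            pooled = np.maximum(pooled, 0.0)  # all-invalid guard; valid pools are >= 0
            ch_cache["windows"][h] = {"Z": Z, "C": C, "pstar": pstar, "pooled": pooled}
            feats.append(pooled)
        cache["channels"][name] = ch_cache
    feat = np.concatenate(feats, axis=1)  # (B, n_feats)
    if train_mode and mc.dropout > 0:
        assert rng is not None
        mask = (rng.random(feat.shape) >= mc.dropout) / (1.0 - mc.dropout)
    else:
        mask = np.ones_like(feat)
    feat_d = feat * mask
    logits = feat_d @ p["W_out"] + p["b_out"]
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    cache.update(feat=feat, mask=mask, feat_d=feat_d, probs=probs)
    return probs, cache


def _backward(model: SDPCNN, cache: dict, y: np.ndarray) -> dict[str, np.ndarray]:
    p = model.params
    mc, ec = model.mconfig, model.econfig
    probs = cache["probs"]
    B = probs.shape[0]
    grads: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in p.items()}
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads["W_out"] = cache["feat_d"].T @ dlogits
    grads["b_out"] = dlogits.sum(axis=0)
    dfeat = (dlogits @ p["W_out"].T) * cache["mask"]

    F = mc.filters_per_window
    dw, pe = ec.word_dim, ec.pe_dim
    col = 0
    for name in mc.channel_names:
        ch = cache["channels"][name]
        w_ids, p1_ids, p2_ids, pos_ids = ch["ids"]
        L = ch["L"]
        d = ec.token_dim
        dX = np.zeros((B, L, d))
        for h in mc.filter_windows:
            win = ch["windows"][h]
            dpooled = dfeat[:, col : col + F]
            col += F
            Csel = np.take_along_axis(win["C"], win["pstar"][:, None, :], axis=1)[:, 0, :]
            dC = dpooled * (Csel > 0)
            Zsel = np.take_along_axis(
                win["Z"], win["pstar"][:, :, None], axis=1
            )  # (B, F, h*d)
            grads[f"W_{name}_{h}"] += np.einsum("bf,bfk->fk", dC, Zsel)
            grads[f"b_{name}_{h}"] += dC.sum(axis=0)
            dZsel = dC[:, :, None] * p[f"W_{name}_{h}"][None, :, :]  # (B, F, h*d)
            rows = win["pstar"][:, :, None] + np.arange(h)[None, None, :]  # (B, F, h)
            b_idx = np.arange(B)[:, None, None]
            np.add.at(dX, (b_idx, rows), dZsel.reshape(B, F, h, d))
        np.add.at(grads["E_word"], w_ids, dX[:, :, :dw])
        np.add.at(grads["E_p1"], p1_ids, dX[:, :, dw : dw + pe])
        np.add.at(grads["E_p2"], p2_ids, dX[:, :, dw + pe : dw + 2 * pe])
        np.add.at(grads["E_pos"], pos_ids, dX[:, :, dw + 2 * pe :])
    if ec.static:
        grads["E_word"][:] = 0.0
    return grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# training / prediction

def _usable(instances: Sequence[RelationInstance]) -> list[RelationInstance]:
    """Instances with an SDP; parse failures are excluded from the model."""
    return [i for i in instances if not i.no_sdp]


def train(
    model: SDPCNN,
    instances: Sequence[RelationInstance],
    epochs: int | None = None,
    batch_size: int | None = None,
    seed: int | None = None,
    validation: Sequence[RelationInstance] | None = None,
    patience: int = 3,
) -> SDPCNN:
    """Minimize cross-entropy with Adam; in place, returns the model.

    The epoch-mean training loss is appended to ``model.history``.  With a
    validation set, training stops once validation loss fails to improve
    for ``patience`` consecutive epochs and the best parameters are kept.
    In static mode the word-embedding matrix is left untouched.
    """
    instances = _usable(instances)
    labels = sorted({i.label for i in instances})
    if len(labels) < 2:
        raise ValueError("training needs at least two classes")
    unknown = set(labels) - set(model.mconfig.labels)
    if unknown:
        raise ValueError(f"labels {unknown} missing from model config")
    epochs = epochs if epochs is not None else model.mconfig.epochs
    batch_size = batch_size if batch_size is not None else model.mconfig.batch_size
    rng = np.random.default_rng(model.mconfig.seed if seed is None else seed)

    label_ids = {l: i for i, l in enumerate(model.mconfig.labels)}
    encoded = [model.encode(i) for i in instances]
    y = np.array([label_ids[i.label] for i in instances])
    val_enc = [model.encode(i) for i in validation] if validation else None
    val_y = (
        np.array([label_ids[i.label] for i in validation]) if validation else None
    )

    opt = _Adam(model.params, model.mconfig.learning_rate)
    best_val = np.inf
    best_params: dict[str, np.ndarray] | None = None
    bad_epochs = 0
    for _ in range(epochs):
        order = rng.permutation(len(encoded))
        losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            batch = [encoded[i] for i in idx]
            probs, cache = _forward(model, batch, train_mode=True, rng=rng)
            yb = y[idx]
            losses.append(float(-np.log(probs[np.arange(len(idx)), yb] + 1e-12).mean()))
            grads = _backward(model, cache, yb)
            opt.step(model.params, grads)
        model.history.append(float(np.mean(losses)))
        if val_enc is not None:
            vp, _ = _forward(model, val_enc, train_mode=False)
            vloss = float(-np.log(vp[np.arange(len(val_y)), val_y] + 1e-12).mean())
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_params = {k: v.copy() for k, v in model.params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= patience:
                    break
    if best_params is not None:
        model.params = best_params
    return model


def predict(
    model: SDPCNN, instances: Sequence[RelationInstance]
) -> tuple[np.ndarray, list[str]]:
    """Evaluation-mode probabilities and argmax labels (ties -> lowest
    label index); deterministic, dropout disabled."""
    encoded = [model.encode(i) for i in instances]
    probs, _ = _forward(model, encoded, train_mode=False)
    labels = [model.mconfig.labels[i] for i in probs.argmax(axis=1)]
    return probs, labels


def relabel_binary(
    instances: Sequence[RelationInstance], positive: set[str] | Sequence[str]
) -> list[RelationInstance]:
    """Map 4-class labels onto {Positive, Negative}; idempotent."""
    positive = set(positive)
    if not positive:
        raise ValueError("positive set must be non-empty")
    allowed = set(DEFAULT_LABELS[:3]) | {"Positive"}
    if not positive <= allowed:
        raise ValueError(f"positive set may only contain {sorted(allowed)}")
    out = []
    for inst in instances:
        if inst.label in ("Positive", "Negative") and inst.label not in positive:
            new = inst.label  # already binary
        else:
            new = "Positive" if inst.label in positive else "Negative"
        out.append(replace_label(inst, new))
    return out


def replace_label(inst: RelationInstance, label: str) -> RelationInstance:
    new = copy.copy(inst)
    new.label = label
    return new


@dataclass
class CrossValidationResult:
    report: EvaluationReport
    fold_micro: list[float]
    predictions: PredictionSet
    fold_assignment: dict[str, int] = field(default_factory=dict)


def cross_validate(
    instances: Sequence[RelationInstance],
    mconfig: ModelConfig,
    econfig: EmbeddingConfig,
    folds: int = 10,
    seed: int | None = None,
) -> CrossValidationResult:
    """Document-grouped k-fold cross-validation.

    Abstracts (not instances) are partitioned into ``folds`` subsets of
    near-equal size (differing by at most one); each fold's instances are
    scored by a model trained from scratch on the remaining folds.  Micro
    and macro scores are computed over the pooled predictions.
    """
    instances = _usable(instances)
    doc_ids = sorted({i.doc_id for i in instances})
    if len(doc_ids) < folds:
        raise ValueError(f"{len(doc_ids)} documents cannot fill {folds} folds")
    rng = np.random.default_rng(mconfig.seed if seed is None else seed)
    order = rng.permutation(len(doc_ids))
    fold_of = {doc_ids[j]: i % folds for i, j in enumerate(order)}

    y_true: list[str] = []
    y_pred: list[str] = []
    ids: list = []
    fold_micro = []
    for fold in range(folds):
        train_insts = [i for i in instances if fold_of[i.doc_id] != fold]
        test_insts = [i for i in instances if fold_of[i.doc_id] == fold]
        if not test_insts:
            continue
        vocab = Vocabulary.build(train_insts, mconfig.position_clip)
        fold_cfg = replace(mconfig, seed=int(mconfig.seed + 1000 * fold + 1))
        model = init_model(fold_cfg, econfig, vocab)
        train(model, train_insts)
        _, pred = predict(model, test_insts)
        y_true.extend(i.label for i in test_insts)
        y_pred.extend(pred)
        ids.extend((i.doc_id, n) for n, i in enumerate(test_insts))
        hits = sum(t == p for t, p in zip((i.label for i in test_insts), pred))
        fold_micro.append(hits / len(test_insts))
    preds = PredictionSet(tuple(ids), tuple(y_true), tuple(y_pred), mconfig.labels)
    return CrossValidationResult(
        report=evaluate(preds),
        fold_micro=fold_micro,
        predictions=preds,
        fold_assignment=fold_of,
    )
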