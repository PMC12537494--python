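"""EUNIS habitat-type classification on top of the sentence encoder.

EUNIS codes are hierarchical: a broad habitat group (level 1) is one
letter — N, Q, R, S, T, U or V — except littoral biogenic habitats, whose
broad code is "MA2"; one further alphanumeric character per level gives the
habitat group (level 2) and habitat type (level 3).  N14 thus belongs to
group N1 and broad group N.  Training and prediction operate at level 3;
group and broad accuracies are obtained by projecting the top-1 prediction
and the truth upward.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from ._nn import Adam, Encoder
from .corpus import Sentence, Vocabulary, encode
from .lm import (EncoderModel, LMConfig, _new_encoder, pad_batch, stable_seed)

__all__ = ["EunisCode", "parse_code", "ClassifierConfig", "HabitatClassifier",
           "Metrics", "fine_tune", "predict_habitat", "evaluate",
           "compute_metrics"]

BROAD_LETTERS = frozenset("NQRSTUV")
_CODE_RE = re.compile(r"^[A-Za-z0-9]+$")


@dataclass(frozen=True)
class EunisCode:
    """A level-3 habitat code with its level-2 and level-1 projections."""

    code: str

    def __post_init__(self) -> None:
        c = self.code
        if not c or not _CODE_RE.match(c):
            raise ValueError(f"malformed EUNIS code {c!r}")
        if c.startswith("MA"):
            if not c.startswith("MA2") or len(c) != 5:
                raise ValueError(f"{c!r}: littoral biogenic codes are MA2 + 2 characters")
        elif c[0] in BROAD_LETTERS:
            if len(c) != 3:
                raise ValueError(f"{c!r}: level-3 codes are broad letter + 2 characters")
        else:
            raise ValueError(f"{c!r}: unknown broad habitat group {c[0]!r}")

    @property
    def broad(self) -> str:
        return "MA2" if self.code.startswith("MA2") else self.code[0]

    @property
    def group(self) -> str:
        return self.code[:len(self.broad) + 1]

    def __str__(self) -> str:
        return self.code


def parse_code(text: str) -> EunisCode:
    """Validate and parse a level-3 EUNIS habitat code."""
    return EunisCode(text.strip())


@dataclass(frozen=True)
class ClassifierConfig(LMConfig):
    """Encoder settings plus the classification head's dropout."""

    head_dropout: float = 0.0


@dataclass
class Metrics:
    """The classification metric set: hierarchical accuracies and per-class
    precision/recall/F1 (macro over classes present in truth, micro over
    plots)."""

    top1: float
    top3: float
    group: float
    broad: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    precision_micro: float
    recall_micro: float
    f1_micro: float
    classes: list[str]
    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]

    @property
    def micro_accuracy(self) -> float:
        return self.top1


class HabitatClassifier:
    """Encoder + pooled-[CLS] softmax head over a closed label set."""

    def __init__(self, encoder: Encoder, vocab: Vocabulary,
                 config: ClassifierConfig, classes: Sequence[str]) -> None:
        if len(classes) < 2:
            raise ValueError("need at least 2 habitat classes")
        self.encoder = encoder
        self.vocab = vocab
        self.config = config
        self.classes = [str(c) for c in classes]
        self.class_to_idx = {c: i for i, c in enumerate(self.classes)}
        self.history: list[float] = []

    # -- inference ------------------------------------------------------------
    def predict_proba(self, sentences: Sequence[Sentence]) -> np.ndarray:
        """(n, n_classes) probabilities, rows summing to 1."""
        for s in sentences:
            if not s.species:
                raise ValueError(f"plot {s.plot_id!r}: empty sentence")
        seqs = [encode(s, self.vocab) for s in sentences]
        probs = np.empty((len(seqs), len(self.classes)), dtype=np.float64)
        order = np.argsort([len(s) for s in seqs], kind="stable")
        for start in range(0, len(order), 64):
            idx = order[start:start + 64]
            ids = pad_batch([seqs[i].ids for i in idx], self.vocab.pad_id)
            probs[idx] = self.encoder.predict_cls_probs(ids, self.vocab.pad_id)
        return probs

    def predict(self, sentences: Sequence[Sentence]) -> list[str]:
        probs = self.predict_proba(sentences)
        return [self.classes[i] for i in probs.argmax(1)]

    def save(self, directory) -> None:
        import json
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        from dataclasses import asdict
        (d / "config.json").write_text(json.dumps(
            {"config": asdict(self.config), "classes": self.classes}))
        (d / "vocab.json").write_text(self.vocab.to_json())
        np.savez(d / "weights.npz", **self.encoder.params)

    @classmethod
    def load(cls, directory) -> "HabitatClassifier":
        import json
        from pathlib import Path
        d = Path(directory)
        meta = json.loads((d / "config.json").read_text())
        config = ClassifierConfig(**meta["config"])
        vocab = Vocabulary.from_json((d / "vocab.json").read_text())
        encoder = _new_encoder(config, vocab, n_classes=len(meta["classes"]))
        with np.load(d / "weights.npz") as data:
            for k in encoder.params:
                encoder.params[k] = data[k]
        return cls(encoder, vocab, config, meta["classes"])


def fine_tune(model: EncoderModel | None, sentences: Sequence[Sentence],
              labels: Sequence[str], config: Optional[ClassifierConfig] = None,
              vocab: Optional[Vocabulary] = None) -> HabitatClassifier:
    """Attach a classification head and train the whole stack.

    ``model`` may be a pretrained sentence encoder (domain-adapted weights
    are copied in) or None to train from random initialization, in which
    case ``vocab`` is required.  Labels must be parseable level-3 EUNIS
    codes; the label set observed here is closed at prediction time.
    Deterministic given ``config.seed``.
    """
    if len(sentences) != len(labels):
        raise ValueError("sentences and labels length mismatch")
    if not sentences:
        raise ValueError("empty training set")
    for lab in labels:
        parse_code(lab)
    classes = sorted(set(str(l) for l in labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 habitat classes in training data")
    if model is not None:
        vocab = model.vocab
        base_cfg = config or ClassifierConfig(**{
            k: getattr(model.config, k) for k in model.config.__dataclass_fields__})
    else:
        if vocab is None:
            raise ValueError("vocab required when training from scratch")
        base_cfg = config or ClassifierConfig()
    rng = np.random.default_rng(base_cfg.seed)
    encoder = _new_encoder(base_cfg, vocab, n_classes=len(classes), rng=rng)
    if model is not None:
        for k, v in model.encoder.params.items():
            encoder.params[k] = v.copy()
    clf = HabitatClassifier(encoder, vocab, base_cfg, classes)

    y = np.array([clf.class_to_idx[str(l)] for l in labels])
    seqs = [encode(s, vocab) for s in sentences]
    opt = Adam(lr=base_cfg.learning_rate)
    drop_rng = (np.random.default_rng(stable_seed(base_cfg.seed, "dropout"))
                if base_cfg.dropout > 0 or base_cfg.head_dropout > 0 else None)
    for epoch in range(base_cfg.epochs):
        opt.lr = base_cfg.epoch_lr(epoch)
        shuffle_rng = np.random.default_rng(
            stable_seed(base_cfg.seed, "cls-shuffle", epoch))
        order = np.argsort([len(s) for s in seqs], kind="stable")
        batches = [order[i:i + base_cfg.batch_size]
                   for i in range(0, len(order), base_cfg.batch_size)]
        shuffle_rng.shuffle(batches)
        losses = []
        for idx in batches:
            ids = pad_batch([seqs[i].ids for i in idx], vocab.pad_id)
            loss, grads = encoder.cls_loss_and_grads(
                ids, y[idx], vocab.pad_id, drop_rng=drop_rng,
                head_dropout=base_cfg.head_dropout)
            opt.step(encoder.params, grads)
            losses.append(loss)
        clf.history.append(float(np.mean(losses)))
    return clf


def predict_habitat(classifier: HabitatClassifier, sentence: Sentence,
                    k: int = 3) -> list[tuple[EunisCode, float]]:
    """Top-k habitat codes with probabilities (full distribution sums to 1)."""
    probs = classifier.predict_proba([sentence])[0]
    order = np.argsort(-probs, kind="stable")[:k]
    return [(parse_code(classifier.classes[i]), float(probs[i])) for i in order]


def compute_metrics(classes: Sequence[str], probs: np.ndarray,
                    labels: Sequence[str]) -> Metrics:
    """Metric set from a class-probability matrix and true level-3 codes.

    Group/broad accuracies project the top-1 prediction and the truth to
    levels 2 and 1, hence top1 <= group <= broad and top1 <= top3 by
    construction.  Macro metrics average over classes present in the truth.
    """
    classes = [str(c) for c in classes]
    truth = [parse_code(str(l)) for l in labels]
    top3_idx = np.argsort(-probs, axis=1, kind="stable")[:, :3]
    pred1 = [parse_code(classes[i]) for i in top3_idx[:, 0]]
    top1 = float(np.mean([p.code == t.code for p, t in zip(pred1, truth)]))
    top3 = float(np.mean([t.code in (classes[i] for i in row)
                          for row, t in zip(top3_idx, truth)]))
    group = float(np.mean([p.group == t.group for p, t in zip(pred1, truth)]))
    broad = float(np.mean([p.broad == t.broad for p, t in zip(pred1, truth)]))

    y_true = [t.code for t in truth]
    y_pred = [p.code for p in pred1]
    present = sorted(set(y_true))
    pm, rm, fm, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average="macro", zero_division=0)
    pu, ru, fu, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average="micro", zero_division=0)
    pc, rc, fc, support = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average=None, zero_division=0)
    all_labels = sorted(set(present) | set(y_pred))
    conf = confusion_matrix(y_true, y_pred, labels=all_labels)
    per_class = {c: {"precision": float(p), "recall": float(r),
                     "f1": float(f), "support": int(s)}
                 for c, p, r, f, s in zip(present, pc, rc, fc, support)}
    return Metrics(top1, top3, group, broad, float(pm), float(rm), float(fm),
                   float(pu), float(ru), float(fu), all_labels, conf, per_class)


def evaluate(classifier: HabitatClassifier, sentences: Sequence[Sentence],
             labels: Sequence[str]) -> Metrics:
    """Score a classifier on labelled test plots (see :func:`compute_metrics`)."""
    probs = classifier.predict_proba(sentences)
    return compute_metrics(classifier.classes, probs, labels)
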