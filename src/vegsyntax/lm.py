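"""Masked-language modelling of species sentences.

Training follows the standard denoising-encoder recipe on abundance-ordered
species sentences: 15% of content tokens are selected per sentence, 80% of
those become [MASK], 10% a random same-category token, 10% stay unchanged,
and the model is trained for five epochs to recover the originals from
bidirectional context.  Cover-tie permutations and mask draws are refreshed
every epoch, seeded from (seed, epoch, plot id) so runs are reproducible.

Evaluation utilities cover fill-mask top-k prediction, perplexity
(exponential of the mean masked-position cross-entropy), open-ended
assemblage completion with the [SEP]-argmax stopping rule, the rank-wise
masking accuracy breakdown (ranks 1..10 on plots with more than ten
species), and species-removal ablations.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

from ._nn import Adam, Encoder, EncoderConfig
from .corpus import (CAT_EPITHET, CAT_GENUS, MASK, SEP, MaskedBatch, Sentence,
                     TokenSequence, Vocabulary, build_sentence, encode,
                     mask_collate)
from .plot_data import PlotTable

__all__ = [
    "LMConfig", "EncoderModel", "Prediction",
    "train_mlm", "predict_topk", "perplexity", "masked_cross_entropy",
    "complete_assemblage", "rank_masking_eval", "RankAccuracy",
    "ablation_eval", "MLMFillMask", "sentences_from_table",
]


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary parts (hash-seed independent)."""
    return zlib.crc32(":".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class LMConfig:
    """Architecture and training settings for the sentence encoder.

    The defaults are a desk-scale model (2 layers, width 64); larger presets
    are a matter of raising ``n_layers``/``d_model``.  ``epochs`` defaults to
    five complete passes.
    """

    n_layers: int = 2
    d_model: int = 64
    n_heads: int = 4
    d_ff: int = 256
    dropout: float = 0.0
    epochs: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    max_len: int = 256
    select_rate: float = 0.15
    mask_frac: float = 0.8
    random_frac: float = 0.1
    sep_mask_prob: float = 0.1
    order_mode: str = "abundance"
    #: per-epoch learning-rate schedule: "constant" (default) or "cosine"
    #: (decay to ~0 over the configured epochs)
    lr_schedule: str = "constant"

    def epoch_lr(self, epoch: int) -> float:
        if self.lr_schedule == "constant" or self.epochs <= 1:
            return self.learning_rate
        if self.lr_schedule != "cosine":
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")
        t = epoch / self.epochs
        return self.learning_rate * 0.5 * (1.0 + np.cos(np.pi * t))

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if min(self.n_layers, self.d_model, self.n_heads, self.d_ff,
               self.batch_size, self.max_len) <= 0:
            raise ValueError("sizes must be positive")


@dataclass(frozen=True)
class Prediction:
    token: str
    probability: float


class EncoderModel:
    """Trained sentence encoder with its vocabulary and config."""

    def __init__(self, encoder: Encoder, vocab: Vocabulary, config: LMConfig,
                 history: Optional[list[float]] = None) -> None:
        self.encoder = encoder
        self.vocab = vocab
        self.config = config
        self.history = history or []

    def logits(self, ids: np.ndarray) -> np.ndarray:
        """Token logits (B, T, V) for a padded id batch."""
        return self.encoder.predict_lm_logits(ids, self.vocab.pad_id)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(json.dumps(asdict(self.config)))
        (d / "vocab.json").write_text(self.vocab.to_json())
        np.savez(d / "weights.npz", **self.encoder.params)

    @classmethod
    def load(cls, directory) -> "EncoderModel":
        d = Path(directory)
        config = LMConfig(**json.loads((d / "config.json").read_text()))
        vocab = Vocabulary.from_json((d / "vocab.json").read_text())
        model = cls(_new_encoder(config, vocab), vocab, config)
        with np.load(d / "weights.npz") as data:
            for k in model.encoder.params:
                model.encoder.params[k] = data[k]
        return model


def _new_encoder(config: LMConfig, vocab: Vocabulary, n_classes: int = 0,
                 rng: Optional[np.random.Generator] = None) -> Encoder:
    ec = EncoderConfig(vocab_size=len(vocab), n_layers=config.n_layers,
                       d_model=config.d_model, n_heads=config.n_heads,
                       d_ff=config.d_ff, max_len=config.max_len,
                       dropout=config.dropout, n_classes=n_classes)
    return Encoder(ec, rng or np.random.default_rng(config.seed))


def sentences_from_table(table: PlotTable, order_mode: str = "abundance",
                         seed: int = 0, epoch: int = 0) -> list[Sentence]:
    """Build one sentence per plot, tie-breaks seeded per (seed, epoch, plot)."""
    out = []
    for pid, grp in table.groupby_plot():
        out.append(build_sentence(pid, grp["taxon_name"].tolist(),
                                  grp["cover_pct"].tolist(), order_mode,
                                  seed=stable_seed(seed, epoch, pid)))
    return out


Corpus = Union[PlotTable, Sequence[Sentence]]


def _epoch_sentences(corpus: Corpus, config: LMConfig, epoch: int) -> list[Sentence]:
    if isinstance(corpus, PlotTable):
        return sentences_from_table(corpus, config.order_mode, config.seed, epoch)
    return list(corpus)


def pad_batch(seqs: Sequence[np.ndarray], pad_id: int) -> np.ndarray:
    T = max(len(s) for s in seqs)
    out = np.full((len(seqs), T), pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, :len(s)] = s
    return out


def _batched_masked(seqs: Sequence[TokenSequence], vocab: Vocabulary,
                    config: LMConfig, epoch: int, shuffle_rng: np.random.Generator):
    """Yield (ids, labels) padded batches with fresh per-sentence corruption."""
    masked = []
    for i, seq in enumerate(seqs):
        rng = np.random.default_rng(stable_seed(config.seed, "mask", epoch, i))
        masked.append(mask_collate(seq, rng, vocab, config.select_rate,
                                   config.mask_frac, config.random_frac,
                                   config.sep_mask_prob))
    order = np.argsort([len(m.ids) for m in masked], kind="stable")
    batches = [order[i:i + config.batch_size]
               for i in range(0, len(order), config.batch_size)]
    shuffle_rng.shuffle(batches)
    for idx in batches:
        ids = pad_batch([masked[i].ids for i in idx], vocab.pad_id)
        labels = pad_batch([masked[i].labels for i in idx], MaskedBatch.IGNORE)
        yield ids, labels


def train_mlm(corpus: Corpus, vocab: Vocabulary, config: LMConfig = LMConfig(),
              ) -> EncoderModel:
    """Train a masked-language encoder from random initialization.

    ``corpus`` is either a curated :class:`PlotTable` (sentences are rebuilt
    each epoch with fresh tie-break permutations) or a fixed sequence of
    :class:`Sentence`.  Deterministic given ``config.seed``.
    """
    first = _epoch_sentences(corpus, config, 0)
    if not first:
        raise ValueError("empty corpus")
    encoder = _new_encoder(config, vocab,
                           rng=np.random.default_rng(config.seed))
    opt = Adam(lr=config.learning_rate)
    model = EncoderModel(encoder, vocab, config)
    drop_rng = (np.random.default_rng(stable_seed(config.seed, "dropout"))
                if config.dropout > 0 else None)
    for epoch in range(config.epochs):
        sentences = first if epoch == 0 else _epoch_sentences(corpus, config, epoch)
        seqs = [encode(s, vocab) for s in sentences]
        shuffle_rng = np.random.default_rng(stable_seed(config.seed, "shuffle", epoch))
        opt.lr = config.epoch_lr(epoch)
        losses = []
        for ids, labels in _batched_masked(seqs, vocab, config, epoch, shuffle_rng):
            loss, grads = encoder.mlm_loss_and_grads(
                ids, labels, vocab.pad_id, drop_rng=drop_rng)
            if grads:
                opt.step(encoder.params, grads)
                losses.append(loss)
        model.history.append(float(np.mean(losses)) if losses else float("nan"))
    return model


# ---------------------------------------------------------------------------
# fill-mask inference
# ---------------------------------------------------------------------------

def _mask_positions(seq: TokenSequence, vocab: Vocabulary) -> np.ndarray:
    return np.nonzero(seq.ids == vocab.mask_id)[0]


def predict_topk(model: EncoderModel, masked_species: Sequence[str], k: int = 5,
                 renormalize: bool = True, content_only: bool = True,
                 exclude_observed: bool = False) -> list[list[Prediction]]:
    """Ranked predictions for each "[MASK]" slot in a species list.

    Probabilities are softmax over the full vocabulary; with ``renormalize``
    the returned top-k list is rescaled to sum to 1 (as in reporting the
    "top five predictions summing to 100%").  ``content_only`` restricts
    candidates to content tokens.  ``exclude_observed`` removes the
    sentence's visible (unmasked) species from the candidates — the same
    candidate policy the co-occurrence baselines use, since a species
    cannot fill a slot in an assemblage that already lists it.
    """
    vocab = model.vocab
    seq = encode(list(masked_species), vocab)
    positions = _mask_positions(seq, vocab)
    if len(positions) == 0:
        raise ValueError("no [MASK] in input")
    banned: set[int] = set()
    if exclude_observed:
        for name in masked_species:
            if MASK not in name and name in vocab.token_to_id:
                banned.add(vocab.token_to_id[name])
    logits = model.logits(seq.ids[None, :])[0]
    out: list[list[Prediction]] = []
    for pos in positions:
        probs = _softmax1(logits[pos])
        cand = vocab.content_ids if content_only else np.arange(len(vocab))
        if banned:
            cand = np.array([i for i in cand if i not in banned])
        order = cand[np.argsort(-probs[cand], kind="stable")][:k]
        p = probs[order]
        if renormalize:
            p = p / p.sum()
        out.append([Prediction(model.vocab.tokens[i], float(pi))
                    for i, pi in zip(order, p)])
    return out


def _softmax1(x: np.ndarray) -> np.ndarray:
    x = x - x.max()
    e = np.exp(x)
    return e / e.sum()


# ---------------------------------------------------------------------------
# perplexity
# ---------------------------------------------------------------------------

def masked_cross_entropy(model, corpus: Sequence[Sentence],
                         rng: np.random.Generator,
                         select_rate: float = 0.15) -> float:
    """Mean cross-entropy at masked positions under the standard collator.

    ``model`` is anything with ``.vocab`` and ``.logits(ids) -> (B, T, V)``.
    Held-out corruption uses pure [MASK] replacement (mask_frac=1) so the
    measured quantity is the canonical fill-mask uncertainty.
    """
    if not corpus:
        raise ValueError("empty corpus")
    vocab = model.vocab
    total, count = 0.0, 0
    for sent in corpus:
        seq = encode(sent, vocab)
        mb = mask_collate(seq, rng, vocab, select_rate, mask_frac=1.0,
                          random_frac=0.0)
        sel = mb.labels != MaskedBatch.IGNORE
        if not sel.any():
            continue
        logits = model.logits(mb.ids[None, :])[0]
        for pos in np.nonzero(sel)[0]:
            row = logits[pos] - logits[pos].max()
            logz = np.log(np.exp(row).sum())
            total += float(logz - row[mb.labels[pos]])
            count += 1
    if count == 0:
        raise ValueError("no positions were masked; corpus too small")
    return total / count


def perplexity(model, corpus: Sequence[Sentence], rng: np.random.Generator,
               select_rate: float = 0.15) -> float:
    """Exponential of the mean masked-position cross-entropy (>= 1)."""
    return float(np.exp(masked_cross_entropy(model, corpus, rng, select_rate)))


# ---------------------------------------------------------------------------
# assemblage completion
# ---------------------------------------------------------------------------

def complete_assemblage(model: EncoderModel, observed: Sequence[str],
                        max_additions: int = 10,
                        sep_threshold: Optional[float] = None,
                        ) -> list[Prediction]:
    """Iteratively append the most probable missing species.

    A [MASK] slot is appended after the observed list (no trailing [SEP],
    matching how end-of-assemblage prediction is trained); the argmax
    species not already present is appended, until [SEP] outranks every
    candidate species (or, if ``sep_threshold`` is set, until P([SEP])
    exceeds it), or ``max_additions`` is reached.
    """
    if not observed:
        raise ValueError("observed species list must be non-empty")
    vocab = model.vocab
    current = [s.lower() for s in observed]
    added: list[Prediction] = []
    for _ in range(max_additions):
        pred = _next_species(model, current)
        if pred is None:
            break
        name, p_name, p_sep = pred
        stop = (p_sep > sep_threshold) if sep_threshold is not None else (p_sep > p_name)
        if stop:
            break
        current.append(name)
        added.append(Prediction(name, p_name))
    return added


def _next_species(model: EncoderModel, current: list[str]):
    """(best new species, its prob, P(sep)) at an appended mask slot."""
    vocab = model.vocab
    present = set(current)
    if vocab.scheme == "species":
        seq = encode(current + [MASK], vocab, append_sep=False)
        probs = _softmax1(model.logits(seq.ids[None, :])[0][-1])
        p_sep = float(probs[vocab.sep_id])
        cand = [i for i in vocab.content_ids if vocab.tokens[i] not in present]
        if not cand:
            return None
        best = max(cand, key=lambda i: probs[i])
        return vocab.tokens[best], float(probs[best]), p_sep
    # term scheme: greedy genus then epithet
    seq = encode(current + [f"{MASK} {MASK}"], vocab, append_sep=False)
    logits = model.logits(seq.ids[None, :])[0]
    gpos, epos = _mask_positions(seq, vocab)[-2:]
    gprobs = _softmax1(logits[gpos])
    p_sep = float(gprobs[vocab.sep_id])
    gids = vocab.category_ids(CAT_GENUS)
    genus = vocab.tokens[int(gids[np.argmax(gprobs[gids])])]
    filled = encode(current + [f"{genus} {MASK}"], vocab, append_sep=False)
    eprobs = _softmax1(model.logits(filled.ids[None, :])[0][-1])
    eids = vocab.category_ids(CAT_EPITHET)
    ranked = eids[np.argsort(-eprobs[eids], kind="stable")]
    for i in ranked:
        name = f"{genus} {vocab.tokens[i]}"
        if name not in present:
            return name, float(gprobs[vocab.token_to_id[genus]] * eprobs[i]), p_sep
    return None


# ---------------------------------------------------------------------------
# rank-wise masking evaluation
# ---------------------------------------------------------------------------

@dataclass
class RankAccuracy:
    """Per-rank top-1 accuracy for ranks 1..10 plus the micro average."""

    per_rank: list[float]
    overall: float
    n_plots: int


class MLMFillMask:
    """Adapter giving the encoder the shared fill-mask predictor interface.

    ``predict(species, index)`` hides the species at ``index`` in the
    abundance-ordered list and returns ranked full-binomial candidates
    (under the term scheme both tokens must be recovered; candidates are
    composed from the top genus/epithet combinations by joint probability).
    """

    def __init__(self, model: EncoderModel, k: int = 10, beam: int = 5) -> None:
        self.model = model
        self.k = k
        self.beam = beam

    def predict(self, species: Sequence[str], index: int) -> list[str]:
        return self.predict_batch([(species, index)])[0]

    def predict_batch(self, queries: Sequence[tuple[Sequence[str], int]],
                      ) -> list[list[str]]:
        vocab = self.model.vocab
        hidden_name = MASK if vocab.scheme == "species" else f"{MASK} {MASK}"
        seqs = []
        for species, index in queries:
            masked = list(species)
            masked[index] = hidden_name
            seqs.append(encode(masked, vocab))
        results: list[list[str]] = []
        order = np.argsort([len(s) for s in seqs], kind="stable")
        out: dict[int, list[str]] = {}
        for start in range(0, len(order), 64):
            idx = order[start:start + 64]
            ids = pad_batch([seqs[i].ids for i in idx], vocab.pad_id)
            logits = self.model.logits(ids)
            for row, i in enumerate(idx):
                positions = _mask_positions(seqs[i], vocab)
                out[i] = self._candidates(logits[row], positions, vocab)
        return [out[i] for i in range(len(seqs))]

    def _candidates(self, logits, positions, vocab) -> list[str]:
        if vocab.scheme == "species":
            probs = _softmax1(logits[positions[0]])
            cand = vocab.content_ids
            top = cand[np.argsort(-probs[cand], kind="stable")][:self.k]
            return [vocab.tokens[i] for i in top]
        gpos, epos = positions[:2]
        gprobs = _softmax1(logits[gpos])
        eprobs = _softmax1(logits[epos])
        gids = vocab.category_ids(CAT_GENUS)
        eids = vocab.category_ids(CAT_EPITHET)
        gtop = gids[np.argsort(-gprobs[gids], kind="stable")][:self.beam]
        etop = eids[np.argsort(-eprobs[eids], kind="stable")][:self.beam]
        combos = sorted(((float(gprobs[g] * eprobs[e]), g, e)
                         for g in gtop for e in etop), reverse=True)
        return [f"{vocab.tokens[g]} {vocab.tokens[e]}"
                for _, g, e in combos[:self.k]]


def rank_masking_eval(predictor, plots: Sequence[Sentence],
                      max_rank: int = 10) -> RankAccuracy:
    """Mask the ten most abundant species one by one and score top-1 recovery.

    Only plots with strictly more than ``max_rank`` species qualify.  The
    predictor is any object with ``predict(species, index) -> ranked list``
    (a batch path ``predict_batch`` is used when available).
    """
    qualifying = [s for s in plots if len(s.species) > max_rank]
    queries = [(s.species, r) for s in qualifying for r in range(max_rank)]
    if hasattr(predictor, "predict_batch"):
        ranked = predictor.predict_batch(queries)
    else:
        ranked = [predictor.predict(sp, r) for sp, r in queries]
    hits = np.zeros(max_rank)
    totals = np.zeros(max_rank)
    for (species, r), cands in zip(queries, ranked):
        totals[r] += 1
        if cands and cands[0] == species[r]:
            hits[r] += 1
    per_rank = [float(h / t) if t else float("nan")
                for h, t in zip(hits, totals)]
    overall = float(hits.sum() / totals.sum()) if totals.sum() else float("nan")
    return RankAccuracy(per_rank, overall, len(qualifying))


# ---------------------------------------------------------------------------
# species-removal ablation
# ---------------------------------------------------------------------------

def ablation_eval(classifier, plots: Sequence[Sentence], labels: Sequence[str],
                  drop: str = "none", seed: int = 0) -> float:
    """Classification accuracy after removing one species per plot.

    ``drop`` is one of none/first/last/random (first = most abundant).
    ``classifier`` is any object with ``predict(sentences) -> list[str]``.
    """
    if drop not in ("none", "first", "last", "random"):
        raise ValueError(f"unknown drop mode {drop!r}")
    rng = np.random.default_rng(seed)
    modified = []
    for sent in plots:
        sp = list(sent.species)
        cov = list(sent.covers) if sent.covers else [0.0] * len(sp)
        if drop != "none":
            if len(sp) < 2:
                raise ValueError("ablation requires plots with >= 2 species")
            pos = {"first": 0, "last": len(sp) - 1}.get(drop)
            if pos is None:
                pos = int(rng.integers(len(sp)))
            del sp[pos], cov[pos]
        modified.append(Sentence(sent.plot_id, tuple(sp), tuple(cov)))
    predictions = classifier.predict(modified)
    return float(np.mean([p == y for p, y in zip(predictions, labels)]))
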