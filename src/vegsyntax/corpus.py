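"""Species sentences, tokenization schemes and the masking collator.

A vegetation plot becomes a "sentence": its species listed in descending
cover-abundance order, lowercase, separated by commas.  Two tokenization
schemes exist:

* ``species`` — one token per full binomial ("hedera helix" is one token);
* ``term``    — two tokens per binomial, genus then epithet.

Sequences carry the usual special tokens ([CLS] ... [SEP]) plus a single
comma token between species groups.  The masking collator implements the
standard denoising recipe: each content token is independently selected
with probability 0.15 and a selected token is replaced by [MASK] 80% of
the time, by a random same-category content token 10% of the time, and
left unchanged 10% of the time.  Commas and special tokens are never
selected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "PAD", "UNK", "CLS", "SEP", "MASK", "COMMA", "SPECIAL_TOKENS",
    "Sentence", "Vocabulary", "TokenSequence", "MaskedBatch",
    "build_sentence", "fit_vocabulary", "encode", "decode", "mask_collate",
    "save_corpus", "load_corpus",
]

PAD = "[PAD]"
UNK = "[UNK]"
CLS = "[CLS]"
SEP = "[SEP]"
MASK = "[MASK]"
COMMA = ","
SPECIAL_TOKENS = (PAD, UNK, CLS, SEP, MASK, COMMA)

# position categories
CAT_CLASSIFY = "classify"
CAT_SEPARATOR = "separator"
CAT_COMMA = "comma"
CAT_GENUS = "genus"
CAT_EPITHET = "epithet"
CAT_SPECIES = "species"
CAT_UNKNOWN = "unknown"
CONTENT_CATEGORIES = frozenset({CAT_GENUS, CAT_EPITHET, CAT_SPECIES, CAT_UNKNOWN})


@dataclass(frozen=True)
class Sentence:
    """Abundance-ordered species list of one plot."""

    plot_id: str
    species: tuple[str, ...]
    covers: Optional[tuple[float, ...]] = None

    def render(self) -> str:
        return ", ".join(self.species)

    def __post_init__(self) -> None:
        if any(s != s.lower() for s in self.species):
            raise ValueError("species names must be lowercase")


def build_sentence(plot_id: str, taxa: Sequence[str], covers: Sequence[float],
                   order_mode: str = "abundance", seed: int = 0) -> Sentence:
    """Order a plot's species into a sentence.

    ``abundance`` sorts by descending cover with a seeded shuffle inside
    tied groups (cover ties are frequent in ordinal-scale data); ``random``
    is a seeded full shuffle.  The species multiset is invariant under mode
    and seed.
    """
    if len(taxa) == 0:
        raise ValueError(f"plot {plot_id!r} has no species")
    if len(taxa) != len(covers):
        raise ValueError("taxa and covers length mismatch")
    taxa = [t.lower() for t in taxa]
    rng = np.random.default_rng(seed)
    jitter = rng.random(len(taxa))
    if order_mode == "abundance":
        order = np.lexsort((jitter, -np.asarray(covers, dtype=float)))
    elif order_mode == "random":
        order = np.argsort(jitter)
    else:
        raise ValueError(f"unknown order_mode {order_mode!r}")
    return Sentence(plot_id,
                    tuple(taxa[i] for i in order),
                    tuple(float(covers[i]) for i in order))


@dataclass
class Vocabulary:
    """Tokenizer state for one scheme plus the special tokens.

    Ids are dense from 0 with specials first; content tokens follow in
    lexicographic order, so identical corpora yield identical vocabularies.
    """

    scheme: str
    tokens: list[str]
    genus_tokens: frozenset = frozenset()
    epithet_tokens: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.scheme not in ("species", "term"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if set(self.tokens[:len(SPECIAL_TOKENS)]) != set(SPECIAL_TOKENS):
            raise ValueError("tokens must start with the special tokens")
        self.token_to_id = {t: i for i, t in enumerate(self.tokens)}
        if len(self.token_to_id) != len(self.tokens):
            raise ValueError("duplicate tokens")

    # -- id helpers -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int: return self.token_to_id[PAD]
    @property
    def unk_id(self) -> int: return self.token_to_id[UNK]
    @property
    def cls_id(self) -> int: return self.token_to_id[CLS]
    @property
    def sep_id(self) -> int: return self.token_to_id[SEP]
    @property
    def mask_id(self) -> int: return self.token_to_id[MASK]
    @property
    def comma_id(self) -> int: return self.token_to_id[COMMA]

    @property
    def content_ids(self) -> np.ndarray:
        return np.arange(len(SPECIAL_TOKENS), len(self.tokens))

    @property
    def n_content(self) -> int:
        return len(self.tokens) - len(SPECIAL_TOKENS)

    def category_ids(self, category: str) -> np.ndarray:
        """Content ids eligible as a random replacement for a category."""
        if self.scheme == "term" and category in (CAT_GENUS, CAT_EPITHET):
            pool = (self.genus_tokens if category == CAT_GENUS
                    else self.epithet_tokens)
            return np.array(sorted(self.token_to_id[t] for t in pool), dtype=int)
        return self.content_ids

    # -- persistence ----------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({"scheme": self.scheme, "tokens": self.tokens,
                           "genus_tokens": sorted(self.genus_tokens),
                           "epithet_tokens": sorted(self.epithet_tokens)})

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        d = json.loads(text)
        return cls(d["scheme"], d["tokens"],
                   frozenset(d["genus_tokens"]), frozenset(d["epithet_tokens"]))


def fit_vocabulary(corpus: Iterable[Sentence], scheme: str) -> Vocabulary:
    """Build the vocabulary for a corpus under one scheme (deterministic)."""
    genera: set[str] = set()
    epithets: set[str] = set()
    binomials: set[str] = set()
    n = 0
    for sent in corpus:
        n += 1
        for name in sent.species:
            binomials.add(name)
            parts = name.split()
            genera.add(parts[0])
            epithets.add(" ".join(parts[1:]) if len(parts) > 1 else parts[0])
    if n == 0:
        raise ValueError("empty corpus")
    if scheme == "species":
        content = sorted(binomials)
        return Vocabulary(scheme, list(SPECIAL_TOKENS) + content)
    content = sorted(genera | epithets)
    return Vocabulary("term", list(SPECIAL_TOKENS) + content,
                      frozenset(genera), frozenset(epithets))


@dataclass
class TokenSequence:
    """Encoded sentence: ids plus a parallel per-position category array."""

    ids: np.ndarray
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if len(self.ids) != len(self.categories):
            raise ValueError("ids/categories length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def content_positions(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.categories)
                         if c in CONTENT_CATEGORIES], dtype=int)


def _species_units(rendered: Sequence[str], scheme: str):
    """Split each species string into its token unit(s) for a scheme."""
    for name in rendered:
        if scheme == "species":
            yield [(name, CAT_SPECIES)]
            continue
        parts = name.split()
        if MASK in parts:
            # partially or fully hidden species: "[MASK] marina", "[MASK] [MASK]"
            yield [(p, CAT_GENUS if j == 0 else CAT_EPITHET)
                   for j, p in enumerate(parts)]
        else:
            units = [(parts[0], CAT_GENUS)]
            if len(parts) > 1:
                units.append((" ".join(parts[1:]), CAT_EPITHET))
            yield units


def encode(sentence: Sentence | Sequence[str], vocab: Vocabulary,
           append_sep: bool = True) -> TokenSequence:
    """Encode a sentence (or bare species list, possibly containing "[MASK]").

    Layout: [CLS] + content/comma interleave + [SEP].  Unseen names map to
    [UNK] with their structural category preserved.  A literal "[MASK]"
    entry becomes the mask token (one token per masked slot; under the term
    scheme a fully hidden species is two "[MASK]" entries).
    """
    species = sentence.species if isinstance(sentence, Sentence) else tuple(sentence)
    ids = [vocab.cls_id]
    cats = [CAT_CLASSIFY]
    first = True
    for units in _species_units(species, vocab.scheme):
        if not first:
            ids.append(vocab.comma_id)
            cats.append(CAT_COMMA)
        first = False
        for tok, cat in units:
            if tok == MASK:
                ids.append(vocab.mask_id)
                cats.append(cat)
            elif tok in vocab.token_to_id:
                ids.append(vocab.token_to_id[tok])
                cats.append(cat)
            else:
                ids.append(vocab.unk_id)
                cats.append(CAT_UNKNOWN)
    if append_sep:
        ids.append(vocab.sep_id)
        cats.append(CAT_SEPARATOR)
    return TokenSequence(np.array(ids), tuple(cats))


def decode(seq: TokenSequence, vocab: Vocabulary) -> str:
    """Inverse of :func:`encode` on in-vocabulary input; [MASK] renders literally."""
    ids = list(seq.ids)
    if vocab.sep_id not in ids:
        raise ValueError("malformed sequence: no [SEP]")
    groups: list[list[str]] = [[]]
    for i, cat in zip(ids, seq.categories):
        if cat == CAT_COMMA:
            groups.append([])
        elif cat in CONTENT_CATEGORIES:
            groups[-1].append(vocab.tokens[i])
    return ", ".join(" ".join(g) for g in groups if g)


def save_corpus(sentences: Iterable[Sentence], path) -> None:
    """One rendered sentence per line, plain text (plot ids are not kept)."""
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            fh.write(sent.render() + "\n")


def load_corpus(path) -> list[Sentence]:
    """Inverse of :func:`save_corpus`; plot ids become line numbers."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if line:
                out.append(Sentence(str(i), tuple(
                    s.strip() for s in line.split(","))))
    return out


@dataclass
class MaskedBatch:
    """Corrupted sequence plus labels (-100 at unselected positions)."""

    ids: np.ndarray
    labels: np.ndarray
    seed: Optional[int] = None

    IGNORE: int = -100


def mask_collate(seq: TokenSequence, rng: np.random.Generator,
                 vocab: Vocabulary, select_rate: float = 0.15,
                 mask_frac: float = 0.8, random_frac: float = 0.1,
                 sep_mask_prob: float = 0.0) -> MaskedBatch:
    """Corrupt one sequence for the masked-token objective.

    Each content token is independently selected with ``select_rate``.  A
    selected token becomes [MASK] with ``mask_frac``, a random content token
    of the same category with ``random_frac`` (genus slots draw genera and
    epithet slots draw epithets under the term scheme), and stays unchanged
    otherwise; the label at selected positions is the original id.  Commas,
    [CLS] and [SEP] are never selected.

    ``sep_mask_prob`` optionally masks the final [SEP] (label [SEP]) on that
    fraction of sentences; this teaches a from-scratch model where
    assemblages end, which the [SEP]-stopped completion rule requires.
    """
    ids = seq.ids.copy()
    labels = np.full(len(ids), MaskedBatch.IGNORE, dtype=np.int64)
    content = seq.content_positions
    if len(content):
        selected = content[rng.random(len(content)) < select_rate]
        for pos in selected:
            labels[pos] = ids[pos]
            u = rng.random()
            if u < mask_frac:
                ids[pos] = vocab.mask_id
            elif u < mask_frac + random_frac:
                pool = vocab.category_ids(seq.categories[pos])
                ids[pos] = int(pool[rng.integers(len(pool))])
            # else: keep the original token (still labelled)
    if sep_mask_prob > 0.0 and rng.random() < sep_mask_prob:
        sep_positions = np.nonzero(seq.ids == vocab.sep_id)[0]
        if len(sep_positions):
            pos = sep_positions[-1]
            labels[pos] = vocab.sep_id
            ids[pos] = vocab.mask_id
    return MaskedBatch(ids, labels)
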