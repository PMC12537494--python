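"""Fill-mask comparison predictors: naive Bayes co-occurrence and an MLP.

The naive Bayes predictor scores a candidate species s against an observed
assemblage O from the presence-absence co-occurrence matrix:

    score(s) = log P(s) + sum_{o in O} log P(o | s)

with P(s) = N_s / sum_t N_t and the additively smoothed conditional
P(o | s) = (C[o, s] + alpha) / (N_s + alpha * V), where C[o, s] counts
plots containing both species, N_s counts plots containing s and V is the
species count.  The multilayer-perceptron baseline is trained on
incomplete assemblages: one random species is hidden per plot per epoch
and the network learns to retrieve it from the remaining presence vector.

Both predictors share the fill-mask interface of
:func:`vegsyntax.lm.rank_masking_eval` (abundance order is ignored; the
observed set is the plot's species minus the masked one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neural_network import MLPClassifier

from .corpus import Sentence

__all__ = ["CooccurrenceMatrix", "NBConfig", "build_cooccurrence",
           "nb_predict", "NaiveBayesFillMask", "MLPFillMaskConfig",
           "mlp_fillmask_train", "mlp_fillmask_predict", "MLPFillMask"]


@dataclass
class CooccurrenceMatrix:
    """Symmetric plot-level pair counts; the diagonal holds N_s."""

    species: list[str]
    counts: np.ndarray      # (V, V) int64, counts[a, a] = N_a
    n_plots: int

    def __post_init__(self) -> None:
        self.index = {s: i for i, s in enumerate(self.species)}

    @property
    def occurrences(self) -> np.ndarray:
        """Per-species plot counts N_s."""
        return np.diagonal(self.counts)

    def save_triplets(self, path) -> None:
        """Persist as a sparse triplet TSV (species_a, species_b, count)."""
        a, b = np.nonzero(np.triu(self.counts))
        df = pd.DataFrame({"species_a": [self.species[i] for i in a],
                           "species_b": [self.species[j] for j in b],
                           "count": self.counts[a, b]})
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def load_triplets(cls, path, n_plots: int) -> "CooccurrenceMatrix":
        df = pd.read_csv(path, sep="\t")
        species = sorted(set(df["species_a"]) | set(df["species_b"]))
        idx = {s: i for i, s in enumerate(species)}
        counts = np.zeros((len(species), len(species)), dtype=np.int64)
        for a, b, c in df.itertuples(index=False):
            counts[idx[a], idx[b]] = c
            counts[idx[b], idx[a]] = c
        return cls(species, counts, n_plots)


def build_cooccurrence(plots: Iterable[Sequence[str] | Sentence],
                       ) -> CooccurrenceMatrix:
    """Count, for every species pair, the plots where both occur.

    Presence-absence semantics: covers and within-plot duplicates are
    ignored.  Accepts species lists or :class:`Sentence` objects.
    """
    sets = [frozenset(p.species if isinstance(p, Sentence) else p)
            for p in plots]
    species = sorted(set().union(*sets)) if sets else []
    idx = {s: i for i, s in enumerate(species)}
    rows, cols = [], []
    for pi, s in enumerate(sets):
        for name in s:
            rows.append(pi)
            cols.append(idx[name])
    X = sparse.csr_matrix((np.ones(len(rows), dtype=np.int64), (rows, cols)),
                          shape=(len(sets), len(species)))
    counts = np.asarray((X.T @ X).todense())
    return CooccurrenceMatrix(species, counts, len(sets))


@dataclass(frozen=True)
class NBConfig:
    alpha: float = 1.0
    exclude_observed: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


def nb_predict(matrix: CooccurrenceMatrix, observed: Sequence[str],
               config: NBConfig = NBConfig(), k: int = 10,
               ) -> list[tuple[str, float]]:
    """Ranked (species, log score) candidates for completing an assemblage.

    Candidates exclude the observed species; ties break lexicographically.
    Observed species unknown to the matrix are ignored with a warning.
    The score is invariant to the order of the observed set.
    """
    if len(observed) == 0:
        raise ValueError("observed species set must be non-empty")
    known, unknown = [], []
    for s in set(observed):
        (known if s in matrix.index else unknown).append(s)
    if unknown:
        warnings.warn(f"ignoring species unknown to the matrix: {sorted(unknown)}")
    V = len(matrix.species)
    N = matrix.occurrences.astype(np.float64)
    alpha = config.alpha
    prior = np.log(N) - np.log(N.sum())           # log P(s)
    score = prior.copy()
    denom = np.log(N + alpha * V)
    # sorted: float accumulation order is then independent of the order
    # (and set-iteration order) of the observed species
    for o in sorted(known):
        C_o = matrix.counts[matrix.index[o]].astype(np.float64)
        score += np.log(C_o + alpha) - denom       # log P(o | s)
    cand = np.ones(V, dtype=bool)
    if config.exclude_observed:
        for s in known:
            cand[matrix.index[s]] = False
    order = sorted(np.nonzero(cand)[0],
                   key=lambda i: (-score[i], matrix.species[i]))
    return [(matrix.species[i], float(score[i])) for i in order[:k]]


class NaiveBayesFillMask:
    """Shared fill-mask predictor interface over :func:`nb_predict`."""

    def __init__(self, matrix: CooccurrenceMatrix,
                 config: NBConfig = NBConfig(), k: int = 10) -> None:
        self.matrix = matrix
        self.config = config
        self.k = k

    def predict(self, species: Sequence[str], index: int) -> list[str]:
        observed = [s for i, s in enumerate(species) if i != index]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranked = nb_predict(self.matrix, observed, self.config, self.k)
        return [s for s, _ in ranked]


@dataclass(frozen=True)
class MLPFillMaskConfig:
    hidden_sizes: tuple[int, ...] = (128,)
    learning_rate: float = 1e-3
    epochs: int = 5
    batch_size: int = 64
    seed: int = 0


class MLPFillMask:
    """MLP retrieving a hidden species from the remaining presence vector."""

    def __init__(self, species: Sequence[str], net: MLPClassifier,
                 config: MLPFillMaskConfig) -> None:
        self.species = list(species)
        self.index = {s: i for i, s in enumerate(self.species)}
        self.net = net
        self.config = config

    def _vector(self, observed: Iterable[str]) -> np.ndarray:
        x = np.zeros(len(self.species), dtype=np.float32)
        for s in observed:
            i = self.index.get(s)
            if i is not None:
                x[i] = 1.0
        return x

    def predict_scores(self, observed: Sequence[str]) -> np.ndarray:
        """Probability over all species; observed species zeroed out."""
        probs = np.zeros(len(self.species))
        if not hasattr(self.net, "coefs_"):  # epochs=0: uninformed predictor
            probs[:] = 1.0 / len(self.species)
        else:
            p = self.net.predict_proba(self._vector(observed)[None, :])[0]
            probs[self.net.classes_] = p
        for s in observed:
            i = self.index.get(s)
            if i is not None:
                probs[i] = 0.0
        return probs

    def predict(self, species: Sequence[str], index: int) -> list[str]:
        observed = [s for i, s in enumerate(species) if i != index]
        ranked = mlp_fillmask_predict(self, observed, k=10)
        return [s for s, _ in ranked]


def mlp_fillmask_train(plots: Sequence[Sequence[str] | Sentence],
                       config: MLPFillMaskConfig = MLPFillMaskConfig(),
                       ) -> MLPFillMask:
    """Train the masked-retrieval MLP (fresh random mask per plot per epoch).

    Plots with a single species cannot be masked and are skipped.
    Deterministic given ``config.seed``.
    """
    sets = [list(dict.fromkeys(p.species if isinstance(p, Sentence) else p))
            for p in plots]
    sets = [s for s in sets if len(s) >= 2]
    if not sets:
        raise ValueError("no trainable plots (need >= 2 species each)")
    species = sorted(set().union(*map(set, sets)))
    idx = {s: i for i, s in enumerate(species)}
    V = len(species)
    net = MLPClassifier(hidden_layer_sizes=config.hidden_sizes,
                        solver="sgd", learning_rate_init=config.learning_rate,
                        batch_size=config.batch_size, max_iter=1,
                        random_state=config.seed, warm_start=False)
    model = MLPFillMask(species, net, config)
    rng = np.random.default_rng(config.seed)
    classes = np.arange(V)
    for epoch in range(config.epochs):
        X = np.zeros((len(sets), V), dtype=np.float32)
        y = np.empty(len(sets), dtype=np.int64)
        for pi, s in enumerate(sets):
            hidden = int(rng.integers(len(s)))
            for j, name in enumerate(s):
                if j != hidden:
                    X[pi, idx[name]] = 1.0
            y[pi] = idx[s[hidden]]
        order = rng.permutation(len(sets))
        net.partial_fit(X[order], y[order], classes=classes)
    return model


def mlp_fillmask_predict(model: MLPFillMask, observed: Sequence[str],
                         k: int = 10) -> list[tuple[str, float]]:
    """Ranked (species, probability) candidates excluding observed species."""
    probs = model.predict_scores(observed)
    order = sorted(range(len(probs)), key=lambda i: (-probs[i], model.species[i]))
    observed_set = set(observed)
    out = [(model.species[i], float(probs[i])) for i in order
           if model.species[i] not in observed_set]
    return out[:k]
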