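"""Seeded generator of vegetation-plot datasets with known habitat structure.

The generator emulates the features of real plot archives that matter for
this pipeline: habitat-specific species pools with a shared generalist
pool, long-tailed species frequencies (a few generalists occur in a large
share of plots), negative-binomial plot richness around a configurable
mean (about 19 species per plot by default), geometric rank-abundance
covers quantized to an ordinal grid (creating the frequent cover ties of
ordinal field scales), and spatial clustering of habitats around
per-habitat centres.  Every draw flows from one seed, so a dataset can be
regenerated byte-identically and the generating truth (plot -> habitat,
habitat -> pool) is available as an oracle for recovery tests.

A motif constraint can be injected to create the diagnostic co-occurrence
pattern in which two species never occur together without a third.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .plot_data import PlotHeader, PlotTable

__all__ = ["MotifSpec", "HabitatSpec", "CommunityModel", "make_model",
           "sample_plots", "inject_motif", "truth_tables", "species_name",
           "make_motif_model"]

_SYLLABLES = ("ba", "ce", "da", "fe", "gi", "lo", "ma", "ni", "pe", "ra",
              "su", "ti", "vo", "xa", "ze", "mu")
_GENUS_SUFFIX = ("us", "a", "um", "ia", "ix")
_EPITHET_SUFFIX = ("ensis", "alis", "atum", "osa", "ii")


def species_name(genus_idx: int, epithet_idx: int) -> str:
    """Deterministic pronounceable lowercase binomial for index pairs."""

    def syllabify(i: int, n: int) -> str:
        parts = []
        for _ in range(n):
            parts.append(_SYLLABLES[i % len(_SYLLABLES)])
            i //= len(_SYLLABLES)
        return "".join(parts)

    genus = syllabify(genus_idx, 2) + _GENUS_SUFFIX[genus_idx % len(_GENUS_SUFFIX)]
    epithet = (syllabify(epithet_idx * 7 + 3, 2)
               + _EPITHET_SUFFIX[epithet_idx % len(_EPITHET_SUFFIX)])
    return f"{genus} {epithet}"


@dataclass(frozen=True)
class MotifSpec:
    """Species triple: a and c may never occur together without b."""

    a: str
    b: str
    c: str

    def __post_init__(self) -> None:
        if len({self.a, self.b, self.c}) != 3:
            raise ValueError("motif species must be distinct")


@dataclass(frozen=True)
class HabitatSpec:
    code: str                      # EUNIS-like level-3 label
    pool: tuple[str, ...]
    occ_weight: tuple[float, ...]  # relative occurrence weights, > 0
    centre: tuple[float, float]    # (lon, lat) degrees
    dispersion: float              # spatial std dev, degrees
    dominant: Optional[str] = None  # always present with the top cover


@dataclass(frozen=True)
class CommunityModel:
    habitats: tuple[HabitatSpec, ...]
    generalists: tuple[str, ...]
    generalist_weight: tuple[float, ...]
    geometric_ratio: float = 0.75
    richness_mean: float = 19.0
    richness_shape: float = 6.0    # negative-binomial overdispersion
    cover_grid: tuple[float, ...] = (0.5, 3.0, 8.0, 18.0, 38.0, 63.0, 88.0)
    motif: Optional[MotifSpec] = None

    def __post_init__(self) -> None:
        if not self.habitats:
            raise ValueError("need at least one habitat")
        if not 0.0 < self.geometric_ratio < 1.0:
            raise ValueError("geometric_ratio must be in (0, 1)")
        for h in self.habitats:
            if not h.pool:
                raise ValueError(f"habitat {h.code}: empty pool")
            if any(w <= 0 for w in h.occ_weight):
                raise ValueError(f"habitat {h.code}: weights must be > 0")

    @property
    def all_species(self) -> list[str]:
        out: set[str] = set(self.generalists)
        for h in self.habitats:
            out.update(h.pool)
        return sorted(out)


_BROADS = ("R", "T", "S", "Q", "N", "U", "V", "MA2")


def _habitat_code(i: int) -> str:
    broad = _BROADS[i % len(_BROADS)]
    j = i // len(_BROADS)
    return f"{broad}{1 + j % 9}{1 + (j // 9) % 9}"


def make_model(n_habitats: int = 4, pool_size: int = 50,
               n_generalists: int = 0, geometric_ratio: float = 0.75,
               seed: int = 0, generalist_weight: float = 1.0,
               richness_mean: float = 19.0, dispersion: float = 0.25,
               dominant_marker: bool = False,
               shared_pool: bool = False) -> CommunityModel:
    """Build a community model with disjoint habitat pools.

    Habitat pools overlap only through the shared generalists.  Per-species
    occurrence weights are drawn log-uniform in [0.2, 0.9] (long-tailed
    frequencies); generalists all get ``generalist_weight``, so heavy
    weighting concentrates occurrences on a few species.  With
    ``dominant_marker`` each habitat gets a dedicated species that is
    always present with the highest cover; combined with ``shared_pool``
    (one common subdominant pool for every habitat) habitat identity is
    carried *solely* by the dominant species.
    """
    if min(n_habitats, pool_size) <= 0 or n_generalists < 0:
        raise ValueError("sizes must be positive")
    if shared_pool and not dominant_marker:
        raise ValueError("shared_pool requires dominant_marker")
    rng = np.random.default_rng(seed)
    habitats = []
    next_species = 0

    def take(n: int) -> list[str]:
        nonlocal next_species
        names = [species_name(next_species + i, next_species + i)
                 for i in range(n)]
        next_species += n
        return names

    common = take(pool_size) if shared_pool else None
    common_w = (np.exp(rng.uniform(np.log(0.2), np.log(0.9), pool_size))
                if shared_pool else None)
    for i in range(n_habitats):
        if shared_pool:
            pool = take(1) + common          # dedicated dominant + shared rest
            weights = np.concatenate(([1.0], common_w))
            dominant = pool[0]
        else:
            pool = take(pool_size)
            weights = np.exp(rng.uniform(np.log(0.2), np.log(0.9), pool_size))
            dominant = None
            if dominant_marker:
                dominant = pool[0]
                weights[0] = 1.0
        centre = (float(-6.0 + 3.5 * i + rng.normal(0, 0.2)),
                  float(42.0 + 2.0 * (i % 3) + rng.normal(0, 0.2)))
        habitats.append(HabitatSpec(_habitat_code(i), tuple(pool),
                                    tuple(weights), centre, dispersion,
                                    dominant))
    generalists = tuple(take(n_generalists))
    gw = tuple([float(generalist_weight)] * n_generalists)
    return CommunityModel(tuple(habitats), generalists, gw,
                          geometric_ratio=geometric_ratio,
                          richness_mean=richness_mean)


def inject_motif(model: CommunityModel, motif: Optional[MotifSpec],
                 ) -> CommunityModel:
    """Enforce (or with None, remove) the a/c-never-without-b constraint."""
    if motif is not None:
        known = set(model.all_species)
        missing = {motif.a, motif.b, motif.c} - known
        if missing:
            raise ValueError(f"motif species not in model: {sorted(missing)}")
    return replace(model, motif=motif)


def _quantize(cover: np.ndarray, grid: Sequence[float]) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    return g[np.argmin(np.abs(cover[:, None] - g[None, :]), axis=1)]


def sample_plots(model: CommunityModel, n_plots: int, seed: int = 0,
                 ) -> tuple[PlotTable, list[PlotHeader]]:
    """Draw plots: habitat, richness, species, covers and coordinates.

    Species are drawn without replacement with probability proportional to
    their occurrence weight (Gumbel top-k).  Covers follow a geometric
    rank-abundance series quantized to the ordinal grid, which produces
    ties; the habitat's dominant (if any) takes the top rank.  Coordinates
    scatter around the habitat centre.  Fully reproducible by seed.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    headers: list[PlotHeader] = []
    warned = False
    m, shape = model.richness_mean, model.richness_shape
    for i in range(n_plots):
        h = model.habitats[int(rng.integers(len(model.habitats)))]
        pool = list(h.pool) + list(model.generalists)
        weights = np.array(list(h.occ_weight) + list(model.generalist_weight))
        richness = 1 + int(rng.negative_binomial(
            shape, shape / (shape + max(m - 1.0, 0.01))))
        if richness > len(pool):
            if not warned:
                warnings.warn("plot richness exceeds pool size; truncating")
                warned = True
            richness = len(pool)
        keys = np.log(weights) + rng.gumbel(size=len(pool))
        if h.dominant is not None:
            keys[pool.index(h.dominant)] = np.inf
        chosen = np.argsort(-keys, kind="stable")[:richness]
        species = [pool[j] for j in chosen]
        if model.motif is not None:
            mo = model.motif
            if mo.a in species and mo.c in species and mo.b not in species:
                repl = [j for j, s in enumerate(species)
                        if s not in (mo.a, mo.c, h.dominant)]
                if repl:
                    species[repl[int(rng.integers(len(repl)))]] = mo.b
                else:
                    species.append(mo.b)
        covers = 90.0 * model.geometric_ratio ** np.arange(len(species))
        covers = _quantize(covers, model.cover_grid)
        pid = f"plot{i:06d}"
        for s, c in zip(species, covers):
            rows.append((pid, s, None, float(c)))
        lon = float(np.clip(rng.normal(h.centre[0], h.dispersion), -180, 180))
        lat = float(np.clip(rng.normal(h.centre[1], h.dispersion), -90, 90))
        headers.append(PlotHeader(pid, lon, lat, h.code))
    table = PlotTable(pd.DataFrame(
        rows, columns=["plot_id", "taxon_name", "layer", "cover_pct"]))
    return table, headers


def truth_tables(model: CommunityModel, headers: Sequence[PlotHeader],
                 ) -> dict:
    """Generating truth for downstream recovery tests."""
    return {
        "plot_habitat": {h.plot_id: h.habitat_code for h in headers},
        "habitat_pool": {h.code: sorted(set(h.pool) | set(model.generalists))
                         for h in model.habitats},
        "habitat_dominant": {h.code: h.dominant for h in model.habitats},
    }


def make_motif_model(seed: int = 0, richness_mean: float = 5.0,
                     ) -> tuple[CommunityModel, MotifSpec]:
    """Community model staging the diagnostic co-occurrence motif.

    Four habitats sharing three generalists: one very high-frequency
    species (the globally most frequent) plus the motif pair a and c,
    which occur across habitats independently of each other; b is a
    habitat species that is frequent in its home pool but outside the
    global frequency top three.  The constraint that a and c never occur
    together without b is the only statistical link between b and the
    pair — pair counts alone make b look like just another moderately
    frequent species, which is exactly the signal that marginal
    co-occurrence predictors cannot see.  The low mean richness keeps
    three-species assemblages common, so short fill-mask queries are
    in-distribution.
    """
    base = make_model(n_habitats=4, pool_size=50, n_generalists=3,
                      generalist_weight=6.0, richness_mean=richness_mean,
                      seed=seed)
    g, a, c = base.generalists
    b = base.habitats[3].pool[0]
    habitats = list(base.habitats)
    h3 = habitats[3]
    w3 = list(h3.occ_weight)
    w3[0] = 1.5                            # b frequent at home
    habitats[3] = replace(h3, occ_weight=tuple(w3))
    model = replace(base, habitats=tuple(habitats),
                    generalist_weight=(6.0, 1.5, 1.5))
    return inject_motif(model, MotifSpec(a, b, c)), MotifSpec(a, b, c)
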