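"""Pre-processing filter chain turning raw plot tables into model datasets.

The chain mirrors common practice for aggregated vegetation-plot archives,
in a fixed order:

1. drop records with cover exactly 0 (absence reports / data errors);
2. merge duplicate species within a plot (different layers), summing covers;
3. snapshot each plot's taxon set and most-abundant taxon;
4. standardize taxon names against a user-supplied synonym table
   (genus-only and unmatched names dropped, subspecies lumped to species);
5. drop hybrid species and dataset-wide rare species (< 10 plots);
6. drop plots that lost more than 25% of their taxa, or their most
   abundant taxon, relative to the snapshot;
7. demote habitat labels occurring on fewer than 10 plots to unlabelled;
8. split into the fill-mask (unlabelled) and classification (labelled)
   datasets.

Boundary semantics are strict as stated: "less than ten" drops 9 and keeps
10; "more than 25%" keeps a plot losing exactly 25%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .plot_data import NameRecord, PlotHeader, PlotTable

__all__ = [
    "CurationConfig",
    "CurationStep",
    "CurationReport",
    "CurationResult",
    "PlotSnapshot",
    "drop_zero_cover",
    "merge_duplicate_layers",
    "take_snapshot",
    "standardize_taxa",
    "drop_hybrids_and_rare",
    "drop_degraded_plots",
    "demote_rare_habitats",
    "split_datasets",
    "curate",
]


@dataclass(frozen=True)
class CurationConfig:
    min_species_occurrences: int = 10
    plot_loss_threshold: float = 0.25
    min_habitat_plots: int = 10
    drop_hybrids: bool = True
    #: iterate the rare-species filter to a fixed point instead of the
    #: default single pass with counts frozen up front
    rare_filter_fixed_point: bool = False
    #: seed for the tie-break when a plot's most-abundant taxon is ambiguous
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_species_occurrences <= 0 or self.min_habitat_plots <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.plot_loss_threshold < 1.0:
            raise ValueError("plot_loss_threshold must be in (0, 1)")


@dataclass(frozen=True)
class CurationStep:
    name: str
    observations: int
    plots: int
    dropped: int


class CurationReport:
    """Ordered per-step bookkeeping; observation counts are non-increasing."""

    def __init__(self) -> None:
        self.steps: list[CurationStep] = []

    def add(self, name: str, table: PlotTable, dropped: int,
            chained: bool = True) -> None:
        step = CurationStep(name, len(table), table.n_plots, dropped)
        if chained and self.steps and step.observations > self.steps[-1].observations:
            raise AssertionError("observation count increased across a step")
        self.steps.append(step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])

    def __repr__(self) -> str:
        return self.to_frame().to_string(index=False)


@dataclass
class CurationResult:
    fill_mask: PlotTable
    classification: PlotTable
    headers: list[PlotHeader]
    report: CurationReport


def drop_zero_cover(table: PlotTable) -> PlotTable:
    """Remove records whose cover is exactly zero (strict test)."""
    return PlotTable(table.df[table.df["cover_pct"] != 0.0])


def merge_duplicate_layers(table: PlotTable) -> PlotTable:
    """Collapse (plot, taxon) duplicates across layers, summing covers.

    Per-plot cover mass is conserved; sums may exceed 100%.  The merged
    record keeps the first occurrence's position and drops the layer code.
    """
    df = table.df
    merged = (df.groupby(["plot_id", "taxon_name"], sort=False,
                         as_index=False)["cover_pct"].sum())
    merged["layer"] = None
    return PlotTable(merged[["plot_id", "taxon_name", "layer", "cover_pct"]])


@dataclass(frozen=True)
class PlotSnapshot:
    """Per-plot state recorded immediately before name standardization."""

    taxa: Mapping[str, frozenset]
    most_abundant: Mapping[str, str]


def take_snapshot(table: PlotTable, seed: int = 0) -> PlotSnapshot:
    """Record each plot's taxon set and most-abundant taxon (seeded tie-break)."""
    rng = np.random.default_rng(seed)
    taxa: dict[str, frozenset] = {}
    most: dict[str, str] = {}
    for pid, grp in table.groupby_plot():
        names = grp["taxon_name"].tolist()
        covers = grp["cover_pct"].to_numpy()
        taxa[pid] = frozenset(names)
        top = covers.max()
        tied = [n for n, c in zip(names, covers) if c == top]
        most[pid] = tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]
    return PlotSnapshot(taxa, most)


def _name_map(names: Sequence[NameRecord]) -> dict[str, NameRecord]:
    return {r.input_name: r for r in names}


def standardize_taxon(name: str, names: Mapping[str, NameRecord]) -> Optional[str]:
    """Accepted lowercase binomial for an input name, or None if dropped."""
    rec = names.get(name)
    if rec is None or rec.rank in ("unmatched", "genus"):
        return None
    return rec.accepted_binomial.lower() if rec.accepted_binomial else None


def standardize_taxa(table: PlotTable, names: Sequence[NameRecord] | Mapping[str, NameRecord],
                     ) -> tuple[PlotTable, pd.DataFrame]:
    """Map every taxon to its accepted lowercase binomial.

    Genus-only and unmatched names are dropped; subspecies lump into their
    parent binomial, with covers re-merged by summation (same rule as the
    layer merge).  Returns the standardized table and a drop report
    (input_name, reason, rows dropped).
    """
    nmap = names if isinstance(names, Mapping) else _name_map(names)
    df = table.df.copy()
    std = df["taxon_name"].map(lambda n: standardize_taxon(n, nmap))
    dropped = df[std.isna()]
    reasons = dropped["taxon_name"].map(
        lambda n: (nmap[n].rank if n in nmap else "unmatched"))
    report = (pd.DataFrame({"input_name": dropped["taxon_name"],
                            "reason": reasons})
              .groupby(["input_name", "reason"]).size()
              .rename("rows_dropped").reset_index())
    df = df[std.notna()].assign(taxon_name=std[std.notna()])
    return merge_duplicate_layers(PlotTable(df)), report


def drop_hybrids_and_rare(table: PlotTable, config: CurationConfig,
                          names: Sequence[NameRecord] | Mapping[str, NameRecord] = (),
                          ) -> PlotTable:
    """Remove hybrid species and dataset-wide rare species.

    Rarity is plot-level presence over the whole dataset, strictly below
    ``min_species_occurrences`` (9 plots drops, 10 keeps).  In the default
    single-pass mode, counts are frozen before any removal in this step.
    """
    nmap = names if isinstance(names, Mapping) else _name_map(names)
    hybrids = {r.accepted_binomial.lower() for r in nmap.values()
               if r.rank == "hybrid" and r.accepted_binomial}
    df = table.df
    if config.drop_hybrids and hybrids:
        df = df[~df["taxon_name"].isin(hybrids)]
    while True:
        counts = df.groupby("taxon_name")["plot_id"].nunique()
        rare = set(counts[counts < config.min_species_occurrences].index)
        if not rare:
            break
        df = df[~df["taxon_name"].isin(rare)]
        if not config.rare_filter_fixed_point:
            break
    return PlotTable(df)


def drop_degraded_plots(table: PlotTable, snapshot: PlotSnapshot,
                        names: Sequence[NameRecord] | Mapping[str, NameRecord],
                        config: CurationConfig) -> PlotTable:
    """Remove plots degraded by name matching.

    A plot is removed when the fraction of its snapshot taxa whose
    standardized form is no longer present exceeds ``plot_loss_threshold``
    (strict: exactly 25% is retained), or when the standardized form of its
    snapshot most-abundant taxon is gone.  Subspecies lumping does not
    count as loss (both lumped names map to a surviving binomial).
    """
    nmap = names if isinstance(names, Mapping) else _name_map(names)
    current = {pid: set(grp["taxon_name"]) for pid, grp in table.groupby_plot()}
    keep: list[str] = []
    for pid, surviving in current.items():
        if pid not in snapshot.taxa:
            raise KeyError(f"plot {pid!r} missing from curation snapshot")
        original = snapshot.taxa[pid]
        lost = sum(1 for t in original
                   if (standardize_taxon(t, nmap) or object()) not in surviving)
        frac = lost / len(original)
        top_std = standardize_taxon(snapshot.most_abundant[pid], nmap)
        if frac <= config.plot_loss_threshold and top_std in surviving:
            keep.append(pid)
    return table.subset(keep)


def demote_rare_habitats(headers: Sequence[PlotHeader], config: CurationConfig,
                         table: Optional[PlotTable] = None) -> list[PlotHeader]:
    """Clear habitat labels whose type occurs on < ``min_habitat_plots`` plots.

    Counts are taken over curated labelled plots (pass ``table`` to restrict
    to plots surviving curation); demoted plots become unlabelled and feed
    the fill-mask dataset.
    """
    kept = set(table.plot_ids) if table is not None else None
    in_scope = [h for h in headers
                if h.habitat_code and (kept is None or h.plot_id in kept)]
    counts: dict[str, int] = {}
    for h in in_scope:
        counts[h.habitat_code] = counts.get(h.habitat_code, 0) + 1
    rare = {code for code, n in counts.items() if n < config.min_habitat_plots}
    return [replace(h, habitat_code=None)
            if h.habitat_code in rare else h for h in headers]


def split_datasets(table: PlotTable, headers: Sequence[PlotHeader],
                   ) -> tuple[PlotTable, PlotTable]:
    """Partition curated plots into (fill-mask, classification) datasets.

    Every curated plot lands in exactly one set; the classification set is
    the plots with a habitat label.  Plots without any header row are
    treated as unlabelled.
    """
    labelled = {h.plot_id for h in headers if h.habitat_code}
    ids = table.plot_ids
    fm = table.subset([p for p in ids if p not in labelled])
    cl = table.subset([p for p in ids if p in labelled])
    return fm, cl


def curate(table: PlotTable, headers: Sequence[PlotHeader],
           names: Sequence[NameRecord], config: CurationConfig = CurationConfig(),
           ) -> CurationResult:
    """Run the full chain in fixed order and report per-step counts."""
    nmap = _name_map(names)
    report = CurationReport()
    report.add("input", table, 0)

    n = len(table)
    table = drop_zero_cover(table)
    report.add("zero_cover", table, n - len(table))

    n = len(table)
    table = merge_duplicate_layers(table)
    report.add("layer_merge", table, n - len(table))

    snapshot = take_snapshot(table, seed=config.seed)

    n = len(table)
    table, _drops = standardize_taxa(table, nmap)
    report.add("standardize", table, n - len(table))

    n = len(table)
    table = drop_hybrids_and_rare(table, config, nmap)
    report.add("hybrid_rare", table, n - len(table))

    n = len(table)
    table = drop_degraded_plots(table, snapshot, nmap, config)
    report.add("degraded_plots", table, n - len(table))

    labelled_before = sum(1 for h in headers if h.habitat_code)
    headers = demote_rare_habitats(headers, config, table)
    n_demoted = labelled_before - sum(1 for h in headers if h.habitat_code)
    report.add("rare_habitats", table, n_demoted)

    fill_mask, classification = split_datasets(table, headers)
    report.add("split:fill_mask", fill_mask, 0, chained=False)
    report.add("split:classification", classification, 0, chained=False)
    return CurationResult(fill_mask, classification, list(headers), report)
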