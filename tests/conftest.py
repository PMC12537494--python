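"""Shared fixtures: hand-built curation tables and small synthetic corpora."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from vegsyntax.curation import CurationConfig
from vegsyntax.plot_data import NameRecord, PlotTable

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def obs_table(rows):
    """Build a PlotTable from (plot, taxon, layer, cover) tuples."""
    return PlotTable(pd.DataFrame(
        rows, columns=["plot_id", "taxon_name", "layer", "cover_pct"]))


@pytest.fixture
def name_records():
    return [
        NameRecord("Quercus robur", "quercus robur", "species"),
        NameRecord("Fagus sylvatica", "fagus sylvatica", "species"),
        NameRecord("Abies alba", "abies alba", "species"),
        NameRecord("Pinus mugo", "pinus mugo", "species"),
        NameRecord("Betula pendula", "betula pendula", "species"),
        NameRecord("Rara avis", "rara avis", "species"),
        NameRecord("Hedera helix subsp. helix", "hedera helix", "subspecies"),
        NameRecord("Hedera helix subsp. poetarum", "hedera helix", "subspecies"),
        NameRecord("Hedera", None, "genus"),
        NameRecord("Carex cuprina", None, "unmatched"),
        NameRecord("Salix ×rubens", "salix rubens", "hybrid"),
    ]


@pytest.fixture
def twelve_plot_table():
    """Twelve plots exercising every curation rule at once.

    The expected per-step counts in the tests were enumerated by hand from
    these rows (see test_curation / test_acceptance).
    """
    return obs_table([
        # p1: layer duplicate (merged to 80), genus-only, one subspecies
        ("p1", "Quercus robur", "tree", 60.0),
        ("p1", "Quercus robur", "herb", 20.0),
        ("p1", "Fagus sylvatica", None, 30.0),
        ("p1", "Hedera", None, 5.0),
        ("p1", "Hedera helix subsp. helix", None, 10.0),
        # p2: unmatched name, a zero-cover record
        ("p2", "Quercus robur", None, 50.0),
        ("p2", "Fagus sylvatica", None, 40.0),
        ("p2", "Abies alba", None, 10.0),
        ("p2", "Carex cuprina", None, 5.0),
        ("p2", "Betula pendula", None, 0.0),
        # p3: clean
        ("p3", "Fagus sylvatica", None, 70.0),
        ("p3", "Abies alba", None, 20.0),
        ("p3", "Pinus mugo", None, 10.0),
        # p4: rare species, both subspecies lumped in one plot
        ("p4", "Quercus robur", None, 80.0),
        ("p4", "Betula pendula", None, 10.0),
        ("p4", "Rara avis", None, 5.0),
        ("p4", "Hedera helix subsp. poetarum", None, 10.0),
        ("p4", "Hedera helix subsp. helix", None, 5.0),
        # p5, p6: clean (p6 has a cover tie at the top)
        ("p5", "Abies alba", None, 60.0),
        ("p5", "Pinus mugo", None, 30.0),
        ("p5", "Fagus sylvatica", None, 10.0),
        ("p6", "Quercus robur", None, 40.0),
        ("p6", "Fagus sylvatica", None, 40.0),
        ("p6", "Betula pendula", None, 20.0),
        # p7: hybrid is the most abundant taxon
        ("p7", "Salix ×rubens", None, 50.0),
        ("p7", "Quercus robur", None, 30.0),
        ("p7", "Fagus sylvatica", None, 20.0),
        # p8: unmatched name is the most abundant taxon
        ("p8", "Carex cuprina", None, 60.0),
        ("p8", "Quercus robur", None, 30.0),
        ("p8", "Fagus sylvatica", None, 20.0),
        ("p8", "Abies alba", None, 10.0),
        # p9, p10: two-species plots
        ("p9", "Quercus robur", None, 10.0),
        ("p9", "Betula pendula", None, 90.0),
        ("p10", "Pinus mugo", None, 50.0),
        ("p10", "Abies alba", None, 50.0),
        # p11: loses exactly 25% (the genus-only record)
        ("p11", "Fagus sylvatica", None, 30.0),
        ("p11", "Quercus robur", None, 30.0),
        ("p11", "Abies alba", None, 30.0),
        ("p11", "Hedera", None, 10.0),
        # p12: loses 50%
        ("p12", "Quercus robur", None, 30.0),
        ("p12", "Fagus sylvatica", None, 25.0),
        ("p12", "Carex cuprina", None, 25.0),
        ("p12", "Hedera", None, 20.0),
    ])


@pytest.fixture
def twelve_plot_headers():
    from vegsyntax.plot_data import PlotHeader
    hab = {"p1": "T11", "p2": "T11", "p3": "T11", "p5": "T11",
           "p6": "R11", "p9": "R11", "p7": "S11", "p8": "S11"}
    return [PlotHeader(f"p{i}", 5.0 + 0.01 * i, 45.0 + 0.01 * i,
                       hab.get(f"p{i}"))
            for i in range(1, 13)]


@pytest.fixture
def small_config():
    """Thresholds scaled to the 12-plot fixture (3 instead of 10)."""
    return CurationConfig(min_species_occurrences=3, min_habitat_plots=3)


# expected per-step (observations, plots, dropped) for the fixture above,
# enumerated by hand
TWELVE_PLOT_EXPECTED = [
    ("input", 43, 12, 0),
    ("zero_cover", 42, 12, 1),
    ("layer_merge", 41, 12, 1),
    ("standardize", 34, 12, 7),
    ("hybrid_rare", 30, 12, 4),
    ("degraded_plots", 19, 7, 11),
    ("rare_habitats", 19, 7, 2),
    ("split:fill_mask", 10, 4, 0),
    ("split:classification", 9, 3, 0),
]
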