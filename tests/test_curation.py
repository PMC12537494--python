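import numpy as np
import pandas as pd
import pytest

from vegsyntax.curation import (CurationConfig, curate, demote_rare_habitats,
                                drop_degraded_plots, drop_hybrids_and_rare,
                                drop_zero_cover, merge_duplicate_layers,
                                split_datasets, standardize_taxa,
                                take_snapshot)
from vegsyntax.plot_data import NameRecord, PlotHeader

from conftest import TWELVE_PLOT_EXPECTED, obs_table


class TestZeroCover:
    def test_strictly_zero_removed_only(self):
        t = obs_table([("p1", "a a", None, 0.0), ("p1", "b b", None, 0.0001),
                       ("p1", "c c", None, 5.0), ("p2", "d d", None, 0.0),
                       ("p2", "e e", None, 1.0)])
        out = drop_zero_cover(t)
        assert len(out) == 3
        assert set(out.df["taxon_name"]) == {"b b", "c c", "e e"}

    def test_identity_when_no_zeros(self):
        t = obs_table([("p1", "a a", None, 5.0)])
        assert drop_zero_cover(t) == t


class TestLayerMerge:
    def test_covers_summed_across_layers(self):
        t = obs_table([("p1", "a a", "tree", 60.0), ("p1", "a a", "herb", 50.0)])
        out = merge_duplicate_layers(t)
        assert len(out) == 1
        assert out.df["cover_pct"].iloc[0] == 110.0  # sums may exceed 100

    def test_distinct_taxa_unchanged_and_mass_conserved(self):
        t = obs_table([("p1", "a a", "t", 30.0), ("p1", "b b", "h", 20.0),
                       ("p2", "a a", "t", 10.0), ("p2", "a a", "m", 15.0)])
        out = merge_duplicate_layers(t)
        for pid in ("p1", "p2"):
            assert (out.plot(pid)["cover_pct"].sum()
                    == t.plot(pid)["cover_pct"].sum())


class TestStandardize:
    def test_subspecies_lumped_to_single_record(self, name_records):
        t = obs_table([
            ("p1", "Hedera helix subsp. helix", None, 10.0),
            ("p1", "Hedera helix subsp. poetarum", None, 5.0)])
        out, _ = standardize_taxa(t, name_records)
        assert len(out) == 1
        assert out.df["taxon_name"].iloc[0] == "hedera helix"
        assert out.df["cover_pct"].iloc[0] == 15.0

    def test_genus_only_dropped(self, name_records):
        t = obs_table([("p1", "Hedera", None, 5.0),
                       ("p1", "Quercus robur", None, 50.0)])
        out, report = standardize_taxa(t, name_records)
        assert list(out.df["taxon_name"]) == ["quercus robur"]
        assert report["reason"].tolist() == ["genus"]

    def test_accepted_names_only_lowercased(self, name_records):
        t = obs_table([("p1", "Quercus robur", None, 50.0),
                       ("p1", "Fagus sylvatica", None, 10.0)])
        out, _ = standardize_taxa(t, name_records)
        assert list(out.df["taxon_name"]) == ["quercus robur",
                                              "fagus sylvatica"]
        assert list(out.df["cover_pct"]) == [50.0, 10.0]


class TestHybridsAndRare:
    def _table(self, n_plots_a, n_plots_b):
        rows = [(f"p{i}", "alpha alpha", None, 5.0) for i in range(n_plots_a)]
        rows += [(f"p{i}", "beta beta", None, 5.0) for i in range(n_plots_b)]
        return obs_table(rows)

    def test_nine_occurrences_dropped_ten_kept(self):
        t = self._table(10, 9)
        out = drop_hybrids_and_rare(t, CurationConfig())
        assert set(out.df["taxon_name"]) == {"alpha alpha"}

    def test_counts_frozen_in_single_pass(self):
        # beta co-occurs with alpha in 10 plots; alpha alone in 9 others.
        # Dropping beta does not retroactively doom alpha: counts are
        # computed once, before any removal in the step.
        rows = [(f"p{i}", "alpha alpha", None, 5.0) for i in range(19)]
        rows += [(f"p{i}", "beta beta", None, 5.0) for i in range(9)]
        t = obs_table(rows)
        out = drop_hybrids_and_rare(t, CurationConfig(min_species_occurrences=15))
        assert set(out.df["taxon_name"]) == {"alpha alpha"}

    def test_hybrid_flag_behaviour(self, name_records):
        t = obs_table([(f"p{i}", "salix rubens", None, 5.0) for i in range(12)])
        keep = drop_hybrids_and_rare(t, CurationConfig(drop_hybrids=False),
                                     name_records)
        drop = drop_hybrids_and_rare(t, CurationConfig(), name_records)
        assert len(keep) == 12
        assert len(drop) == 0


class TestDegradedPlots:
    def _run(self, n_taxa, n_lost, lose_top: bool = False):
        taxa = [f"tax{i} sp{i}" for i in range(n_taxa)]
        lost = (set(range(n_lost)) if lose_top
                else set(range(n_taxa - n_lost, n_taxa)))
        records = [NameRecord(t, None if i in lost else t,
                              "unmatched" if i in lost else "species")
                   for i, t in enumerate(taxa)]
        t = obs_table([("p1", t, None, 50.0 - i)
                       for i, t in enumerate(taxa)])
        snap = take_snapshot(t)
        std, _ = standardize_taxa(t, records)
        return drop_degraded_plots(std, snap, records, CurationConfig())

    def test_exactly_25pct_loss_retained(self):
        assert self._run(4, 1).n_plots == 1  # lost taxon is not most abundant

    def test_over_25pct_loss_removed(self):
        assert self._run(4, 2).n_plots == 0

    def test_losing_most_abundant_alone_removes_plot(self):
        # 1 of 10 lost (10% <= 25%) but it is the top taxon
        out = self._run(10, 1, lose_top=True)
        assert out.n_plots == 0

    def test_plot_missing_from_snapshot_is_consistency_error(self):
        t = obs_table([("p1", "a a", None, 5.0)])
        snap = take_snapshot(obs_table([("p2", "a a", None, 5.0)]))
        rec = [NameRecord("a a", "a a", "species")]
        with pytest.raises(KeyError):
            drop_degraded_plots(t, snap, rec, CurationConfig())


class TestRareHabitats:
    def _headers(self, counts):
        out = []
        i = 0
        for code, n in counts.items():
            for _ in range(n):
                out.append(PlotHeader(f"p{i}", 5.0, 45.0, code))
                i += 1
        return out

    def test_boundary_nine_demoted_ten_kept(self):
        headers = self._headers({"T11": 10, "R11": 9})
        out = demote_rare_habitats(headers, CurationConfig())
        codes = [h.habitat_code for h in out]
        assert codes.count("T11") == 10
        assert codes.count("R11") == 0
        assert codes.count(None) == 9

    def test_identity_when_all_frequent(self):
        headers = self._headers({"T11": 10})
        assert demote_rare_habitats(headers, CurationConfig()) == headers


class TestSplit:
    def test_partition(self):
        t = obs_table([(f"p{i}", "a a", None, 5.0) for i in range(10)])
        headers = [PlotHeader(f"p{i}", 0, 0, "T11" if i < 6 else None)
                   for i in range(10)]
        fm, cl = split_datasets(t, headers)
        assert fm.n_plots == 4 and cl.n_plots == 6
        assert set(fm.plot_ids) | set(cl.plot_ids) == set(t.plot_ids)
        assert not set(fm.plot_ids) & set(cl.plot_ids)

    def test_all_labelled_gives_empty_fill_mask(self):
        t = obs_table([("p1", "a a", None, 5.0)])
        fm, cl = split_datasets(t, [PlotHeader("p1", 0, 0, "T11")])
        assert fm.n_plots == 0 and cl.n_plots == 1


class TestFullChain:
    def test_hand_enumerated_counts(self, twelve_plot_table,
                                    twelve_plot_headers, name_records,
                                    small_config):
        result = curate(twelve_plot_table, twelve_plot_headers, name_records,
                        small_config)
        got = [(s.name, s.observations, s.plots, s.dropped)
               for s in result.report.steps]
        assert got == TWELVE_PLOT_EXPECTED

    def test_counts_non_increasing(self, twelve_plot_table,
                                   twelve_plot_headers, name_records,
                                   small_config):
        result = curate(twelve_plot_table, twelve_plot_headers, name_records,
                        small_config)
        chain = result.report.steps[:7]  # before the partition rows
        obs = [s.observations for s in chain]
        assert obs == sorted(obs, reverse=True)

    def test_all_surviving_taxa_are_lowercase_binomials(
            self, twelve_plot_table, twelve_plot_headers, name_records,
            small_config):
        result = curate(twelve_plot_table, twelve_plot_headers, name_records,
                        small_config)
        for table in (result.fill_mask, result.classification):
            for name in table.df["taxon_name"]:
                assert name == name.lower()
                assert len(name.split()) == 2

    def test_clean_input_reports_zero_drops(self):
        rows = [(f"p{i}", f"alpha{j} beta{j}", None, 5.0 + j)
                for i in range(12) for j in range(3)]
        names = [NameRecord(f"alpha{j} beta{j}", f"alpha{j} beta{j}", "species")
                 for j in range(3)]
        headers = [PlotHeader(f"p{i}", 0, 0, None) for i in range(12)]
        result = curate(obs_table(rows), headers, names,
                        CurationConfig(min_species_occurrences=3,
                                       min_habitat_plots=3))
        assert all(s.dropped == 0 for s in result.report.steps)

    def test_idempotent_on_already_curated_data(self, twelve_plot_table,
                                                twelve_plot_headers,
                                                name_records, small_config):
        """Re-curating changes nothing except rare-species knock-ons."""
        first = curate(twelve_plot_table, twelve_plot_headers, name_records,
                       small_config)
        merged = obs_table(
            pd.concat([first.fill_mask.df, first.classification.df])
            .values.tolist())
        names2 = [NameRecord(n, n, "species")
                  for n in merged.df["taxon_name"].unique()]
        second = curate(merged, first.headers, names2, small_config)
        by_name = {s.name: s for s in second.report.steps}
        for step in ("zero_cover", "layer_merge", "standardize"):
            assert by_name[step].dropped == 0
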