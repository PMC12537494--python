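import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vegsyntax.baselines import (CooccurrenceMatrix, MLPFillMaskConfig,
                                 NBConfig, build_cooccurrence,
                                 mlp_fillmask_predict, mlp_fillmask_train,
                                 nb_predict)


def brute_force_nb(matrix, observed, alpha=1.0):
    """Independent per-candidate loop implementing the scoring formula."""
    V = len(matrix.species)
    N = {s: matrix.counts[i, i] for i, s in enumerate(matrix.species)}
    total = sum(N.values())
    scores = {}
    for s in matrix.species:
        if s in observed:
            continue
        si = matrix.index[s]
        score = math.log(N[s] / total)
        for o in observed:
            c = matrix.counts[matrix.index[o], si]
            score += math.log((c + alpha) / (N[s] + alpha * V))
        scores[s] = score
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def assert_same_ranking(got, expected, tol=1e-9):
    """Rankings must agree wherever scores are numerically distinguishable.

    Mathematically tied candidates (identical counts) may differ in the
    last float ulp between the vectorized and looped computations, so pairs
    closer than ``tol`` are treated as ties with free relative order.
    """
    scores_g = dict(got)
    scores_e = dict(expected)
    assert set(scores_g) == set(scores_e)
    for s in scores_g:
        assert scores_g[s] == pytest.approx(scores_e[s], rel=1e-9, abs=1e-9)
    names_g = [s for s, _ in got]
    names_e = [s for s, _ in expected]
    for i, a in enumerate(names_e):
        for b in names_e[i + 1:]:
            if scores_e[a] - scores_e[b] > tol:
                assert names_g.index(a) < names_g.index(b)


class TestCooccurrence:
    def test_hand_counted_pairs(self):
        m = build_cooccurrence([["a a", "b b"], ["a a", "b b"], ["a a", "c c"]])
        i = m.index
        assert m.counts[i["a a"], i["b b"]] == 2
        assert m.counts[i["a a"], i["c c"]] == 1
        assert m.counts[i["b b"], i["c c"]] == 0
        assert list(m.occurrences) == [3, 2, 1]

    def test_single_plot_single_species(self):
        m = build_cooccurrence([["a a"]])
        assert m.counts[0, 0] == 1 and m.n_plots == 1

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        plots = [[f"s{j} x{j}" for j in rng.choice(10, 4, replace=False)]
                 for _ in range(30)]
        m = build_cooccurrence(plots)
        assert (m.counts == m.counts.T).all()

    def test_triplet_round_trip(self, tmp_path):
        m = build_cooccurrence([["a a", "b b"], ["b b", "c c"]])
        m.save_triplets(tmp_path / "m.tsv")
        back = CooccurrenceMatrix.load_triplets(tmp_path / "m.tsv", m.n_plots)
        assert (back.counts == m.counts).all()
        assert back.species == m.species


class TestNaiveBayes:
    def test_three_plot_fixture_ranks_b_over_c(self):
        m = build_cooccurrence([["a a", "b b"], ["a a", "b b"], ["a a", "c c"]])
        ranked = nb_predict(m, ["a a"], NBConfig(alpha=1.0), k=5)
        names = [s for s, _ in ranked]
        assert names.index("b b") < names.index("c c")
        # hand evaluation of the formula: score(b) = log(2/6 * 3/5)
        assert ranked[0][1] == pytest.approx(math.log(2 / 6 * 3 / 5))

    def test_all_species_observed_gives_empty_candidates(self):
        m = build_cooccurrence([["a a", "b b"]])
        assert nb_predict(m, ["a a", "b b"]) == []

    def test_unknown_species_warns_and_is_ignored(self):
        m = build_cooccurrence([["a a", "b b"], ["a a", "c c"]])
        with pytest.warns(UserWarning, match="unknown"):
            ranked = nb_predict(m, ["a a", "zz zz"], k=5)
        clean = nb_predict(m, ["a a"], k=5)
        assert ranked == clean

    def test_invariant_to_observed_order(self):
        rng = np.random.default_rng(1)
        plots = [[f"s{j} x{j}" for j in rng.choice(12, 5, replace=False)]
                 for _ in range(40)]
        m = build_cooccurrence(plots)
        obs = ["s1 x1", "s4 x4", "s7 x7"]
        assert nb_predict(m, obs) == nb_predict(m, list(reversed(obs)))

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_bruteforce_oracle_on_random_fixtures(self, trial):
        rng = np.random.default_rng(100 + trial)
        n_species = int(rng.integers(5, 31))
        species = [f"g{j} s{j}" for j in range(n_species)]
        n_plots = int(rng.integers(5, 40))
        plots = []
        for _ in range(n_plots):
            k = int(rng.integers(2, min(8, n_species) + 1))
            plots.append([species[j]
                          for j in rng.choice(n_species, k, replace=False)])
        m = build_cooccurrence(plots)
        k_obs = int(rng.integers(1, 4))
        present = sorted({s for p in plots for s in p})
        observed = [present[j] for j in
                    rng.choice(len(present), k_obs, replace=False)]
        expected = brute_force_nb(m, observed)
        got = nb_predict(m, observed, k=len(expected))
        assert_same_ranking(got, expected)


class TestMLPFillMask:
    def test_recovers_partner_in_disjoint_pairs(self):
        plots = ([["a a", "b b"]] * 40 + [["c c", "d d"]] * 40)
        model = mlp_fillmask_train(plots, MLPFillMaskConfig(
            hidden_sizes=(16,), epochs=30, learning_rate=0.5, seed=0))
        assert mlp_fillmask_predict(model, ["a a"], k=1)[0][0] == "b b"
        assert mlp_fillmask_predict(model, ["c c"], k=1)[0][0] == "d d"

    def test_zero_epochs_gives_uniform_scores(self):
        plots = [["a a", "b b"], ["c c", "d d"]]
        model = mlp_fillmask_train(plots, MLPFillMaskConfig(epochs=0))
        ranked = mlp_fillmask_predict(model, ["a a"], k=4)
        probs = [p for _, p in ranked]
        assert len(set(probs)) == 1

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(2)
        plots = [[f"s{j} x{j}" for j in rng.choice(10, 4, replace=False)]
                 for _ in range(30)]
        cfg = MLPFillMaskConfig(hidden_sizes=(8,), epochs=3, seed=5)
        r1 = mlp_fillmask_predict(mlp_fillmask_train(plots, cfg), ["s1 x1"])
        r2 = mlp_fillmask_predict(mlp_fillmask_train(plots, cfg), ["s1 x1"])
        assert r1 == r2

    def test_single_species_plots_skipped(self):
        plots = [["a a"], ["b b", "c c"]]
        model = mlp_fillmask_train(plots, MLPFillMaskConfig(epochs=1))
        assert "a a" not in model.species or len(model.species) == 3

    def test_observed_excluded_from_candidates(self):
        plots = [["a a", "b b", "c c"]] * 20
        model = mlp_fillmask_train(plots, MLPFillMaskConfig(epochs=2, seed=1))
        ranked = mlp_fillmask_predict(model, ["a a", "b b"], k=5)
        assert all(s not in ("a a", "b b") for s, _ in ranked)


class TestFrequencyFailureMode:
    def test_nb_converges_to_marginal_ranking_on_independent_species(self):
        """With independent species, the ranking follows marginal frequency."""
        rng = np.random.default_rng(7)
        n_species = 20
        freqs = np.linspace(0.8, 0.05, n_species)
        species = [f"g{j} s{j}" for j in range(n_species)]
        plots = []
        for _ in range(2000):
            mask = rng.random(n_species) < freqs
            if mask.sum() >= 2:
                plots.append([s for s, m_ in zip(species, mask) if m_])
        m = build_cooccurrence(plots)
        ranked = [s for s, _ in nb_predict(m, [species[-1]],
                                           k=n_species - 1)]
        # the top candidate is among the few most frequent species and the
        # whole ranking tracks marginal frequency (sampling noise can swap
        # near-equal neighbours)
        assert ranked[0] in species[:3]
        from scipy.stats import spearmanr
        freq_rank = {s: i for i, s in enumerate(species[:-1])}
        rho, _ = spearmanr(range(len(ranked)),
                           [freq_rank[s] for s in ranked])
        assert rho > 0.9
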