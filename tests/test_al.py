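"""Active-learning heuristics and the accept-if-better loop."""

import numpy as np
import pytest

from chimetraits import al as al_mod
from chimetraits import gpr


class TestEBD:
    def test_hand_ranked_1d_instance(self):
        labeled = np.array([[0.0]])
        candidates = np.array([[1.0], [3.0]])
        order = al_mod.rank_ebd(candidates, labeled)
        assert list(order) == [1, 0]

    def test_duplicate_of_labeled_ranked_last(self):
        labeled = np.array([[0.0, 0.0], [1.0, 1.0]])
        candidates = np.array([[5.0, 5.0], [0.0, 0.0], [-3.0, 2.0]])
        order = al_mod.rank_ebd(candidates, labeled)
        assert order[-1] == 1

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        labeled = rng.normal(size=(5, 3))
        candidates = rng.normal(size=(12, 3))
        shift = np.array([10.0, -4.0, 2.5])
        a = al_mod.rank_ebd(candidates, labeled)
        b = al_mod.rank_ebd(candidates + shift, labeled + shift)
        assert np.array_equal(a, b)


class TestABD:
    def test_hand_ranked_angles(self):
        labeled = np.array([[1.0, 0.0]])
        candidates = np.array([[0.0, 1.0], [1.0, 1.0]])
        order = al_mod.rank_abd(candidates, labeled)
        assert list(order) == [0, 1]  # 90° before 45°

    def test_collinear_candidate_scores_zero_and_scale_invariance(self):
        labeled = np.array([[1.0, 2.0]])
        candidates = np.array([[2.0, 4.0], [4.0, 1.0]])
        order = al_mod.rank_abd(candidates, labeled)
        assert order[-1] == 0
        doubled = al_mod.rank_abd(2.0 * candidates, labeled)
        assert np.array_equal(order, doubled)


class TestCBD:
    def test_underrepresented_blob_ranked_first(self):
        rng = np.random.default_rng(1)
        blob_a = rng.normal(0.0, 0.1, size=(20, 2))
        blob_b = rng.normal(8.0, 0.1, size=(20, 2))
        candidates = np.vstack([blob_a, blob_b])
        labeled = rng.normal(0.0, 0.1, size=(6, 2))  # all in blob A
        order = al_mod.rank_cbd(candidates, labeled, seed=0, n_clusters=2)
        assert order[0] >= 20  # first pick from blob B

    def test_each_candidate_own_cluster_at_k_equal_n(self):
        rng = np.random.default_rng(2)
        candidates = rng.normal(size=(6, 2))
        labeled = rng.normal(size=(3, 2))
        order = al_mod.rank_cbd(candidates, labeled, seed=0, n_clusters=6)
        assert sorted(order) == list(range(6))

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        candidates = rng.normal(size=(30, 4))
        labeled = rng.normal(size=(5, 4))
        a = al_mod.rank_cbd(candidates, labeled, seed=9)
        b = al_mod.rank_cbd(candidates, labeled, seed=9)
        assert np.array_equal(a, b)


class TestPAL:
    def test_extrapolation_region_ranked_first_on_1d_toy(self):
        rng = np.random.default_rng(4)
        X = np.linspace(0, 1, 12)[:, None]
        y = np.sin(3 * X[:, 0]) + rng.normal(0, 0.01, 12)
        candidates = np.array([[0.5], [0.55], [3.0], [2.5]])
        order = al_mod.rank_pal(candidates, X, y, seed=0)
        assert set(order[:2]) == {2, 3}

    def test_labeled_duplicate_ranked_last_with_tiny_noise(self):
        X = np.linspace(0, 1, 10)[:, None]
        y = 2 * X[:, 0]
        hp = gpr.GPRHyperparams(1.0, 1e-8, np.array([0.3]))
        candidates = np.array([[0.5], [5.0], [7.0]])
        order = al_mod.rank_pal(candidates, X, y, seed=1, hp=hp)
        assert order[-1] == 0

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 2))
        y = X[:, 0] + rng.normal(0, 0.1, 15)
        cand = rng.normal(size=(10, 2))
        a = al_mod.rank_pal(cand, X, y, seed=3)
        b = al_mod.rank_pal(cand, X, y, seed=3)
        assert np.array_equal(a, b)


class TestRSAL:
    def test_high_noise_region_attracts_top_ranks(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.uniform(0, 1, 25), rng.uniform(4, 5, 25)])
        noise = np.where(x < 2, 0.005, 0.8)
        y = 0.5 * x + rng.normal(0, 1, 50) * noise
        X = x[:, None]
        candidates = np.array([[0.5], [0.6], [4.4], [4.6]])
        order = al_mod.rank_rsal(candidates, X, y, seed=0)
        assert set(order[:2]) == {2, 3}

    def test_seed_determinism(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 2))
        y = X[:, 1] + rng.normal(0, 0.1, 20)
        cand = rng.normal(size=(8, 2))
        a = al_mod.rank_rsal(cand, X, y, seed=2)
        b = al_mod.rank_rsal(cand, X, y, seed=2)
        assert np.array_equal(a, b)


class TestRankingContracts:
    @pytest.mark.parametrize("heuristic", al_mod.HEURISTICS)
    def test_total_order_on_random_inputs(self, heuristic):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 3))
        y = X[:, 0] + rng.normal(0, 0.2, 25)
        cand = rng.normal(size=(14, 3))
        order = al_mod._rank(heuristic, cand, X, y, seed=1, hp=None)
        assert sorted(order) == list(range(14))

    def test_unknown_heuristic_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError, match="heuristic"):
            al_mod.al_run(
                rng.normal(size=(30, 2)), rng.normal(size=30),
                rng.normal(size=(5, 2)), rng.normal(size=5),
                heuristic="QBC",
            )


@pytest.fixture(scope="module")
def al_problem():
    """A learnable 2-D regression pool with a held-out validation set."""
    rng = np.random.default_rng(10)
    X = rng.uniform(-2, 2, size=(120, 2))
    y = np.sin(X[:, 0]) + 0.5 * X[:, 1] + rng.normal(0, 0.05, 120)
    Xv = rng.uniform(-1.8, 1.8, size=(30, 2))
    yv = np.sin(Xv[:, 0]) + 0.5 * Xv[:, 1]
    return X, y, Xv, yv


class TestALRun:
    @pytest.mark.parametrize("heuristic", ["EBD", "CBD"])
    def test_accepted_rmse_strictly_decreasing_and_never_worse(
        self, al_problem, heuristic
    ):
        X, y, Xv, yv = al_problem
        idx, model, state = al_mod.al_run(
            X, y, Xv, yv, heuristic=heuristic, init_size=10, seed=0
        )
        hist = state.history_frame()
        accepted = hist[hist.accepted]["rmse"].to_numpy()
        assert np.all(np.diff(accepted) < 0)
        assert accepted[-1] <= accepted[0]
        assert set(idx) <= set(range(len(y)))
        assert len(idx) <= len(y)

    def test_every_candidate_processed_exactly_once(self, al_problem):
        X, y, Xv, yv = al_problem
        _, _, state = al_mod.al_run(X, y, Xv, yv, heuristic="EBD", init_size=10, seed=1)
        hist = state.history_frame()
        processed = hist[hist.candidate_id >= 0]["candidate_id"]
        assert processed.is_unique
        assert len(processed) == len(y) - 10

    def test_final_pool_contains_initial_plus_accepted(self, al_problem):
        X, y, Xv, yv = al_problem
        idx, _, state = al_mod.al_run(X, y, Xv, yv, heuristic="EBD", init_size=10, seed=2)
        hist = state.history_frame()
        n_accepted = int(hist[hist.candidate_id >= 0]["accepted"].sum())
        assert len(idx) == 10 + n_accepted

    def test_seed_determinism(self, al_problem):
        X, y, Xv, yv = al_problem
        idx1, _, s1 = al_mod.al_run(X, y, Xv, yv, heuristic="CBD", init_size=10, seed=5)
        idx2, _, s2 = al_mod.al_run(X, y, Xv, yv, heuristic="CBD", init_size=10, seed=5)
        assert np.array_equal(idx1, idx2)
        assert s1.history_frame().equals(s2.history_frame())

    def test_empty_candidate_set_returns_initial_model(self, al_problem):
        X, y, Xv, yv = al_problem
        n = 12
        idx, model, state = al_mod.al_run(
            X[:n], y[:n], Xv, yv, heuristic="EBD", init_size=n, seed=0
        )
        assert len(idx) == n
        assert len(state.history) == 1  # only the initial entry

    def test_history_csv_export(self, al_problem, tmp_path):
        X, y, Xv, yv = al_problem
        _, _, state = al_mod.al_run(
            X[:40], y[:40], Xv, yv, heuristic="EBD", init_size=10, seed=3
        )
        path = tmp_path / "history.csv"
        state.to_csv(path)
        import pandas as pd

        hist = pd.read_csv(path)
        assert list(hist.columns) == ["iteration", "candidate_id", "accepted", "rmse"]
        assert len(hist) == 31
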