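import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from causnet import (
    ConditionTags,
    LanguageInput,
    ModelConfig,
    VerbEntry,
    corpus_log_loss,
    enumerate_grid,
    grid_search,
    init_network,
    mean_predictions,
    run_condition,
    shuffle_semantics,
    split_half_assign,
)
from causnet.errors import DegenerateInputError


class TestSplitHalf:
    def test_60_verbs_split_30_30(self, rng):
        train, test = split_half_assign(range(60), rng)
        assert len(train) == 30 and len(test) == 30

    def test_odd_cardinality_rule(self, rng):
        train, test = split_half_assign(range(3), rng)
        assert len(train) == 2 and len(test) == 1

    @settings(max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 100))
    def test_partition_property(self, seed, n):
        ids = set(range(n))
        train, test = split_half_assign(ids, np.random.default_rng(seed))
        assert train | test == ids and not (train & test)
        assert len(train) == -(-n // 2)

    def test_fewer_than_two_verbs_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            split_half_assign({0}, rng)


class TestShuffleSemantics:
    def test_multiset_of_sem_vectors_preserved(self, synth_world, rng):
        _, lang, _ = synth_world
        shuffled = shuffle_semantics(lang, rng)
        orig = sorted(map(tuple, lang.sem_matrix()))
        new = sorted(map(tuple, shuffled.sem_matrix()))
        assert orig == new

    def test_counts_and_labels_untouched(self, synth_world, rng):
        _, lang, _ = synth_world
        shuffled = shuffle_semantics(lang, rng)
        assert shuffled.labels == lang.labels
        np.testing.assert_array_equal(shuffled.counts(), lang.counts())

    def test_single_verb_identity(self, rng):
        lang = LanguageInput("one", (VerbEntry(0, "v", 1, 2, 3, (0.5,) * 4),))
        assert shuffle_semantics(lang, rng) == lang

    def test_permutation_null_correlation(self, synth_world):
        """Average correlation between original and shuffled event-merge
        ratings across seeds is ~0 (permutation null)."""
        _, lang, _ = synth_world
        em = lang.sem_matrix()[:, 0]
        rs = []
        for seed in range(200):
            shuffled = shuffle_semantics(lang, np.random.default_rng(seed))
            rs.append(np.corrcoef(em, shuffled.sem_matrix()[:, 0])[0, 1])
        assert abs(np.mean(rs)) < 0.05


class TestCorpusLogLoss:
    def test_zero_weight_network_scores_log3(self, tiny_lang, rng):
        net = init_network(ModelConfig.baseline(init_range=0.0), tiny_lang.n_verbs, rng)
        assert corpus_log_loss(net, tiny_lang) == pytest.approx(np.log(3), abs=1e-9)

    def test_optimal_constant_predictor_scores_entropy(self, rng):
        lang = LanguageInput("one", (VerbEntry(0, "v", 30, 60, 10, (0.5,) * 4),))
        net = init_network(ModelConfig.baseline(init_range=0.0), 1, rng)
        net.biases[0] = np.log(np.array([0.3, 0.6, 0.1]))
        expected = -sum(p * np.log(p) for p in (0.3, 0.6, 0.1))
        assert corpus_log_loss(net, lang) == pytest.approx(expected, abs=1e-9)

    def test_near_perfect_predictor_scores_near_zero(self, rng):
        lang = LanguageInput("one", (VerbEntry(0, "v", 100, 0, 0, (0.5,) * 4),))
        net = init_network(ModelConfig.baseline(init_range=0.0), 1, rng)
        net.biases[0] = np.array([30.0, 0.0, 0.0])
        assert corpus_log_loss(net, lang) < 1e-9


class TestRunCondition:
    def test_zero_epochs_zero_init_gives_uniform_means(self, tiny_lang):
        cfg = ModelConfig.baseline(epochs=0, runs=4, init_range=0.0)
        rec = run_condition(tiny_lang, cfg)
        means = mean_predictions(rec)
        np.testing.assert_allclose(means[["p_less", "p_more", "p_other"]], 1 / 3, atol=1e-12)

    def test_record_count_is_product(self, tiny_lang):
        cfg = ModelConfig.baseline(epochs=3, runs=2, items_per_epoch=200)
        rec = run_condition(tiny_lang, cfg)
        assert len(rec) == 2 * 3 * tiny_lang.n_verbs

    def test_probabilities_normalized(self, tiny_lang):
        cfg = ModelConfig.baseline(epochs=2, runs=2, items_per_epoch=200)
        rec = run_condition(tiny_lang, cfg)
        np.testing.assert_allclose(
            rec[["p_less", "p_more", "p_other"]].sum(axis=1), 1.0, atol=1e-9
        )

    def test_same_seed_reproducible(self, tiny_lang):
        cfg = ModelConfig.baseline(epochs=2, runs=2, items_per_epoch=200, seed=9)
        r1 = run_condition(tiny_lang, cfg)
        r2 = run_condition(tiny_lang, cfg)
        pd.testing.assert_frame_equal(r1, r2)

    def test_split_half_marks_held_out_verbs(self, tiny_lang):
        cfg = ModelConfig.baseline(epochs=1, runs=3, items_per_epoch=200)
        rec = run_condition(tiny_lang, cfg, ConditionTags(split_half=True))
        per_run = rec.groupby("run")["held_out"].sum()
        # ceil(3/2)=2 train, 1 held out, per epoch
        assert (per_run == 1).all()

    def test_run_averaging_reduces_variance(self, tiny_lang):
        """Variance of a k-run mean is ~1/k of single-run variance (i.i.d. runs)."""
        cfg = ModelConfig.baseline(epochs=1, runs=64, items_per_epoch=100, seed=3)
        rec = run_condition(tiny_lang, cfg)
        x = (
            rec[rec.verb == "laugh"].sort_values("run")["p_less"].to_numpy()
        )
        var_single = x.var(ddof=1)
        group_means = x.reshape(8, 8).mean(axis=1)
        ratio = group_means.var(ddof=1) / var_single
        assert 0.125 / 4 < ratio < 0.125 * 4


class TestHeldOutMeanR:
    def make_records(self, run_offsets):
        """Held-out predictions whose diff = truth + per-run constant."""
        rng = np.random.default_rng(0)
        verbs = [f"v{i}" for i in range(10)]
        truth = pd.Series(np.linspace(-0.8, 0.8, 10), index=verbs)
        rows = []
        for run, off in enumerate(run_offsets):
            for v in verbs:
                d = truth[v] * 0.1 + off
                rows.append((run, 1, v, 0.4 + d / 2, 0.4 - d / 2, 0.2,
                             True, "real", "adult_directed", True))
        cols = ["run", "epoch", "verb", "p_less", "p_more", "p_other",
                "split_half", "semantics", "corpus", "held_out"]
        return pd.DataFrame(rows, columns=cols), truth

    def test_invariant_to_run_level_shifts(self):
        from causnet import held_out_mean_r
        rec0, truth = self.make_records([0.0, 0.0, 0.0])
        rec1, _ = self.make_records([0.05, -0.04, 0.08])
        r0 = held_out_mean_r(rec0, truth)
        r1 = held_out_mean_r(rec1, truth)
        assert r0 == pytest.approx(1.0)
        assert r1 == pytest.approx(r0, abs=1e-12)


class TestGrid:
    def test_full_factorial_count(self):
        assert len(enumerate_grid()) == 2048

    def test_64_configs_per_cell(self):
        cells = enumerate_grid(
            corpora=("x",),
            protocols={"split_half": (False,), "semantics": ("real",)},
        )
        assert len(cells) == 64

    def test_single_combination(self):
        cells = enumerate_grid(
            corpora=("x",),
            grid={"epochs": (2,), "hidden_layers": ((4,),), "dropout": (0.0,),
                  "annealing": (0.0,)},
            protocols={"split_half": (False,), "semantics": ("real",)},
        )
        assert len(cells) == 1

    def test_grid_search_ranks_by_log_loss(self, synth_world):
        _, lang, gt = synth_world
        small = LanguageInput(lang.language, lang.verbs[:10])
        target = pd.Series(
            gt.diff[:10], index=[v.label for v in small.verbs], name="value"
        )
        base = ModelConfig.extended((4,), runs=2, items_per_epoch=300, seed=1)
        result = grid_search(
            {"syn": small},
            grid={"epochs": (1, 3), "hidden_layers": ((4,),),
                  "dropout": (0.0,), "annealing": (0.0,)},
            human_targets={"syn": {"truth": target}},
            base_config=base,
            protocols={"split_half": (False, True), "semantics": ("real", "shuffled")},
        )
        assert len(result) == 8
        assert result["log_loss"].is_monotonic_increasing
        assert list(result["rank"]) == list(range(1, 9))
        assert "r_truth" in result.columns

    def test_grid_search_deterministic(self, synth_world):
        _, lang, _ = synth_world
        small = LanguageInput(lang.language, lang.verbs[:8])
        base = ModelConfig.extended((4,), runs=2, items_per_epoch=200, seed=5)
        kw = dict(
            grid={"epochs": (1,), "hidden_layers": ((4,),), "dropout": (0.0,),
                  "annealing": (0.0,)},
            base_config=base,
            protocols={"split_half": (False,), "semantics": ("real",)},
        )
        pd.testing.assert_frame_equal(
            grid_search({"syn": small}, **kw), grid_search({"syn": small}, **kw)
        )

    def test_missing_human_target_yields_nan_not_error(self, synth_world):
        _, lang, gt = synth_world
        small = LanguageInput(lang.language, lang.verbs[:8])
        target = pd.Series(gt.diff[:8], index=[v.label for v in small.verbs])
        base = ModelConfig.extended((4,), runs=1, items_per_epoch=200, seed=5)
        result = grid_search(
            {"a": small, "b": small},
            grid={"epochs": (1,), "hidden_layers": ((4,),), "dropout": (0.0,),
                  "annealing": (0.0,)},
            human_targets={"a": {"truth": target}},
            base_config=base,
            protocols={"split_half": (False,), "semantics": ("real",)},
        )
        assert result.loc[result.corpus == "b", "r_truth"].isna().all()
        assert result.loc[result.corpus == "a", "r_truth"].notna().all()
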