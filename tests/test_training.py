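import numpy as np
import pytest

from scmpep import (
    GAConfig,
    LabeledDataset,
    Peptide,
    PropensityScoreModel,
    SynthSpec,
    fitness,
    ga_optimize,
    generate,
    initial_propensity_scores,
    run_experiments,
    select_cutoff,
)
from scmpep.datasets import REFERENCE_NONTHP_ROWS, REFERENCE_THP_ROWS
from scmpep.scoring_card import STANDARD_RESIDUES, ScoreCard, score_dataset
from scmpep.training import card_correlation

FAST_GA = dict(population_size=16, generations=12, cv_folds=5)


def tiny_dataset(pos_seqs, neg_seqs):
    return LabeledDataset(
        [Peptide(f"p{i}", s, 1) for i, s in enumerate(pos_seqs)]
        + [Peptide(f"n{i}", s, 0) for i, s in enumerate(neg_seqs)]
    )


class TestInitialPropensityScores:
    def test_pure_contrast_assigns_scale_extremes(self):
        ds = tiny_dataset(["CWCW", "CWCWCW"] * 10, ["IKIK", "IKIKIK"] * 10)
        card = initial_propensity_scores(ds)
        assert {card.scores["C"], card.scores["W"]} == {1000.0}
        assert card.scores["I"] == 0.0 and card.scores["K"] == 0.0
        assert card.origin == "initial"

    def test_scores_span_full_scale_after_rescaling(self, separable_dataset):
        card = initial_propensity_scores(separable_dataset)
        vals = list(card.scores.values())
        assert min(vals) == 0.0 and max(vals) == 1000.0
        assert all(float(v).is_integer() for v in vals)

    def test_identical_classes_flagged_degenerate(self):
        ds = tiny_dataset(["ACDEF"] * 5, ["ACDEF"] * 5)
        with pytest.warns(UserWarning, match="degenerate"):
            card = initial_propensity_scores(ds)
        assert len(set(card.scores.values())) == 1

    def test_ratio_matches_brute_force_on_generated_data(self, separable_dataset):
        """The rescaled card preserves the ordering of hand-computed
        class-composition ratios."""
        card = initial_propensity_scores(separable_dataset)
        pos = [p.seq for p in separable_dataset if p.label == 1]
        neg = [p.seq for p in separable_dataset if p.label == 0]

        def comp(seqs, r):
            counts = sum(s.count(r) for s in seqs)
            total = sum(len(s) for s in seqs)
            return counts / total

        ratios = {}
        for r in STANDARD_RESIDUES:
            p, n = comp(pos, r), comp(neg, r)
            ratios[r] = (p if p else 1e-9) / (n if n else 1e-9)
        order_card = sorted(STANDARD_RESIDUES, key=lambda r: card.scores[r])
        order_ratio = sorted(STANDARD_RESIDUES, key=lambda r: ratios[r])
        # enriched residues must sit at the top in both orderings
        assert set(order_card[-3:]) == set(order_ratio[-3:]) == set("CWR")


class TestFitness:
    def test_self_correlation_gives_point_nine_auc_plus_point_one(self, separable_dataset):
        initial = initial_propensity_scores(separable_dataset)
        cfg = GAConfig(cv_folds=5)
        f = fitness(initial, separable_dataset, initial, cfg)
        from scmpep.evaluation import auc
        a = auc(score_dataset(separable_dataset.sequences, initial),
                separable_dataset.labels)
        assert f == pytest.approx(0.9 * a + 0.1)

    def test_negated_card_has_anticorrelation_term(self, separable_dataset):
        initial = initial_propensity_scores(separable_dataset)
        negated = ScoreCard({r: 1000 - v for r, v in initial.scores.items()})
        assert card_correlation(negated.as_vector(), initial.as_vector()) == pytest.approx(-1.0)

    def test_constant_card_correlation_is_zero_with_warning(self):
        const = np.full(20, 42.0)
        with pytest.warns(UserWarning, match="constant"):
            assert card_correlation(const, np.arange(20.0)) == 0.0

    def test_separable_data_auc_component_is_one(self):
        ds = tiny_dataset(["CWCW"] * 10, ["IKIK"] * 10)
        initial = initial_propensity_scores(ds)
        f = fitness(initial, ds, initial, GAConfig(cv_folds=5))
        assert f == pytest.approx(0.9 * 1.0 + 0.1 * 1.0)


class TestSelectCutoff:
    def test_separable_scores_return_smallest_optimal_cutoff(self):
        scores = [600, 600, 100, 100]
        assert select_cutoff(scores, [1, 1, 0, 0]) == 100

    def test_inverted_labels_best_accuracy_is_half(self):
        scores = [600.0, 600.0, 100.0, 100.0]
        labels = [0, 0, 1, 1]
        c = select_cutoff(scores, labels)
        preds = [1 if s > c else 0 for s in scores]
        acc = np.mean(np.array(preds) == labels)
        assert acc == 0.5

    def test_published_score_columns_perfectly_separated(self, ref_card):
        scores = [r[1] for r in REFERENCE_THP_ROWS] + [r[1] for r in REFERENCE_NONTHP_ROWS]
        labels = [1] * 20 + [0] * 20
        c = select_cutoff(scores, labels)
        preds = [1 if s > c else 0 for s in scores]
        assert preds == labels
        assert 140 <= c < 571  # between max non-THP and min THP scores

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_cutoff([1.0, 2.0], [1, 1])


class TestGAOptimize:
    def test_elitism_makes_best_fitness_non_decreasing(self, separable_dataset):
        res = ga_optimize(separable_dataset, GAConfig(seed=5, **FAST_GA))
        hist = res.fitness_history
        assert all(b >= a for a, b in zip(hist, hist[1:]))

    def test_optimized_fitness_at_least_initial(self, separable_dataset):
        res = ga_optimize(separable_dataset, GAConfig(seed=5, **FAST_GA))
        assert res.optimized_fitness >= res.initial_fitness

    def test_zero_generations_returns_initial_card(self, separable_dataset):
        res = ga_optimize(separable_dataset, GAConfig(seed=5, generations=0, cv_folds=5))
        assert res.optimized_card.scores == res.initial_card.scores
        assert res.optimized_card.cutoff is not None

    def test_parameter_recovery_ranks_enriched_above_depleted(self, separable_dataset):
        res = ga_optimize(separable_dataset, GAConfig(seed=5, **FAST_GA))
        card = res.optimized_card
        assert min(card.scores[r] for r in "CWR") > max(card.scores[r] for r in "IKV")

    def test_genes_stay_clamped_to_scale(self, separable_dataset):
        res = ga_optimize(separable_dataset, GAConfig(seed=5, **FAST_GA))
        vals = list(res.optimized_card.scores.values())
        assert min(vals) >= 0 and max(vals) <= 1000

    def test_bit_reproducible_given_seed(self, separable_dataset):
        cfg = GAConfig(seed=9, population_size=10, generations=5, cv_folds=5)
        r1 = ga_optimize(separable_dataset, cfg)
        r2 = ga_optimize(separable_dataset, cfg)
        assert r1.optimized_card.scores == r2.optimized_card.scores
        assert r1.fitness_history == r2.fitness_history
        assert r1.cv_metrics == r2.cv_metrics

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=1)


class TestRunExperiments:
    def test_runs_use_distinct_seeds_and_sort_by_cv_acc(self, separable_dataset):
        results = run_experiments(separable_dataset, 3,
                                  GAConfig(seed=2, population_size=10,
                                           generations=4, cv_folds=5))
        assert len(results) == 3
        assert {r.experiment_id for r in results} == {1, 2, 3}
        accs = [r.cv_metrics.acc for r in results]
        assert accs == sorted(accs, reverse=True)

    def test_single_run(self, separable_dataset):
        results = run_experiments(separable_dataset, 1,
                                  GAConfig(seed=2, population_size=8,
                                           generations=2, cv_folds=5))
        assert len(results) == 1


class TestModelResultsFrontEnd:
    def test_fit_returns_results_with_summary(self, separable_dataset):
        model = PropensityScoreModel(separable_dataset)
        res = model.fit(seed=3, **FAST_GA)
        text = res.summary()
        assert "cutoff" in text and "fitness" in text and "CV" in text
        assert res.card.cutoff == res.cutoff

    def test_predict_separates_held_out_synthetic_peptides(self, separable_dataset):
        model = PropensityScoreModel(separable_dataset)
        res = model.fit(seed=3, **FAST_GA)
        holdout = generate(SynthSpec(n_pos=40, n_neg=40, bias=8.0, seed=99))
        preds = res.predict(holdout.sequences)
        acc = np.mean(preds == np.array(holdout.labels))
        assert acc >= 0.9

    def test_single_class_data_rejected(self):
        ds = tiny_dataset(["CW"] * 4, ["IK"] * 4)
        PropensityScoreModel(ds)  # fine
        with pytest.raises(ValueError):
            PropensityScoreModel(LabeledDataset([Peptide("p", "CW", 1)] * 4))
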