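"""Propensity-card estimation: composition ratios plus GA refinement.

The initial card is the per-residue ratio of mean positive-class composition
to mean negative-class composition, min-max rescaled to the 0-1000 integer
scale. A genetic algorithm then perturbs the card to maximize

    Fit = w1 * AUC + w2 * R

where AUC is the cross-validated area under the ROC curve of the
weighted-sum scorer and R is the Pearson correlation between the candidate
and the initial card — the correlation term keeps the optimized card
interpretable as a composition propensity. Defaults w1 = 0.9, w2 = 0.1.

The statsmodels-style entry point is :class:`PropensityScoreModel`; the
module-level functions are the underlying operations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .evaluation import MetricSet, auc, cross_validate, stratified_folds
from .scoring_card import (
    STANDARD_RESIDUES,
    ScoreCard,
    classify_score,
    composition_matrix,
    score_dataset,
)
from .sequences_io import LabeledDataset


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm and fitness settings.

    mutation_step is the largest per-gene perturbation (uniform in
    +-mutation_step, applied to genes on the 0-1000 scale). w1/w2 weight the
    cross-validated AUC and the correlation-with-initial terms of the
    fitness.
    """

    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    mutation_step: float = 100.0
    elitism_count: int = 2
    tournament_size: int = 3
    w1: float = 0.9
    w2: float = 0.1
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must be < population_size")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass
class TrainingResult:
    """Outcome of one GA training run."""

    initial_card: ScoreCard
    optimized_card: ScoreCard
    fitness_history: list[float]
    initial_fitness: float
    optimized_fitness: float
    cv_metrics: MetricSet
    experiment_id: int = 0

    def report(self) -> str:
        """JSON run report: cards, fitness trajectory, CV metrics."""
        return json.dumps({
            "experiment_id": self.experiment_id,
            "initial_card": {r: self.initial_card.scores[r] for r in STANDARD_RESIDUES},
            "optimized_card": {r: self.optimized_card.scores[r] for r in STANDARD_RESIDUES},
            "cutoff": self.optimized_card.cutoff,
            "initial_fitness": self.initial_fitness,
            "optimized_fitness": self.optimized_fitness,
            "fitness_history": self.fitness_history,
            "cv_metrics": self.cv_metrics.as_dict(),
        }, indent=2)


def _rescale_0_1000(values: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1000]; a constant vector maps to all-500."""
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        warnings.warn("degenerate card: all residue ratios equal", stacklevel=2)
        return np.full_like(values, 500.0)
    return (values - lo) / (hi - lo) * 1000.0


def class_compositions(train: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Mean residue composition of the positive and negative class."""
    X = composition_matrix(train.sequences)
    y = np.asarray(train.labels)
    if not (y == 1).any() or not (y == 0).any():
        raise ValueError("both classes must be present")
    return X[y == 1].mean(axis=0), X[y == 0].mean(axis=0)


def initial_propensity_scores(train: LabeledDataset) -> ScoreCard:
    """Composition-ratio card: r_i = p_i / n_i, min-max rescaled to 0-1000.

    Residues absent from a class receive a pseudo-composition of
    1/(total residues in that class) before the ratio, so no ratio is 0/0 or
    division by zero. Scores are rounded to integers to match the card's
    printed scale.
    """
    pos_comp, neg_comp = class_compositions(train)
    n_pos_res = sum(len(p.seq) for p in train if p.label == 1)
    n_neg_res = sum(len(p.seq) for p in train if p.label == 0)
    if n_pos_res == 0 or n_neg_res == 0:
        raise ValueError("a class has zero total residues")
    pos = np.where(pos_comp > 0, pos_comp, 1.0 / n_pos_res)
    neg = np.where(neg_comp > 0, neg_comp, 1.0 / n_neg_res)
    ratios = pos / neg
    scaled = np.round(_rescale_0_1000(ratios))
    scores = {r: float(scaled[i]) for i, r in enumerate(STANDARD_RESIDUES)}
    return ScoreCard(scores, origin="initial")


def card_correlation(card_vec: np.ndarray, initial_vec: np.ndarray) -> float:
    """Pearson correlation between two 20-score vectors; 0 if degenerate."""
    if np.std(card_vec) == 0 or np.std(initial_vec) == 0:
        warnings.warn("constant card: correlation undefined, using 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(card_vec, initial_vec)[0, 1])


class _FitnessEvaluator:
    """Precomputes compositions and fold assignment so each candidate card
    costs one matrix-vector product plus a rank statistic."""

    def __init__(self, train: LabeledDataset, initial: ScoreCard, config: GAConfig):
        self.X = composition_matrix(train.sequences)
        self.y = np.asarray(train.labels)
        self.initial_vec = initial.as_vector()
        self.config = config
        self.folds = stratified_folds(self.y, config.cv_folds, config.seed)

    def cv_auc(self, card_vec: np.ndarray) -> float:
        # Pooled out-of-fold AUC. The candidate card is fixed across folds,
        # so pooled out-of-fold scores coincide with scoring all peptides.
        scores = self.X @ card_vec
        return auc(scores, self.y)

    def __call__(self, card_vec: np.ndarray) -> float:
        r = card_correlation(card_vec, self.initial_vec)
        return self.config.w1 * self.cv_auc(card_vec) + self.config.w2 * r


def fitness(card: ScoreCard, train: LabeledDataset, initial: ScoreCard,
            config: GAConfig | None = None) -> float:
    """Fit = w1 * cross-validated AUC + w2 * Pearson R with the initial card."""
    config = config or GAConfig()
    return _FitnessEvaluator(train, initial, config)(card.as_vector())


def select_cutoff(scores: Sequence[float], labels: Sequence[int]) -> int:
    """Integer cutoff maximizing accuracy under the strict-'>' rule.

    Candidates span the integer range of the scores; ties are broken by the
    smallest maximizing cutoff, for determinism.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (y == 1).any() or not (y == 0).any():
        raise ValueError("cutoff selection requires both classes")
    lo = int(np.floor(s.min()))
    hi = int(np.ceil(s.max()))
    candidates = np.arange(lo, hi + 1)
    # predictions: score > cutoff; vectorized over the candidate grid
    pred = s[None, :] > candidates[:, None]
    acc = ((pred == (y == 1)[None, :]).sum(axis=1)) / len(y)
    best = int(np.argmax(acc))  # argmax returns the first (smallest) maximizer
    return int(candidates[best])


def _card_from_vector(vec: np.ndarray, origin: str) -> ScoreCard:
    return ScoreCard({r: float(vec[i]) for i, r in enumerate(STANDARD_RESIDUES)},
                     origin=origin)


def _cutoff_builder(card: ScoreCard):
    """CV card builder that re-selects the cutoff on each training fold,
    keeping the card's scores fixed."""
    def build(fold_train: LabeledDataset) -> ScoreCard:
        s = score_dataset(fold_train.sequences, card)
        return card.with_cutoff(select_cutoff(s, fold_train.labels))
    return build


def ga_optimize(train: LabeledDataset, config: GAConfig | None = None,
                experiment_id: int = 0) -> TrainingResult:
    """Run the full training pipeline: initial card, GA refinement, cutoff.

    The population is seeded with the initial card plus integer perturbations
    of it; tournament selection, uniform crossover and bounded per-gene
    mutation are iterated, with elitism carrying the best individuals
    forward, so the best fitness never decreases. Genes are integers clamped
    to [0, 1000]. The run is reproducible given config.seed.
    """
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    initial = initial_propensity_scores(train)
    evaluate = _FitnessEvaluator(train, initial, config)
    init_vec = initial.as_vector()
    initial_fitness = evaluate(init_vec)

    if config.generations == 0:
        best_vec, best_fit = init_vec.copy(), initial_fitness
        history = [best_fit]
    else:
        pop = np.tile(init_vec, (config.population_size, 1))
        noise = rng.integers(-config.mutation_step, config.mutation_step + 1,
                             size=pop.shape).astype(float)
        noise[0] = 0.0  # keep the unperturbed initial card in the population
        pop = np.clip(pop + noise, 0, 1000)
        fits = np.array([evaluate(ind) for ind in pop])
        history = [float(fits.max())]

        for _ in range(config.generations):
            order = np.argsort(fits)[::-1]
            new_pop = [pop[i].copy() for i in order[:config.elitism_count]]
            while len(new_pop) < config.population_size:
                pa = _tournament(pop, fits, config.tournament_size, rng)
                pb = _tournament(pop, fits, config.tournament_size, rng)
                child = pa.copy()
                if rng.random() < config.crossover_rate:
                    mask = rng.random(20) < 0.5
                    child[mask] = pb[mask]
                mut = rng.random(20) < config.mutation_rate
                if mut.any():
                    step = rng.integers(-config.mutation_step,
                                        config.mutation_step + 1,
                                        size=int(mut.sum())).astype(float)
                    child[mut] = np.clip(child[mut] + step, 0, 1000)
                new_pop.append(child)
            pop = np.array(new_pop)
            fits = np.array([evaluate(ind) for ind in pop])
            history.append(float(fits.max()))

        best_idx = int(np.argmax(fits))
        best_vec, best_fit = np.round(pop[best_idx]), float(fits[best_idx])

    optimized = _card_from_vector(best_vec, origin="optimized")
    train_scores = score_dataset(train.sequences, optimized)
    cutoff = select_cutoff(train_scores, train.labels)
    optimized = optimized.with_cutoff(cutoff)

    cv = cross_validate(train, _cutoff_builder(optimized),
                        k=config.cv_folds, seed=config.seed)
    return TrainingResult(
        initial_card=initial,
        optimized_card=optimized,
        fitness_history=history,
        initial_fitness=initial_fitness,
        optimized_fitness=best_fit,
        cv_metrics=cv,
        experiment_id=experiment_id,
    )


def _tournament(pop: np.ndarray, fits: np.ndarray, size: int,
                rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(0, len(pop), size=size)
    return pop[idx[np.argmax(fits[idx])]]


def run_experiments(train: LabeledDataset, n_runs: int,
                    config: GAConfig | None = None) -> list[TrainingResult]:
    """Independent GA runs with seeds seed+0 .. seed+n_runs-1.

    Results are sorted by cross-validation accuracy (descending) so the
    first element is the selected model.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    config = config or GAConfig()
    results = [
        ga_optimize(train, replace(config, seed=config.seed + i), experiment_id=i + 1)
        for i in range(n_runs)
    ]
    return sorted(results, key=lambda r: r.cv_metrics.acc, reverse=True)


# ---------------------------------------------------------------------------
# Model / Results front end

class PropensityScoreModel:
    """Scoring-card classifier for labeled peptide data.

    Parameters
    ----------
    data
        A :class:`~scmpep.sequences_io.LabeledDataset` with both classes
        present.

    Examples
    --------
    >>> model = PropensityScoreModel(dataset)          # doctest: +SKIP
    >>> res = model.fit(generations=50, seed=1)        # doctest: +SKIP
    >>> print(res.summary())                           # doctest: +SKIP
    """

    def __init__(self, data: LabeledDataset):
        if data.n_positive == 0 or data.n_negative == 0:
            raise ValueError("both classes must be present")
        self.data = data

    @classmethod
    def from_fasta(cls, positives, negatives, name: str = "dataset"):
        from .sequences_io import build_dataset, read_fasta
        return cls(build_dataset(read_fasta(positives, label=1),
                                 read_fasta(negatives, label=0), name=name))

    def initial_card(self) -> ScoreCard:
        return initial_propensity_scores(self.data)

    def fit(self, config: GAConfig | None = None, **kwargs) -> "PropensityScoreResults":
        """Train the card; keyword arguments override GAConfig fields."""
        if config is None:
            config = GAConfig(**kwargs)
        elif kwargs:
            config = replace(config, **kwargs)
        result = ga_optimize(self.data, config)
        return PropensityScoreResults(self, config, result)

    def fit_multiple(self, n_runs: int, config: GAConfig | None = None,
                     **kwargs) -> list["PropensityScoreResults"]:
        """Independent runs, best (by CV accuracy) first."""
        if config is None:
            config = GAConfig(**kwargs)
        elif kwargs:
            config = replace(config, **kwargs)
        return [PropensityScoreResults(self, config, r)
                for r in run_experiments(self.data, n_runs, config)]


class PropensityScoreResults:
    """Fitted scoring card with its training diagnostics."""

    def __init__(self, model: PropensityScoreModel, config: GAConfig,
                 result: TrainingResult):
        self.model = model
        self.config = config
        self._result = result

    @property
    def initial_card(self) -> ScoreCard:
        return self._result.initial_card

    @property
    def card(self) -> ScoreCard:
        return self._result.optimized_card

    @property
    def cutoff(self) -> float:
        return self._result.optimized_card.cutoff  # type: ignore[return-value]

    @property
    def fitness_history(self) -> list[float]:
        return self._result.fitness_history

    @property
    def cv_metrics(self) -> MetricSet:
        return self._result.cv_metrics

    @property
    def training_result(self) -> TrainingResult:
        return self._result

    def predict(self, seqs: Sequence[str], cutoff: float | None = None) -> np.ndarray:
        """Binary calls for new sequences under the fitted card."""
        c = self.cutoff if cutoff is None else cutoff
        s = score_dataset(list(seqs), self.card)
        return np.array([classify_score(v, c) for v in s])

    def score(self, seqs: Sequence[str]) -> np.ndarray:
        return score_dataset(list(seqs), self.card)

    def summary(self) -> str:
        r = self._result
        lines = [
            "Propensity score card (scoring-card method)",
            "=" * 47,
            f"n peptides: {len(self.model.data)} "
            f"({self.model.data.n_positive} pos / {self.model.data.n_negative} neg)",
            f"GA: pop={self.config.population_size} gen={self.config.generations} "
            f"seed={self.config.seed}",
            f"fitness (w1*AUC + w2*R): initial={r.initial_fitness:.4f} "
            f"optimized={r.optimized_fitness:.4f}",
            f"selected cutoff: {self.cutoff:g}",
            "",
            "residue  initial  optimized",
        ]
        opt = self.card.scores
        ini = self.initial_card.scores
        for res in sorted(STANDARD_RESIDUES, key=lambda x: -opt[x]):
            lines.append(f"   {res}     {ini[res]:7.0f}  {opt[res]:9.0f}")
        m = r.cv_metrics
        lines += [
            "",
            f"{self.config.cv_folds}-fold CV: ACC={m.acc:.3f} Sn={m.sn:.3f} "
            f"Sp={m.sp:.3f} MCC={m.mcc:.3f} AUC={m.auc:.3f}",
        ]
        return "\n".join(lines)
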