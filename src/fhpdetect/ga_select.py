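"""Genetic-algorithm wrapper feature selection.

A chromosome is a binary inclusion mask over the 12-feature universe
(four posture angles, three vertical distances, five demographics).  The
fitness of a subset with k included features is

    f = C * ( sum_i N(x_i)/P + perf ) / k

where P is the total feature count, N(x_i) tracks how often feature i has
appeared in chromosomes evaluated so far in the run (a pheromone-like
frequency term), and the performance term ``perf`` compares the wrapped
classifier's correct predictions m of the reference class against that
class's size n in the training labels.  Two orientations of the
performance term are provided:

* ``accuracy_rewarding`` (default): perf = log m − log n, so a subset
  whose model recovers more reference-class subjects scores higher;
* ``paper_literal``: perf = log n − log m, the formula exactly as
  printed in the source methodology, which as written rewards
  misclassification; retained behind a flag for fidelity experiments.

N(x_i) is kept as a *normalised* inclusion frequency by default (raw
count divided by the number of evaluations so far), so the term stays
bounded in [0, 1] and commensurate with the log-performance term for any
run length; the raw cumulative count and a per-generation reset are
available through :class:`GAConfig` (``counter_mode`` / ``counter_scope``)
for sensitivity analyses.  With raw counts the frequency term grows
without bound and eventually drowns the performance signal, collapsing
the selection onto a single most-frequent feature.

m is measured by seeded stratified inner cross-validation of the wrapped
model on the masked columns (pooled over held-out folds), so the wrapper
never scores a subset on data its model trained on.  The reference
category defaults to the *normal* (minority) class: because training
folds are balanced by oversampling, noisy feature subsets drift toward
predicting the majority (FHP) class, so majority-class recall rewards
uninformative subsets, whereas minority-class recall (specificity)
degrades sharply when informative features are missing and is the
discriminating signal.  The reference class is configurable.  Fitness evaluations
are cached by mask — the classifier is retrained once per distinct subset
— while the N counters advance on every evaluation request, cached or not,
so the frequency term evolves exactly as if nothing were cached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import ModelSpec, cross_validate
from .errors import DegenerateLabelsError, EmptySubsetError
from .features import FEATURE_COLUMNS

WORST_FITNESS = -1.0e18


@dataclass
class Chromosome:
    mask: np.ndarray  # dtype bool, length P
    fitness: Optional[float] = None

    @property
    def k(self) -> int:
        return int(self.mask.sum())

    def key(self) -> tuple:
        return tuple(int(b) for b in self.mask)


@dataclass
class FitnessContext:
    """Everything Eq-style fitness needs besides the chromosome itself."""

    P: int                                  # total feature count
    N: np.ndarray                           # per-feature inclusion counters/frequencies
    n: int                                  # reference-class size in training labels
    m: int                                  # correct reference-class predictions
    C: float = 1.0                          # scale factor bounding the fitness
    log_base: str = "natural"               # "natural" | "10"
    orientation: str = "accuracy_rewarding"  # | "paper_literal"

    def __post_init__(self):
        if self.P < 1:
            raise ValueError("P must be >= 1")
        if not 0 <= self.m <= self.n:
            raise ValueError(f"require 0 <= m <= n, got m={self.m}, n={self.n}")


def _log(x: float, base: str) -> float:
    return math.log10(x) if base == "10" else math.log(x)


def fitness(chrom: Chromosome, ctx: FitnessContext) -> float:
    """Subset fitness; higher is better under either orientation (the GA
    always maximises).

    m = 0 makes the log undefined; such chromosomes receive the worst
    possible fitness instead of crashing the run.
    """
    k = chrom.k
    if k == 0:
        raise EmptySubsetError("cannot score an empty feature subset")
    if ctx.m == 0:
        return WORST_FITNESS
    freq = float(ctx.N[chrom.mask].sum()) / ctx.P
    perf = _log(ctx.n, ctx.log_base) - _log(ctx.m, ctx.log_base)
    if ctx.orientation == "accuracy_rewarding":
        perf = -perf
    return ctx.C * (freq + perf) / k


@dataclass
class GAConfig:
    population_size: int = 50
    generations: int = 40
    crossover_prob: float = 0.8
    mutation_prob: Optional[float] = None  # per-bit; default 2/P
    tournament_size: int = 3
    elitism_count: int = 2
    seed: int = 0
    inner_cv_folds: int = 5
    C: float = 1.0
    log_base: str = "natural"
    orientation: str = "accuracy_rewarding"
    reference_class: int = 0  # the normal (minority) class; see module notes
    counter_mode: str = "frequency"  # "frequency" (count/evaluations) | "count"
    counter_scope: str = "run"  # "run" | "generation"

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def evaluate_subset(
    table: pd.DataFrame,
    mask: np.ndarray,
    model_spec: ModelSpec,
    folds: int = 5,
    seed: int = 0,
    *,
    feature_cols: Sequence[str] = tuple(FEATURE_COLUMNS),
    label_col: str = "label",
    reference_class: int = 0,
) -> int:
    """m: correctly predicted reference-class training subjects, pooled over
    the held-out folds of a seeded stratified inner CV of the wrapped model
    on the masked columns.  Deterministic for a fixed seed."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptySubsetError("mask selects no features")
    cols = [c for c, b in zip(feature_cols, mask) if b]
    res = cross_validate(
        table, model_spec, k=folds, seed=seed,
        feature_cols=cols, label_col=label_col,
    )
    y = table.reset_index(drop=True)[label_col].to_numpy(dtype=int)
    ref = (y == reference_class)
    return int(np.sum(res.per_sample_correct & ref))


class _Evaluator:
    """Mask-keyed cache around evaluate_subset; N counters advance on every
    request so caching does not perturb the frequency term."""

    def __init__(self, table, spec, config: GAConfig, feature_cols, label_col):
        self.table = table.reset_index(drop=True)
        self.spec = spec
        self.config = config
        self.feature_cols = list(feature_cols)
        self.label_col = label_col
        self.P = len(self.feature_cols)
        self.N = np.zeros(self.P, dtype=np.int64)
        self.cache: Dict[tuple, int] = {}
        self.scope_evaluations = 0
        y = self.table[label_col].to_numpy(dtype=int)
        self.n_ref = int(np.sum(y == config.reference_class))
        if self.n_ref == 0 or self.n_ref == len(y):
            raise DegenerateLabelsError("reference class absent or universal")
        self.evaluations = 0

    def __call__(self, chrom: Chromosome) -> float:
        self.N[chrom.mask] += 1
        self.evaluations += 1
        self.scope_evaluations += 1
        key = chrom.key()
        if key not in self.cache:
            self.cache[key] = evaluate_subset(
                self.table, chrom.mask, self.spec,
                folds=self.config.inner_cv_folds, seed=self.config.seed,
                feature_cols=self.feature_cols, label_col=self.label_col,
                reference_class=self.config.reference_class,
            )
        counters = self.N.astype(float)
        if self.config.counter_mode == "frequency":
            counters /= max(self.scope_evaluations, 1)
        ctx = FitnessContext(
            P=self.P, N=counters, n=self.n_ref, m=self.cache[key],
            C=self.config.C, log_base=self.config.log_base,
            orientation=self.config.orientation,
        )
        return fitness(chrom, ctx)


def _random_mask(rng: np.random.Generator, P: int) -> np.ndarray:
    while True:
        mask = rng.random(P) < 0.5
        if mask.any():
            return mask


def _mutate(rng: np.random.Generator, mask: np.ndarray, p_bit: float) -> np.ndarray:
    flips = rng.random(mask.size) < p_bit
    out = mask ^ flips
    if not out.any():
        out[rng.integers(mask.size)] = True
    return out


def _crossover(rng: np.random.Generator, a: np.ndarray, b: np.ndarray):
    point = int(rng.integers(1, a.size))
    c1 = np.concatenate([a[:point], b[point:]])
    c2 = np.concatenate([b[:point], a[point:]])
    if not c1.any():
        c1[rng.integers(a.size)] = True
    if not c2.any():
        c2[rng.integers(a.size)] = True
    return c1, c2


def run_ga(
    table: pd.DataFrame,
    model_spec: ModelSpec,
    config: GAConfig,
    *,
    feature_cols: Sequence[str] = tuple(FEATURE_COLUMNS),
    label_col: str = "label",
) -> Tuple[np.ndarray, dict]:
    """Evolve feature masks for one wrapped model.

    Tournament selection, single-point crossover, per-bit mutation and
    elitism; fully reproducible per seed.  Returns the highest-fitness mask
    ever observed and a per-generation history (best/mean fitness, best
    mask), plus run metadata (config echo, evaluation and cache counts).
    """
    rng = np.random.default_rng(config.seed)
    P = len(feature_cols)
    p_bit = config.mutation_prob if config.mutation_prob is not None else 2.0 / P
    evaluator = _Evaluator(table, model_spec, config, feature_cols, label_col)

    pop = [Chromosome(_random_mask(rng, P)) for _ in range(config.population_size)]
    for ch in pop:
        ch.fitness = evaluator(ch)

    best = max(pop, key=lambda c: c.fitness)
    best_mask, best_fit = best.mask.copy(), best.fitness
    history = []

    def record(gen):
        fits = [c.fitness for c in pop]
        history.append({
            "generation": gen,
            "best_fitness": float(max(fits)),
            "mean_fitness": float(np.mean(fits)),
            "best_mask": [int(b) for b in best_mask],
        })

    record(0)
    for gen in range(1, config.generations + 1):
        if config.counter_scope == "generation":
            evaluator.N[:] = 0
            evaluator.scope_evaluations = 0
        elite = sorted(pop, key=lambda c: -c.fitness)[: config.elitism_count]
        children: List[Chromosome] = [Chromosome(e.mask.copy(), e.fitness) for e in elite]
        while len(children) < config.population_size:
            parents = []
            for _ in range(2):
                idx = rng.integers(0, len(pop), size=config.tournament_size)
                parents.append(max((pop[i] for i in idx), key=lambda c: c.fitness))
            m1, m2 = parents[0].mask.copy(), parents[1].mask.copy()
            if rng.random() < config.crossover_prob:
                m1, m2 = _crossover(rng, m1, m2)
            for m in (m1, m2):
                if len(children) < config.population_size:
                    children.append(Chromosome(_mutate(rng, m, p_bit)))
        pop = children
        for ch in pop:
            if ch.fitness is None:  # elites keep their recorded fitness
                ch.fitness = evaluator(ch)
        gen_best = max(pop, key=lambda c: c.fitness)
        if gen_best.fitness > best_fit:
            best_fit = gen_best.fitness
            best_mask = gen_best.mask.copy()
        record(gen)

    meta = {
        "config": {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                   for k, v in vars(config).items()},
        "feature_cols": list(feature_cols),
        "evaluations": evaluator.evaluations,
        "distinct_subsets": len(evaluator.cache),
        "best_fitness": float(best_fit),
        "best_mask": [int(b) for b in best_mask],
        "selected_features": [c for c, b in zip(feature_cols, best_mask) if b],
    }
    return best_mask, {"history": history, "meta": meta}


def select_features_across_models(
    table: pd.DataFrame,
    model_specs: Sequence[ModelSpec],
    config: GAConfig,
    *,
    feature_cols: Sequence[str] = tuple(FEATURE_COLUMNS),
    label_col: str = "label",
    outer_cv_folds: int = 5,
) -> Tuple[ModelSpec, np.ndarray, dict]:
    """Run the GA once per candidate model, then re-score each winner by
    outer CV accuracy on its selected columns; the argmax wins, ties broken
    by candidate order."""
    if not model_specs:
        raise ValueError("need at least one model spec")
    entries = []
    for spec in model_specs:
        # one shared seed: identical specs yield identical masks (tie rule)
        mask, run_report = run_ga(table, spec, config,
                                  feature_cols=feature_cols, label_col=label_col)
        cols = [c for c, b in zip(feature_cols, mask) if b]
        outer = cross_validate(table, spec, k=outer_cv_folds, seed=config.seed,
                               feature_cols=cols, label_col=label_col)
        entries.append({
            "model": spec.name or spec.family,
            "mask": mask,
            "selected_features": cols,
            "outer_cv_accuracy": outer.accuracy,
            "ga": run_report["meta"],
        })
    best_i = max(range(len(entries)), key=lambda i: entries[i]["outer_cv_accuracy"])
    # max() keeps the first argmax, matching the list-order tie rule
    report = {
        "winner": entries[best_i]["model"],
        "winner_index": best_i,
        "comparison": [
            {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in e.items()
             if k != "ga"}
            for e in entries
        ],
        "runs": [e["ga"] for e in entries],
    }
    return model_specs[best_i], entries[best_i]["mask"], report
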