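"""Phase I: training wavelet networks with an elitist (mu + lambda) evolution strategy.

Each generation, lambda offspring are produced by mutating the mu surviving
parents (round-robin); parents and offspring compete together and the mu
best survive.  Fitness is two-dimensional: populations are sorted by
classification accuracy (descending) with mean squared error against the
{0, 1} targets as tie-break (ascending), which favours accurate networks
whose raw outputs also sit close to the targets.

The cross-validation harness :func:`run_phase1` repeats independent
evolutionary runs on each fold's training split and pools the winners into
a classifier pool, one pool per fold, scoring each winner once on the
fold's validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .data import Dataset, Standardizer, two_spiral
from .genome import EWNNGenome, init_genome, mutate
from .wavelets import network_outputs


def derive_seed(*parts: int) -> int:
    """Deterministic child seed from a tuple of integers (master seed,
    fold index, run index, ...); always below 2**31."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class EvalRecord:
    """Dual-criterion fitness of one network on one dataset."""

    accuracy: float
    mse: float


@dataclass
class ESConfig:
    """Evolution-strategy settings.

    ``mu`` parents, ``lam`` offspring per generation, a fixed generation
    budget, per-gene mutation rate and relative perturbation magnitude.
    """

    mu: int = 1
    lam: int = 25
    generations: int = 2000
    mutation_rate: float = 0.01
    mutation_magnitude: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.mu < 1 or self.lam < 1 or self.generations < 1:
            raise ValueError("mu, lam and generations must all be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass(frozen=True)
class GenomeSpec:
    """Architecture template from which random genomes are drawn."""

    n_features: int
    n_wavelons: int
    n_inputs: int | None = None
    wavelet_set: tuple = ("mexican_hat",)

    def build(self, rng) -> EWNNGenome:
        return init_genome(self.n_features, self.n_wavelons,
                           wavelet_set=self.wavelet_set, rng=rng,
                           n_inputs=self.n_inputs)


def evaluate(genome: EWNNGenome, data: Dataset) -> EvalRecord:
    """Accuracy and MSE of one genome on one dataset."""
    if len(data) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    out = network_outputs(genome, data.features)
    pred = out >= 0.5
    return EvalRecord(
        accuracy=float(np.mean(pred == (data.labels == 1))),
        mse=float(np.mean((out - data.labels) ** 2)),
    )


def sort_population(pop):
    """Stable two-dimensional sort: accuracy descending, MSE ascending,
    insertion order as final tie-break.  ``pop`` is a list of
    ``(genome, EvalRecord)`` pairs; the first element of the result is the
    promoted parent."""
    return sorted(pop, key=lambda gr: (-gr[1].accuracy, gr[1].mse))


@dataclass
class EvolveResult:
    genome: EWNNGenome
    record: EvalRecord
    trajectory: list  # best EvalRecord per generation


def evolve(data: Dataset, config: ESConfig, spec: GenomeSpec,
           stop_accuracy: float | None = None) -> EvolveResult:
    """One (mu + lambda) evolutionary run.

    The trajectory holds the best parent's record per generation; by
    elitism its accuracy is non-decreasing.  ``stop_accuracy`` optionally
    ends the run as soon as the best training accuracy reaches the given
    value (the default is the fixed generation budget).
    """
    rng = np.random.default_rng(config.seed)
    parents = [(g, evaluate(g, data))
               for g in (spec.build(rng) for _ in range(config.mu))]
    parents = sort_population(parents)
    trajectory = []
    for _ in range(config.generations):
        offspring = [
            mutate(parents[i % config.mu][0], config.mutation_rate,
                   config.mutation_magnitude, rng)
            for i in range(config.lam)
        ]
        scored = parents + [(g, evaluate(g, data)) for g in offspring]
        parents = sort_population(scored)[: config.mu]
        trajectory.append(parents[0][1])
        if stop_accuracy is not None and parents[0][1].accuracy >= stop_accuracy:
            break
    best, record = parents[0]
    return EvolveResult(best, record, trajectory)


@dataclass
class Phase1Result:
    """Output of the cross-validated Phase I harness."""

    pools: list  # per fold: list of EWNNGenome (one per run)
    manifest: list  # per pooled genome: provenance + train/val records
    fold_val_accuracies: list
    mean_val_accuracy: float
    standardizer: Standardizer | None
    n_folds: int
    n_runs: int


def _fold_indices(data: Dataset, n_folds: int, seed: int):
    y = data.labels
    if data.patient_ids is not None:
        splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True,
                                        random_state=seed % (2 ** 31))
        splits = list(splitter.split(data.features, y, groups=data.patient_ids))
        for tr, va in splits:
            shared = np.intersect1d(np.unique(data.patient_ids[tr]),
                                    np.unique(data.patient_ids[va]))
            if len(shared):
                raise RuntimeError(
                    f"patient {shared[0]!r} spans both sides of a fold split")
        return splits
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                               random_state=seed % (2 ** 31))
    return list(splitter.split(data.features, y))


def run_phase1(train_data: Dataset, n_folds: int, n_runs: int,
               config: ESConfig, spec: GenomeSpec | None = None,
               standardize: bool = True) -> Phase1Result:
    """Cross-validated Phase I: per fold, ``n_runs`` independent evolutions
    on the fold-train split; the best genome of every run joins the fold's
    pool and is scored once on the fold-validation split.

    Folds are stratified by class and grouped by patient when patient ids
    exist.  Features are z-scored on ``train_data`` as a whole (the 90%
    training portion); genomes in the returned pools operate in that
    standardized space and the fitted standardizer is part of the result.
    Per-run seeds derive from ``config.seed`` and the (fold, run) pair, so
    every run is reproducible in isolation.
    """
    if len(train_data) == 0:
        raise ValueError("train_data is empty")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    scaler = Standardizer.fit(train_data.features) if standardize else None
    data = scaler.apply(train_data) if scaler else train_data
    if spec is None:
        spec = GenomeSpec(n_features=data.n_features, n_wavelons=5)
    pools, manifest, fold_accs = [], [], []
    for f, (tr_idx, va_idx) in enumerate(_fold_indices(data, n_folds, config.seed)):
        fold_train = data.subset(tr_idx)
        fold_val = data.subset(va_idx)
        pool = []
        val_accs = []
        for r in range(n_runs):
            run_seed = derive_seed(config.seed, f, r)
            run_cfg = ESConfig(config.mu, config.lam, config.generations,
                               config.mutation_rate, config.mutation_magnitude,
                               seed=run_seed)
            res = evolve(fold_train, run_cfg, spec)
            val = evaluate(res.genome, fold_val)
            pool.append(res.genome)
            val_accs.append(val.accuracy)
            manifest.append({
                "fold": f, "run": r, "seed": run_seed,
                "train_accuracy": res.record.accuracy,
                "train_mse": res.record.mse,
                "val_accuracy": val.accuracy, "val_mse": val.mse,
            })
        pools.append(pool)
        fold_accs.append(float(np.mean(val_accs)))
    return Phase1Result(
        pools=pools, manifest=manifest, fold_val_accuracies=fold_accs,
        mean_val_accuracy=float(np.mean(fold_accs)),
        standardizer=scaler, n_folds=n_folds, n_runs=n_runs,
    )


@dataclass
class SpiralBenchResult:
    solved: bool
    best_accuracy: float
    restarts_used: int
    generations_used: int  # within the solving (or last) restart
    genome: EWNNGenome
    trajectory: list


def learn_two_spiral(restarts: int = 20, generations: int = 2000,
                     points_per_spiral: int = 97, n_wavelons: int = 2,
                     n_inputs: int = 6, lam: int = 25, seed: int = 0,
                     wavelet_set: tuple = ("morlet",)) -> SpiralBenchResult:
    """Multi-restart attempt to separate the two-spiral benchmark with a
    compact Morlet network (default: at most two wavelons).

    Each restart runs an independent (1 + lam) evolution on the
    standardized spiral data and stops early once training accuracy reaches
    100%.  Six input slots per wavelon are used so each wavelon can stack
    several Morlet factors of the two coordinates, which is what gives a
    two-wavelon network enough oscillatory capacity for the task.
    """
    data = two_spiral(points_per_spiral)
    data = Standardizer.fit(data.features).apply(data)
    spec = GenomeSpec(n_features=2, n_wavelons=n_wavelons,
                      n_inputs=n_inputs, wavelet_set=tuple(wavelet_set))
    best = None
    for r in range(restarts):
        cfg = ESConfig(mu=1, lam=lam, generations=generations,
                       seed=derive_seed(seed, r))
        res = evolve(data, cfg, spec, stop_accuracy=1.0)
        if best is None or res.record.accuracy > best[1].record.accuracy:
            best = (r, res)
        if res.record.accuracy >= 1.0:
            return SpiralBenchResult(True, 1.0, r + 1, len(res.trajectory),
                                     res.genome, res.trajectory)
    r, res = best
    return SpiralBenchResult(False, res.record.accuracy, restarts,
                             len(res.trajectory), res.genome, res.trajectory)
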