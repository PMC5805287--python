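"""Phase II: majority-vote ensembles and genetic-algorithm pruning.

A pool of trained networks is pruned by evolving a k-bit mask (bit m set =
classifier m votes) under a (3 + 25) elitist strategy.  The pruning fitness
averages two accuracies measured on the training set U only:

    ``F(mask) = 0.5 * (Tr_acc + Ens(U))``

where ``Tr_acc`` is the mean individual training accuracy of the active
classifiers and ``Ens(U)`` the accuracy of their strict-majority vote.  The
held-out set V is touched exactly once, after the search, to report the
winning ensemble's test metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import metrics as _metrics
from .data import Dataset
from .genome import EWNNGenome
from .wavelets import classify_batch


class EmptyEnsembleError(ValueError):
    """A vote was requested from a mask with no active classifier."""


class ClassifierPool:
    """Ordered, immutable collection of trained genomes."""

    def __init__(self, genomes):
        self.genomes = list(genomes)
        if not self.genomes:
            raise ValueError("classifier pool is empty")

    def __len__(self):
        return len(self.genomes)

    def __iter__(self):
        return iter(self.genomes)

    def __getitem__(self, i) -> EWNNGenome:
        return self.genomes[i]

    def predictions(self, X) -> np.ndarray:
        """(pool_size, n_records) matrix of binary votes."""
        return np.stack([classify_batch(g, X) for g in self.genomes])


@dataclass
class EnsembleMask:
    """Bit string selecting active pool members."""

    bits: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.int64)
        if self.bits.ndim != 1:
            raise ValueError("mask bits must be 1-D")
        if np.any((self.bits != 0) & (self.bits != 1)):
            raise ValueError("mask bits must be 0/1")

    def __len__(self):
        return len(self.bits)


def active_count(mask: EnsembleMask) -> int:
    """Number of set bits (active classifiers)."""
    return int(np.sum(mask.bits))


def majority_vote(votes) -> int:
    """Strict-majority combination of k binary votes: 1 iff the number of
    1-votes strictly exceeds k/2; an even split returns 0."""
    votes = np.asarray(votes)
    k = len(votes)
    if k == 0:
        raise EmptyEnsembleError("empty ensemble")
    return int(np.sum(votes) > k / 2.0)


def ensemble_vote(pool: ClassifierPool, mask: EnsembleMask, x) -> int:
    """Majority vote of the mask's active classifiers on one sample."""
    if len(mask) != len(pool):
        raise ValueError("mask length does not match pool size")
    active = np.flatnonzero(mask.bits)
    if len(active) == 0:
        raise EmptyEnsembleError("empty ensemble")
    from .wavelets import classify
    return majority_vote([classify(pool[i], x) for i in active])


def ensemble_predictions(pool_predictions: np.ndarray,
                         mask_bits: np.ndarray) -> np.ndarray:
    """Vectorised majority vote given a precomputed vote matrix."""
    active = np.flatnonzero(mask_bits)
    if len(active) == 0:
        raise EmptyEnsembleError("empty ensemble")
    k = len(active)
    return (pool_predictions[active].sum(axis=0) > k / 2.0).astype(int)


class _FitnessCache:
    """Precomputed per-classifier votes and accuracies on U, so a mask's
    fitness is a cheap popcount-style reduction."""

    def __init__(self, pool: ClassifierPool, U: Dataset):
        self.P = pool.predictions(U.features)
        self.indiv_acc = (self.P == U.labels).mean(axis=1)
        self.labels = U.labels

    def fitness(self, bits: np.ndarray) -> float:
        active = np.flatnonzero(bits)
        if len(active) == 0:
            return 0.0  # degenerate mask: penalised, never raised
        tr_acc = float(self.indiv_acc[active].mean())
        ens = ensemble_predictions(self.P, bits)
        ens_acc = float(np.mean(ens == self.labels))
        return 0.5 * (tr_acc + ens_acc)


def prune_fitness(mask: EnsembleMask, pool: ClassifierPool, U: Dataset) -> float:
    """``0.5 * (Tr_acc + Ens(U))`` for one mask; the empty mask scores 0."""
    if not isinstance(pool, ClassifierPool):
        pool = ClassifierPool(pool)
    if len(mask) != len(pool):
        raise ValueError("mask length does not match pool size")
    return _FitnessCache(pool, U).fitness(mask.bits)


@dataclass
class PruneConfig:
    """Settings of the Phase II genetic algorithm.

    ``mutation`` selects the offspring operator: ``"flip"`` inverts each bit
    independently at ``mutation_rate`` (the default realisation of bit-level
    mutation: inversion changes ensemble membership, which is the point of
    pruning); ``"swap"`` exchanges the contents of randomly chosen bit
    pairs, the number of swaps being Binomial(k, rate).
    """

    mu: int = 3
    lam: int = 25
    generations: int = 1000
    mutation_rate: float = 0.01
    seed: int = 0
    mutation: str = "flip"

    def __post_init__(self):
        if self.mu < 1 or self.lam < 1 or self.generations < 1:
            raise ValueError("mu, lam and generations must all be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.mutation not in ("flip", "swap"):
            raise ValueError("mutation must be 'flip' or 'swap'")


def _mutate_bits(bits: np.ndarray, rate: float, rng, mode: str) -> np.ndarray:
    if mode == "flip":
        hit = rng.random(len(bits)) < rate
        return np.where(hit, 1 - bits, bits)
    out = bits.copy()
    n_swaps = rng.binomial(len(bits), rate)
    for _ in range(n_swaps):
        i, j = rng.integers(0, len(bits), 2)
        out[i], out[j] = out[j], out[i]
    return out


def _sort_key(entry):
    fitness, n_active, order = entry[1], entry[2], entry[3]
    # maximise fitness; prefer smaller ensembles on ties; stable otherwise
    return (-fitness, n_active, order)


@dataclass
class PruneResult:
    mask: EnsembleMask
    fitness: float
    fitness_trajectory: list
    ete_acc: float
    sensitivity: float
    specificity: float
    mcc: float
    confusion: _metrics.ConfusionCounts
    test_predictions: np.ndarray


def prune(pool, U: Dataset, V: Dataset, config: PruneConfig) -> PruneResult:
    """(3 + 25)-style elitist GA over ensemble masks.

    Fitness is evaluated on ``U`` only; ``V`` enters exactly once, after the
    final generation, to score the winning mask (ensemble test accuracy,
    sensitivity, specificity and MCC under the control-positive
    convention).  Identical seeds give identical masks.
    """
    if not isinstance(pool, ClassifierPool):
        pool = ClassifierPool(pool)
    if len(U) == 0 or len(V) == 0:
        raise ValueError("U and V must be nonempty")
    rng = np.random.default_rng(config.seed)
    cache = _FitnessCache(pool, U)
    k = len(pool)
    counter = 0

    def entry(bits):
        nonlocal counter
        counter += 1
        return (bits, cache.fitness(bits), int(bits.sum()), counter)

    parents = sorted((entry(rng.integers(0, 2, k)) for _ in range(config.mu)),
                     key=_sort_key)
    trajectory = []
    for _ in range(config.generations):
        offspring = [
            entry(_mutate_bits(parents[i % config.mu][0], config.mutation_rate,
                               rng, config.mutation))
            for i in range(config.lam)
        ]
        parents = sorted(parents + offspring, key=_sort_key)[: config.mu]
        trajectory.append(parents[0][1])

    best_bits, best_fitness = parents[0][0], parents[0][1]
    mask = EnsembleMask(best_bits)
    # the single post-search touch of the test set
    pred_V = ensemble_predictions(pool.predictions(V.features), best_bits)
    m = _metrics.classification_metrics(V.labels, pred_V, positive_class=0)
    return PruneResult(
        mask=mask, fitness=best_fitness, fitness_trajectory=trajectory,
        ete_acc=m["accuracy"], sensitivity=m["sensitivity"],
        specificity=m["specificity"], mcc=m["mcc"], confusion=m["confusion"],
        test_predictions=pred_V,
    )


def enumerate_best_fitness(pool, U: Dataset) -> tuple[float, EnsembleMask]:
    """Brute-force oracle: the maximum pruning fitness over all nonempty
    masks of a (small) pool, ties broken toward fewer active classifiers."""
    if not isinstance(pool, ClassifierPool):
        pool = ClassifierPool(pool)
    k = len(pool)
    if k > 20:
        raise ValueError("enumeration oracle is limited to pools of <= 20")
    cache = _FitnessCache(pool, U)
    best = None
    for code in range(1, 2 ** k):
        bits = np.array([(code >> i) & 1 for i in range(k)], dtype=np.int64)
        f = cache.fitness(bits)
        key = (-f, int(bits.sum()))
        if best is None or key < best[0]:
            best = (key, bits)
    return -best[0][0], EnsembleMask(best[1])
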