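"""Model/Results facade over the two-phase system, statsmodels style.

:class:`EWNNModel` holds a dataset plus an architecture and ``fit()`` runs
one evolutionary training, returning :class:`EWNNResults` with the evolved
genome, the fitness trajectory and evaluation helpers.

:class:`TwoPhaseModel` is the full pipeline: a stratified (patient-grouped)
90/10 holdout, cross-validated Phase I producing one classifier pool per
fold, and a Phase II genetic pruning of each pool whose winning ensemble is
scored once on the held-out test set.  :class:`TwoPhaseResults` aggregates
the per-fold outcomes and prints a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics as _metrics
from .data import Dataset, Standardizer, holdout_split
from .ensemble import ClassifierPool, PruneConfig, PruneResult, prune
from .evolve import (ESConfig, EvalRecord, GenomeSpec, derive_seed, evaluate,
                     evolve, run_phase1)
from .genome import EWNNGenome
from .report import ensemble_size_summary
from .wavelets import classify_batch, network_outputs


class EWNNModel:
    """A wavelet network architecture bound to a training dataset.

    Parameters
    ----------
    data : Dataset
        Training data; features are z-scored internally by default.
    n_wavelons : int
        Hidden-layer size (4-5 is typical for the clinical benchmarks).
    n_inputs : int, optional
        Input slots per wavelon; defaults to the feature count.
    wavelet_set : tuple of str
        Allowed activation functions; a single entry gives a homogeneous
        network, several entries a heterogeneous one.
    standardize : bool
        Fit a per-feature z-score on ``data`` and train in that space.
    """

    def __init__(self, data: Dataset, n_wavelons: int = 5,
                 n_inputs: int | None = None,
                 wavelet_set: tuple = ("mexican_hat",),
                 standardize: bool = True):
        self.data = data
        self.scaler = Standardizer.fit(data.features) if standardize else None
        self._train = self.scaler.apply(data) if self.scaler else data
        self.spec = GenomeSpec(n_features=data.n_features,
                               n_wavelons=n_wavelons, n_inputs=n_inputs,
                               wavelet_set=tuple(wavelet_set))

    def fit(self, mu: int = 1, lam: int = 25, generations: int = 2000,
            mutation_rate: float = 0.01, mutation_magnitude: float = 0.1,
            seed: int = 0, stop_accuracy: float | None = None) -> "EWNNResults":
        cfg = ESConfig(mu=mu, lam=lam, generations=generations,
                       mutation_rate=mutation_rate,
                       mutation_magnitude=mutation_magnitude, seed=seed)
        res = evolve(self._train, cfg, self.spec, stop_accuracy=stop_accuracy)
        return EWNNResults(self, res.genome, res.record, res.trajectory, cfg)


@dataclass
class EWNNResults:
    """One evolved network plus its training diagnostics."""

    model: EWNNModel
    genome: EWNNGenome
    train_record: EvalRecord
    trajectory: list
    config: ESConfig

    def _transform(self, X):
        X = np.asarray(X, dtype=float)
        return self.model.scaler.transform(X) if self.model.scaler else X

    def decision_function(self, X) -> np.ndarray:
        """Raw network outputs for a feature matrix in original units."""
        return network_outputs(self.genome, self._transform(X))

    def predict(self, X) -> np.ndarray:
        """Binary labels (0 = control, 1 = diseased)."""
        return classify_batch(self.genome, self._transform(X))

    def evaluate(self, data: Dataset, aggregate: bool = False) -> dict:
        """Metrics on a dataset; with ``aggregate=True`` predictions are
        collapsed to one label per patient before scoring."""
        pred = self.predict(data.features)
        truth = data.labels
        if aggregate:
            if data.patient_ids is None:
                raise ValueError("dataset has no patient ids to aggregate")
            _, pred = _metrics.aggregate_patients(pred, data.patient_ids)
            _, truth = _metrics.aggregate_patients(truth, data.patient_ids)
        return _metrics.classification_metrics(truth, pred, positive_class=0)

    def summary(self) -> str:
        spec = self.model.spec
        active = sum(w.active for w in self.genome.wavelons)
        lines = [
            "Evolved Wavelet Neural Network",
            "==============================",
            f"wavelons: {spec.n_wavelons} ({active} active)",
            f"input slots per wavelon: {self.genome.n_inputs}",
            f"wavelet set: {', '.join(spec.wavelet_set)}",
            f"ES: ({self.config.mu}+{self.config.lam}), "
            f"{len(self.trajectory)} generations run",
            f"training accuracy: {self.train_record.accuracy:.4f}",
            f"training MSE: {self.train_record.mse:.4f}",
        ]
        return "\n".join(lines)


class TwoPhaseModel:
    """Holdout + cross-validated Phase I + genetically pruned ensembles.

    ``fit`` performs, in order: a stratified (patient-grouped) holdout of
    ``test_fraction``; Phase I cross-validation on the training portion
    (``n_folds`` folds x ``n_runs`` independent evolutions, pooling each
    run's winner); and, per fold, a Phase II GA pruning of the pool with
    fitness measured on the training portion, the held-out test set being
    scored once per fold at the very end.
    """

    def __init__(self, data: Dataset, n_wavelons: int = 5,
                 n_inputs: int | None = None,
                 wavelet_set: tuple = ("mexican_hat",),
                 n_folds: int = 10, n_runs: int = 50,
                 test_fraction: float = 0.10, standardize: bool = True):
        self.data = data
        self.n_folds = n_folds
        self.n_runs = n_runs
        self.test_fraction = test_fraction
        self.standardize = standardize
        self.n_wavelons = n_wavelons
        self.n_inputs = n_inputs
        self.wavelet_set = tuple(wavelet_set)

    def fit(self, mu: int = 1, lam: int = 25, generations: int = 2000,
            mutation_rate: float = 0.01, mutation_magnitude: float = 0.1,
            prune_generations: int = 1000, seed: int = 0) -> "TwoPhaseResults":
        train, test = holdout_split(self.data, self.test_fraction, seed=seed)
        cfg = ESConfig(mu=mu, lam=lam, generations=generations,
                       mutation_rate=mutation_rate,
                       mutation_magnitude=mutation_magnitude, seed=seed)
        spec = GenomeSpec(n_features=self.data.n_features,
                          n_wavelons=self.n_wavelons, n_inputs=self.n_inputs,
                          wavelet_set=self.wavelet_set)
        phase1 = run_phase1(train, self.n_folds, self.n_runs, cfg, spec,
                            standardize=self.standardize)
        scaler = phase1.standardizer
        train_s = scaler.apply(train) if scaler else train
        test_s = scaler.apply(test) if scaler else test
        prune_results = []
        for f, pool_genomes in enumerate(phase1.pools):
            pcfg = PruneConfig(generations=prune_generations,
                               seed=derive_seed(seed, 10_000 + f))
            prune_results.append(prune(ClassifierPool(pool_genomes),
                                       train_s, test_s, pcfg))
        # mean individual test accuracy across every pooled classifier
        indiv = [evaluate(g, test_s).accuracy
                 for pool in phase1.pools for g in pool]
        return TwoPhaseResults(
            model=self, phase1=phase1, prune_results=prune_results,
            train=train, test=test, standardizer=scaler,
            mean_individual_test_accuracy=float(np.mean(indiv)), seed=seed,
        )


@dataclass
class TwoPhaseResults:
    """Aggregated outcome of the two-phase pipeline."""

    model: TwoPhaseModel
    phase1: object
    prune_results: list
    train: Dataset
    test: Dataset
    standardizer: Standardizer | None
    mean_individual_test_accuracy: float
    seed: int

    @property
    def te_acc(self) -> float:
        """Phase I mean cross-validation accuracy of individual networks."""
        return self.phase1.mean_val_accuracy

    @property
    def ete_acc(self) -> float:
        """Mean ensemble test accuracy across folds (record level)."""
        return float(np.mean([r.ete_acc for r in self.prune_results]))

    @property
    def sens(self) -> float:
        return float(np.nanmean([r.sensitivity for r in self.prune_results]))

    @property
    def spec(self) -> float:
        return float(np.nanmean([r.specificity for r in self.prune_results]))

    @property
    def mcc(self) -> float:
        return float(np.mean([r.mcc for r in self.prune_results]))

    @property
    def masks(self) -> list:
        return [r.mask for r in self.prune_results]

    @property
    def mean_active(self) -> float:
        """Average number of active classifiers in the pruned ensembles."""
        return ensemble_size_summary(self.masks)

    def patient_level_metrics(self) -> dict:
        """Test metrics after per-patient strict-majority aggregation,
        pooled over folds (requires patient ids)."""
        if self.test.patient_ids is None:
            raise ValueError("test data has no patient ids")
        accs, all_metrics = [], []
        _, truth = _metrics.aggregate_patients(self.test.labels,
                                               self.test.patient_ids)
        for r in self.prune_results:
            _, pred = _metrics.aggregate_patients(r.test_predictions,
                                                  self.test.patient_ids)
            all_metrics.append(
                _metrics.classification_metrics(truth, pred, positive_class=0))
        return {
            "accuracy": float(np.mean([m["accuracy"] for m in all_metrics])),
            "sensitivity": float(np.nanmean([m["sensitivity"] for m in all_metrics])),
            "specificity": float(np.nanmean([m["specificity"] for m in all_metrics])),
            "mcc": float(np.mean([m["mcc"] for m in all_metrics])),
        }

    def summary(self, name: str = "dataset") -> str:
        lines = [
            "Two-phase evolutionary wavelet-network ensemble",
            "===============================================",
            f"records: {len(self.model.data)} "
            f"(train {len(self.train)}, test {len(self.test)})",
            f"phase I: {self.phase1.n_folds} folds x {self.phase1.n_runs} runs",
            f"phase II: {len(self.prune_results)} pruned ensembles, "
            f"mean active classifiers {self.mean_active:.2f} "
            f"of {self.phase1.n_runs}",
            "",
            _metrics.METRICS_HEADER,
            _metrics.metrics_row(name, self.te_acc, self.ete_acc,
                                 self.sens, self.spec, self.mcc),
        ]
        return "\n".join(lines)
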