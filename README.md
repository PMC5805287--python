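# ewnn — evolutionary wavelet neural network ensembles

`ewnn` builds binary disease classifiers for tabular biomedical data
(pre-extracted mammography features, repeated voice measurements from
Parkinson's patients, and similar record-per-visit datasets) out of
**wavelet neural networks trained by evolution** and combined into
**compact majority-vote ensembles selected by a genetic algorithm**.

It is aimed at researchers who want a transparent, fully reproducible
reference implementation of this model family: every training step is
seeded, every evolved network is a plain-text genome, and the synthetic
data generators let the whole pipeline run end to end without any external
dataset.

## The model

A wavelet neural network (WNN) is a single-hidden-layer network whose
hidden units — *wavelons* — apply a wavelet function to a weighted,
translated, dilated and rotated combination of selected inputs. For a
wavelon *m* with active input slots *A* the response is

    z_n  = (w_n · x_sel(n) − β_n) / max(α_n, 10⁻³)
    z'_n = z_n + R_n · z_succ(n)          (cyclic over active slots)
    Ψ_m(x) = ∏_{n∈A} ψ(z'_n)

with ψ one of Morlet `cos(5t)·exp(−t²/2)`, Mexican hat
`(1−t²)·exp(−t²/2)`, the first Gaussian derivative, or Haar. The network
output adds a bias θ and direct input-to-output shortcut connections:

    f(x) = θ + Σ_m wt_m · Ψ_m(x) + Σ_n a_n · x_n,     ŷ = 1[f(x) ≥ 0.5]

Nothing is trained by gradients. **Phase I** evolves the complete genome
(feature selection switches, weights, dilations, translations, rotations,
wavelet identities, unit-activity bits, shortcuts, bias) with an elitist
(μ+λ) evolution strategy under two-dimensional sorting — accuracy
descending, then mean squared error ascending — inside a stratified,
patient-grouped cross-validation that pools the winner of each independent
run into a classifier pool. **Phase II** prunes each pool with a (3+25)
genetic algorithm over bit masks, maximising

    F(mask) = ½ · (Tr_acc + Ens(U))

the average of the active classifiers' mean individual training accuracy
and their strict-majority-vote ensemble accuracy on the training set; the
held-out test set is scored exactly once, after the search.

Reported metrics (accuracy, sensitivity, specificity, Matthews correlation
coefficient) follow the biomedical convention in which the **control class
is the positive class**, and record-level predictions can be collapsed to
one diagnosis per patient by strict majority of that patient's records.

## Worked example

```python
from ewnn.data import synth_clinical
from ewnn.model import TwoPhaseModel

data = synth_clinical(n_patients=40, records_per_patient=8, n_features=8,
                      effect_size=1.0, within_patient_corr=0.4, seed=77)
model = TwoPhaseModel(data, n_wavelons=5, n_inputs=6, n_folds=3, n_runs=10)
res = model.fit(generations=200, prune_generations=1000, seed=77)
print(res.summary(name="synthetic"))
```

prints (runs in about a minute and a half on one CPU):

```
Two-phase evolutionary wavelet-network ensemble
===============================================
records: 320 (train 288, test 32)
phase I: 3 folds x 10 runs
phase II: 3 pruned ensembles, mean active classifiers 3.00 of 10

dataset	Te_acc	ETe_acc	Sens	Spec	MCC
synthetic	62.3	75.0	89.6	60.4	53.4
```

`Te_acc` (62.3%) is the mean cross-validation accuracy of the individual
evolved networks; `ETe_acc` (75.0%) is the mean held-out test accuracy of
the pruned majority-vote ensembles — the ensemble clearly improves on its
members (their mean test accuracy is 57.4%). Sensitivity, specificity and
MCC are computed on the test set under the control-positive convention.
The GA kept 3 of the 10 available networks per ensemble. Collapsing
record-level votes to one diagnosis per patient,
`res.patient_level_metrics()` gives accuracy 83.3% on this example.

The same pipeline is available from the shell:

```bash
ewnn gen-clinical --patients 40 --records 8 --features 8 --out clin.csv
ewnn train --data clin.csv --patient-column patient_id --wavelons 5 \
     --runs 10 --folds 3 --generations 200 --seed 77 --out pool.json
ewnn prune --pool pool.json --fold 0 --train clin.csv --test clin.csv \
     --patient-column patient_id --seed 77 --out mask.json
ewnn report --pool pool.json --mask mask.json
```

## Layout

| module | contents |
| --- | --- |
| `ewnn.wavelets` | wavelet functions and the network forward pass |
| `ewnn.genome` | genome encoding, initialisation, mutation, JSON serialisation |
| `ewnn.evolve` | (μ+λ) evolution strategy and the cross-validated Phase I harness |
| `ewnn.ensemble` | majority voting, pruning fitness, the Phase II GA |
| `ewnn.metrics` | confusion-matrix statistics, patient aggregation, report rows |
| `ewnn.data` | dataset container, two-spiral and clinical generators, CSV I/O, splits |
| `ewnn.report` | feature connectivity, wavelon dimensionality, ensemble sizes |
| `ewnn.model` | `EWNNModel`/`TwoPhaseModel` fit façades with `Results.summary()` |
| `ewnn.cli` | the `ewnn` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
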