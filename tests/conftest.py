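import math

import numpy as np
import pytest

from ewnn.genome import EWNNGenome, WavelonGene


def build_wavelon(features, switches, weights=None, scales=None,
                  translations=None, rotations=None, wavelet="mexican_hat",
                  weight=1.0, active=1):
    """Hand-construct a wavelon; unspecified arrays default to neutral
    values (w=1, alpha=1, beta=0, R=0)."""
    n = len(features)
    return WavelonGene(
        features=np.asarray(features),
        switches=np.asarray(switches),
        weights=np.ones(n) if weights is None else np.asarray(weights, float),
        scales=np.ones(n) if scales is None else np.asarray(scales, float),
        translations=np.zeros(n) if translations is None else np.asarray(translations, float),
        rotations=np.zeros(n) if rotations is None else np.asarray(rotations, float),
        wavelet=wavelet,
        weight=weight,
        active=active,
    )


def build_genome(wavelons, n_features, shortcut=None, bias=0.0,
                 wavelet_set=("mexican_hat", "morlet", "gauss1", "haar")):
    return EWNNGenome(
        wavelons=list(wavelons),
        shortcut_weights=np.zeros(n_features) if shortcut is None
        else np.asarray(shortcut, float),
        bias=bias,
        wavelet_set=wavelet_set,
        n_features=n_features,
    )


# ---------------------------------------------------------------------------
# Independent scalar-loop oracle for the network forward pass, written with
# math.* only (no shared code with the vectorised implementation).
# ---------------------------------------------------------------------------

def _psi_scalar(name, t):
    if name == "mexican_hat":
        return (1.0 - t * t) * math.exp(-0.5 * t * t)
    if name == "morlet":
        return math.cos(5.0 * t) * math.exp(-0.5 * t * t)
    if name == "gauss1":
        return -t * math.exp(-0.5 * t * t)
    if name == "haar":
        if 0.0 <= t < 0.5:
            return 1.0
        if 0.5 <= t < 1.0:
            return -1.0
        return 0.0
    raise KeyError(name)


def naive_network_output(genome, x):
    """Reference forward pass: plain Python loops over slots and wavelons."""
    total = float(genome.bias)
    for a_n, x_n in zip(genome.shortcut_weights, x):
        total += float(a_n) * float(x_n)
    for wv in genome.wavelons:
        if not wv.active:
            continue
        slots = [i for i in range(wv.n_inputs) if wv.switches[i] == 1]
        if not slots:
            continue
        z = {}
        for i in slots:
            alpha = max(float(wv.scales[i]), 1e-3)
            z[i] = (float(wv.weights[i]) * float(x[wv.features[i]])
                    - float(wv.translations[i])) / alpha
        prod = 1.0
        for pos, i in enumerate(slots):
            if len(slots) == 1:
                zp = z[i]
            else:
                succ = slots[(pos + 1) % len(slots)]
                zp = z[i] + float(wv.rotations[i]) * z[succ]
            prod *= _psi_scalar(wv.wavelet, zp)
        total += float(wv.weight) * prod
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
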