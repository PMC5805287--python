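"""Wavelet activation functions and the forward response of a wavelet neural network.

A wavelet neural network (WNN) is a single-hidden-layer feed-forward network
whose hidden units -- *wavelons* -- apply a wavelet basis function to a
weighted, translated, dilated and rotated combination of a subset of the
inputs.  The output neuron sums the weighted wavelon responses, direct
input-to-output *shortcut* connections and a bias term.

Everything in this module is a pure function of a genome (see
:mod:`ewnn.genome`) and a feature vector/matrix; all parameters are set by
the evolution strategy in :mod:`ewnn.evolve`, never by gradients.
"""

from __future__ import annotations

import numpy as np

#: Dilation floor.  Scale genes are initialised uniformly in [0, 1] and may
#: reach 0; every wavelet argument divides by ``max(alpha, ALPHA_MIN)`` so
#: the forward pass is always finite.
ALPHA_MIN = 1e-3

#: Carrier frequency of the Morlet wavelet, the standard choice that makes
#: the function close to admissible while keeping a recognisable envelope.
MORLET_FREQ = 5.0


def _finite(t):
    a = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("invalid wavelet argument")
    return a


def _match(out: np.ndarray, t):
    # return a bare float for scalar input, an array otherwise
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def mexican_hat(t):
    """Mexican hat wavelet ``psi(t) = (1 - t^2) exp(-t^2 / 2)``.

    Even, maximal at ``t = 0`` with ``psi(0) = 1`` and zero crossings at
    ``t = +/-1``.
    """
    a = _finite(t)
    return _match((1.0 - a * a) * np.exp(-0.5 * a * a), t)


def morlet(t):
    """Morlet wavelet ``psi(t) = cos(5 t) exp(-t^2 / 2)``.

    Even; a cosine carrier under a Gaussian envelope, so
    ``|psi(t)| <= exp(-t^2/2)``.
    """
    a = _finite(t)
    return _match(np.cos(MORLET_FREQ * a) * np.exp(-0.5 * a * a), t)


def gauss1(t):
    """First derivative of a Gaussian, ``psi(t) = -t exp(-t^2 / 2)`` (odd)."""
    a = _finite(t)
    return _match(-a * np.exp(-0.5 * a * a), t)


def haar(t):
    """Haar wavelet: 1 on [0, 1/2), -1 on [1/2, 1), 0 elsewhere."""
    a = _finite(t)
    out = np.where((a >= 0.0) & (a < 0.5), 1.0, np.where((a >= 0.5) & (a < 1.0), -1.0, 0.0))
    return _match(out, t)


#: Registry of the available wavelet activations, keyed by name.
WAVELETS = {
    "morlet": morlet,
    "mexican_hat": mexican_hat,
    "gauss1": gauss1,
    "haar": haar,
}

#: Heterogeneous four-function set used for the mammography-style runs.
DEFAULT_WAVELET_SET = ("morlet", "mexican_hat", "gauss1", "haar")


def wavelon_responses(wavelon, X: np.ndarray) -> np.ndarray:
    """Response of one wavelon for every row of ``X`` (records x features).

    For the active input slots ``A = {n : c_n = 1}`` the wavelet argument is

        ``z_n  = (w_n * x_{sel(n)} - beta_n) / max(alpha_n, ALPHA_MIN)``
        ``z'_n = z_n + R_n * z_{succ(n)}``

    where ``sel(n)`` is the feature index chosen by slot ``n`` and
    ``succ(n)`` the next active slot cyclically (``z' = z`` when only one
    slot is active).  The response is the product ``prod_n psi(z'_n)``.
    A wavelon with no active slot, or with its activity bit cleared,
    contributes exactly 0 so that pruned units are silent.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not wavelon.active:
        return np.zeros(n)
    act = np.asarray(wavelon.switches, dtype=bool)
    k = int(act.sum())
    if k == 0:
        return np.zeros(n)
    sel = np.asarray(wavelon.features)[act]
    if sel.max(initial=0) >= X.shape[1]:
        raise ValueError(
            f"wavelon selects feature {int(sel.max())} but input has only "
            f"{X.shape[1]} features"
        )
    w = np.asarray(wavelon.weights, dtype=float)[act]
    beta = np.asarray(wavelon.translations, dtype=float)[act]
    alpha = np.maximum(np.asarray(wavelon.scales, dtype=float)[act], ALPHA_MIN)
    z = (w * X[:, sel] - beta) / alpha
    if k > 1:
        rot = np.asarray(wavelon.rotations, dtype=float)[act]
        z = z + rot * z[:, np.r_[1:k, 0]]
    psi = WAVELETS[wavelon.wavelet]
    return psi(z).prod(axis=1)


def wavelon_response(wavelon, x) -> float:
    """Scalar wavelon response for a single feature vector ``x``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a 1-D feature vector")
    return float(wavelon_responses(wavelon, x[None, :])[0])


def network_outputs(genome, X: np.ndarray) -> np.ndarray:
    """Raw network output ``theta + sum_m wt_m Psi_m(x) + sum_n a_n x_n``
    for every row of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != genome.n_features:
        raise ValueError(
            f"expected a (records, {genome.n_features}) feature matrix, got shape {X.shape}"
        )
    out = genome.bias + X @ np.asarray(genome.shortcut_weights, dtype=float)
    for wv in genome.wavelons:
        if wv.active:
            out = out + wv.weight * wavelon_responses(wv, X)
    return out


def network_output(genome, x) -> float:
    """Raw network output for a single feature vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a 1-D feature vector")
    return float(network_outputs(genome, x[None, :])[0])


def classify_batch(genome, X: np.ndarray) -> np.ndarray:
    """Binary labels for every row of ``X``; output >= 0.5 maps to class 1."""
    return (network_outputs(genome, X) >= 0.5).astype(int)


def classify(genome, x) -> int:
    """Binary label for one feature vector (threshold 0.5 on the raw output)."""
    return int(network_output(genome, x) >= 0.5)
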