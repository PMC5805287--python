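"""Post-hoc structural analyses of classifier pools and pruned ensembles.

Two structural summaries recur when interpreting evolved wavelet networks:
how often each input feature is actually wired into the hidden layer
(feature connectivity), and how many distinct features each hidden unit
reads (wavelon dimensionality).  Both count a connection only when the
wavelon's activity bit is set *and* the slot's switch is on -- silent
wavelons contribute nothing to the network output and are therefore not
counted as structure.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .ensemble import ClassifierPool, EnsembleMask


def _genome_list(pool, mask: EnsembleMask | None = None):
    genomes = list(pool.genomes if isinstance(pool, ClassifierPool) else pool)
    if mask is not None:
        if len(mask) != len(genomes):
            raise ValueError("mask length does not match pool size")
        genomes = [g for g, b in zip(genomes, mask.bits) if b]
        if not genomes:
            raise ValueError("mask selects no classifiers")
    if not genomes:
        raise ValueError("empty classifier collection")
    return genomes


def _connected_features(wavelon) -> set:
    """Distinct features wired into an *active* wavelon (empty if silent)."""
    if not wavelon.active:
        return set()
    on = np.asarray(wavelon.switches, dtype=bool)
    return set(int(f) for f in np.asarray(wavelon.features)[on])


def feature_connectivity(pool, mask: EnsembleMask | None = None) -> np.ndarray:
    """Mean number of active wavelons connected to each feature.

    For each network the per-feature count is the number of active wavelons
    with at least one switched-on slot selecting that feature (so values
    lie in [0, n_wavelons]); the result averages those counts over the
    collection (optionally restricted to the mask's active classifiers).
    """
    genomes = _genome_list(pool, mask)
    n_features = genomes[0].n_features
    counts = np.zeros(n_features)
    for g in genomes:
        for wv in g.wavelons:
            for f in _connected_features(wv):
                counts[f] += 1
    return counts / len(genomes)


def wavelon_dimensionality(pool, mask: EnsembleMask | None = None) -> dict:
    """Histogram of active-wavelon dimensionality across a collection.

    A wavelon's dimensionality is the number of distinct features it reads
    through switched-on slots.  Only active wavelons are counted; the
    returned dict maps dimensionality -> count, and its values sum to the
    total number of active wavelons in the collection.
    """
    genomes = _genome_list(pool, mask)
    hist: Counter = Counter()
    for g in genomes:
        for wv in g.wavelons:
            if wv.active:
                hist[len(_connected_features(wv))] += 1
    return dict(sorted(hist.items()))


def ensemble_size_summary(masks) -> float:
    """Mean number of active classifiers over a collection of masks."""
    masks = list(masks)
    if not masks:
        raise ValueError("no masks given")
    return float(np.mean([np.sum(np.asarray(m.bits if isinstance(m, EnsembleMask) else m))
                          for m in masks]))


def connectivity_table(pool, mask: EnsembleMask | None = None,
                       feature_names=None) -> str:
    """Tab-separated feature-connectivity report."""
    conn = feature_connectivity(pool, mask)
    names = feature_names or [f"f{j}" for j in range(len(conn))]
    lines = ["feature\tmean_connections"]
    lines += [f"{n}\t{c:.4f}" for n, c in zip(names, conn)]
    return "\n".join(lines)


def dimensionality_table(pool, mask: EnsembleMask | None = None) -> str:
    """Tab-separated wavelon-dimensionality histogram."""
    hist = wavelon_dimensionality(pool, mask)
    lines = ["dimensionality\tcount"]
    lines += [f"{d}\t{c}" for d, c in hist.items()]
    return "\n".join(lines)


def plot_connectivity(pool, mask: EnsembleMask | None = None,
                      feature_names=None, ax=None):
    """Bar chart of mean connections per feature (requires matplotlib)."""
    import matplotlib.pyplot as plt

    conn = feature_connectivity(pool, mask)
    names = feature_names or [f"f{j}" for j in range(len(conn))]
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(range(len(conn)), conn)
    ax.set_xticks(range(len(conn)), names, rotation=90)
    ax.set_ylabel("mean connections per feature")
    return ax


def plot_dimensionality(pool, mask: EnsembleMask | None = None, ax=None):
    """Bar chart of the wavelon-dimensionality histogram (matplotlib)."""
    import matplotlib.pyplot as plt

    hist = wavelon_dimensionality(pool, mask)
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(list(hist), list(hist.values()))
    ax.set_xlabel("wavelon dimensionality")
    ax.set_ylabel("count of active wavelons")
    return ax
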