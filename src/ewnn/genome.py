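"""Genome encoding for evolutionary wavelet neural networks.

The genome is a direct encoding of every trainable quantity of the network:
per wavelon a vector of input slots (each slot selects a feature index and
carries a connection switch, an input weight, a dilation, a translation and
a rotation gene), the wavelet identity, the wavelon output weight and an
activity bit; plus the shortcut weights and the output bias.  Evolution
uses mutation only -- there is no crossover -- so this module provides
initialisation, mutation, equality and (de)serialisation.

Parameter ranges
----------------
==================  =============  =========================
gene                range          mutation class
==================  =============  =========================
feature index       [0, Feat)      categorical (resample)
switch c            {0, 1}         binary (invert)
input weight w      [-1, +1]       continuous
dilation alpha      [0, 1]         continuous
translation beta    unbounded      continuous (never clamped)
rotation R          [-1, +1]       continuous
wavelet id          wavelet set    categorical (resample)
wavelon weight wt   [-1, +1]       continuous
activity bit ot     {0, 1}         binary
shortcut weight a   [-1, +1]       continuous
bias theta          [-1, +1]       continuous
==================  =============  =========================

Translations are initialised ``Normal(0, 1)``: an unbounded uniform does not
exist and, with standardized features, unit-scale translations are the
useful region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .wavelets import DEFAULT_WAVELET_SET, WAVELETS

SCHEMA_VERSION = 1

WEIGHT_RANGE = (-1.0, 1.0)
SCALE_RANGE = (0.0, 1.0)
ROTATION_RANGE = (-1.0, 1.0)
WAVELON_WEIGHT_RANGE = (-1.0, 1.0)
BIAS_RANGE = (-1.0, 1.0)
SHORTCUT_RANGE = (-1.0, 1.0)

#: Additive kick, uniform in +/-ZERO_KICK, applied when a continuous gene
#: selected for mutation is exactly zero (a relative perturbation could
#: never move it).
ZERO_KICK = 0.01


class GenomeError(ValueError):
    """A genome violates its structural or range invariants."""


class GenomeParseError(GenomeError):
    """Serialized genome text is malformed."""


@dataclass
class WavelonGene:
    """All genes of a single hidden unit.

    Arrays are indexed by input *slot*; the number of slots is fixed at
    construction and may differ from the number of dataset features (each
    slot's ``features`` entry says which feature it reads, and slots may
    repeat a feature).
    """

    features: np.ndarray
    switches: np.ndarray
    weights: np.ndarray
    scales: np.ndarray
    translations: np.ndarray
    rotations: np.ndarray
    wavelet: str
    weight: float
    active: int

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.int64)
        self.switches = np.asarray(self.switches, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.weight = float(self.weight)
        self.active = int(self.active)

    @property
    def n_inputs(self) -> int:
        return len(self.features)

    def copy(self) -> "WavelonGene":
        return WavelonGene(
            self.features.copy(), self.switches.copy(), self.weights.copy(),
            self.scales.copy(), self.translations.copy(), self.rotations.copy(),
            self.wavelet, self.weight, self.active,
        )


@dataclass
class EWNNGenome:
    """Complete parameterisation of one wavelet neural network."""

    wavelons: list
    shortcut_weights: np.ndarray
    bias: float
    wavelet_set: tuple
    n_features: int

    def __post_init__(self):
        self.shortcut_weights = np.asarray(self.shortcut_weights, dtype=float)
        self.bias = float(self.bias)
        self.wavelet_set = tuple(self.wavelet_set)
        self.n_features = int(self.n_features)

    @property
    def n_wavelons(self) -> int:
        return len(self.wavelons)

    @property
    def n_inputs(self) -> int:
        return self.wavelons[0].n_inputs if self.wavelons else 0

    def copy(self) -> "EWNNGenome":
        return EWNNGenome(
            [w.copy() for w in self.wavelons], self.shortcut_weights.copy(),
            self.bias, self.wavelet_set, self.n_features,
        )

    def validate(self) -> None:
        """Raise :class:`GenomeError` naming the first violated invariant."""
        if not self.wavelons:
            raise GenomeError("genome has no wavelons")
        if not self.wavelet_set:
            raise GenomeError("wavelet_set is empty")
        for name in self.wavelet_set:
            if name not in WAVELETS:
                raise GenomeError(f"unknown wavelet id {name!r}")
        if len(self.shortcut_weights) != self.n_features:
            raise GenomeError("shortcut_weights length does not match n_features")
        _check_range("bias", np.asarray([self.bias]), *BIAS_RANGE)
        _check_range("shortcut_weights", self.shortcut_weights, *SHORTCUT_RANGE)
        n_inputs = self.wavelons[0].n_inputs
        for m, wv in enumerate(self.wavelons):
            tag = f"wavelon {m}"
            for arr_name in ("features", "switches", "weights", "scales",
                             "translations", "rotations"):
                if len(getattr(wv, arr_name)) != n_inputs:
                    raise GenomeError(f"{tag}: {arr_name} has inconsistent length")
            if wv.wavelet not in self.wavelet_set:
                raise GenomeError(f"{tag}: wavelet {wv.wavelet!r} not in wavelet_set")
            if np.any((wv.features < 0) | (wv.features >= self.n_features)):
                raise GenomeError(f"{tag}: feature index out of range [0, {self.n_features})")
            if np.any((wv.switches != 0) & (wv.switches != 1)):
                bad = wv.switches[(wv.switches != 0) & (wv.switches != 1)][0]
                raise GenomeError(f"{tag}: switch value {int(bad)} is not 0/1")
            if wv.active not in (0, 1):
                raise GenomeError(f"{tag}: active flag {wv.active} is not 0/1")
            _check_range(f"{tag}: weights", wv.weights, *WEIGHT_RANGE)
            _check_range(f"{tag}: scales", wv.scales, *SCALE_RANGE)
            _check_range(f"{tag}: rotations", wv.rotations, *ROTATION_RANGE)
            _check_range(f"{tag}: weight", np.asarray([wv.weight]), *WAVELON_WEIGHT_RANGE)
            if not np.all(np.isfinite(wv.translations)):
                raise GenomeError(f"{tag}: translations contain non-finite values")


def _check_range(name: str, arr: np.ndarray, lo: float, hi: float) -> None:
    if not np.all(np.isfinite(arr)):
        raise GenomeError(f"{name}: non-finite value")
    if np.any(arr < lo) or np.any(arr > hi):
        raise GenomeError(f"{name}: value outside [{lo}, {hi}]")


def genomes_equal(a: EWNNGenome, b: EWNNGenome) -> bool:
    """Exact (bit-for-bit) equality of two genomes."""
    if (a.n_features != b.n_features or a.wavelet_set != b.wavelet_set
            or a.n_wavelons != b.n_wavelons or a.bias != b.bias):
        return False
    if not np.array_equal(a.shortcut_weights, b.shortcut_weights):
        return False
    for wa, wb in zip(a.wavelons, b.wavelons):
        if wa.wavelet != wb.wavelet or wa.weight != wb.weight or wa.active != wb.active:
            return False
        for arr_name in ("features", "switches", "weights", "scales",
                         "translations", "rotations"):
            if not np.array_equal(getattr(wa, arr_name), getattr(wb, arr_name)):
                return False
    return True


def init_genome(n_features: int, n_wavelons: int,
                wavelet_set=DEFAULT_WAVELET_SET, rng=None,
                n_inputs: int | None = None) -> EWNNGenome:
    """Draw a random genome, every bounded gene uniform within its range.

    ``n_inputs`` is the number of input slots per wavelon; it defaults to
    ``n_features`` (one slot per feature) but may differ, in which case each
    slot independently selects a feature index.
    """
    if n_features < 1 or n_wavelons < 1:
        raise GenomeError("n_features and n_wavelons must be >= 1")
    wavelet_set = tuple(wavelet_set)
    if not wavelet_set:
        raise GenomeError("wavelet_set is empty")
    for name in wavelet_set:
        if name not in WAVELETS:
            raise GenomeError(f"unknown wavelet id {name!r}")
    if n_inputs is None:
        n_inputs = n_features
    rng = np.random.default_rng(rng)
    wavelons = []
    for _ in range(n_wavelons):
        wavelons.append(WavelonGene(
            features=rng.integers(0, n_features, n_inputs),
            switches=rng.integers(0, 2, n_inputs),
            weights=rng.uniform(*WEIGHT_RANGE, n_inputs),
            scales=rng.uniform(*SCALE_RANGE, n_inputs),
            translations=rng.normal(0.0, 1.0, n_inputs),
            rotations=rng.uniform(*ROTATION_RANGE, n_inputs),
            wavelet=wavelet_set[int(rng.integers(len(wavelet_set)))],
            weight=rng.uniform(*WAVELON_WEIGHT_RANGE),
            active=int(rng.integers(0, 2)),
        ))
    return EWNNGenome(
        wavelons=wavelons,
        shortcut_weights=rng.uniform(*SHORTCUT_RANGE, n_features),
        bias=rng.uniform(*BIAS_RANGE),
        wavelet_set=wavelet_set,
        n_features=n_features,
    )


def _perturb(arr, rate, magnitude, rng, bounds=None):
    """Continuous-gene mutation: with probability ``rate`` per gene add a
    relative ``U(-magnitude, +magnitude)`` perturbation (an additive
    ``U(-ZERO_KICK, +ZERO_KICK)`` kick when the gene is exactly zero), then
    clamp to ``bounds`` if given."""
    arr = np.asarray(arr, dtype=float)
    hit = rng.random(arr.shape) < rate
    rel = rng.uniform(-magnitude, magnitude, arr.shape)
    kick = rng.uniform(-ZERO_KICK, ZERO_KICK, arr.shape)
    delta = np.where(arr == 0.0, kick, rel * arr)
    out = np.where(hit, arr + delta, arr)
    if bounds is not None:
        out = np.clip(out, *bounds)
    return out


def _flip(bits, rate, rng):
    hit = rng.random(bits.shape) < rate
    return np.where(hit, 1 - bits, bits)


def _resample_indices(idx, n_options, rate, rng):
    """Categorical mutation: selected genes are replaced by a uniform draw
    among the *other* options (no-op when only one option exists)."""
    idx = np.asarray(idx, dtype=np.int64)
    hit = rng.random(idx.shape) < rate
    if n_options < 2:
        return idx.copy()
    draw = rng.integers(0, n_options - 1, idx.shape)
    draw = draw + (draw >= idx)
    return np.where(hit, draw, idx)


def mutate(genome: EWNNGenome, rate: float, magnitude: float = 0.1,
           rng=None) -> EWNNGenome:
    """Return a mutated copy of ``genome``; the parent is left untouched.

    Every gene is independently selected with probability ``rate``;
    continuous genes get a relative perturbation (clamped back to range,
    translations excepted), binary genes are inverted, categorical genes
    are resampled among the remaining options.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must be in [0, 1]")
    rng = np.random.default_rng(rng)
    wavelet_set = genome.wavelet_set
    wavelons = []
    for wv in genome.wavelons:
        features = _resample_indices(wv.features, genome.n_features, rate, rng)
        switches = _flip(wv.switches, rate, rng)
        weights = _perturb(wv.weights, rate, magnitude, rng, WEIGHT_RANGE)
        scales = _perturb(wv.scales, rate, magnitude, rng, SCALE_RANGE)
        translations = _perturb(wv.translations, rate, magnitude, rng)
        rotations = _perturb(wv.rotations, rate, magnitude, rng, ROTATION_RANGE)
        w_idx = wavelet_set.index(wv.wavelet)
        new_idx = int(_resample_indices(np.asarray([w_idx]), len(wavelet_set), rate, rng)[0])
        weight = float(_perturb(np.asarray([wv.weight]), rate, magnitude, rng,
                                WAVELON_WEIGHT_RANGE)[0])
        active = int(_flip(np.asarray([wv.active]), rate, rng)[0])
        wavelons.append(WavelonGene(features, switches, weights, scales,
                                    translations, rotations,
                                    wavelet_set[new_idx], weight, active))
    shortcut = _perturb(genome.shortcut_weights, rate, magnitude, rng, SHORTCUT_RANGE)
    bias = float(_perturb(np.asarray([genome.bias]), rate, magnitude, rng, BIAS_RANGE)[0])
    return EWNNGenome(wavelons, shortcut, bias, wavelet_set, genome.n_features)


def count_genes(genome: EWNNGenome) -> int:
    """Total number of evolvable genes in the genome."""
    per_wavelon = 6 * genome.n_inputs + 3  # slot arrays + wavelet id, wt, ot
    return genome.n_wavelons * per_wavelon + genome.n_features + 1


# ---------------------------------------------------------------------------
# Serialization: JSON with an explicit schema version; numbers round-trip
# exactly (Python's float repr is shortest-round-trip).
# ---------------------------------------------------------------------------

def genome_to_dict(genome: EWNNGenome) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "n_features": genome.n_features,
        "wavelet_set": list(genome.wavelet_set),
        "bias": genome.bias,
        "shortcut_weights": [float(v) for v in genome.shortcut_weights],
        "wavelons": [
            {
                "features": [int(v) for v in wv.features],
                "switches": [int(v) for v in wv.switches],
                "weights": [float(v) for v in wv.weights],
                "scales": [float(v) for v in wv.scales],
                "translations": [float(v) for v in wv.translations],
                "rotations": [float(v) for v in wv.rotations],
                "wavelet": wv.wavelet,
                "weight": wv.weight,
                "active": wv.active,
            }
            for wv in genome.wavelons
        ],
    }


def genome_from_dict(d: dict) -> EWNNGenome:
    try:
        wavelons = [
            WavelonGene(
                features=w["features"], switches=w["switches"],
                weights=w["weights"], scales=w["scales"],
                translations=w["translations"], rotations=w["rotations"],
                wavelet=w["wavelet"], weight=w["weight"], active=w["active"],
            )
            for w in d["wavelons"]
        ]
        genome = EWNNGenome(
            wavelons=wavelons,
            shortcut_weights=d["shortcut_weights"],
            bias=d["bias"],
            wavelet_set=d["wavelet_set"],
            n_features=d["n_features"],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise GenomeParseError(f"malformed genome record: {exc}") from exc
    try:
        genome.validate()
    except GenomeError as exc:
        raise GenomeParseError(str(exc)) from exc
    return genome


def serialize(genome: EWNNGenome) -> str:
    """Genome -> JSON text (exact round trip with :func:`deserialize`)."""
    return json.dumps(genome_to_dict(genome), indent=1)


def deserialize(text: str) -> EWNNGenome:
    """JSON text -> genome; malformed input raises :class:`GenomeParseError`
    naming the offending field."""
    try:
        d = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GenomeParseError(f"invalid JSON: {exc}") from exc
    return genome_from_dict(d)


def save_genome(genome: EWNNGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write(serialize(genome))


def load_genome(path) -> EWNNGenome:
    with open(path) as fh:
        return deserialize(fh.read())


def save_pool(path, genomes, manifest=None, standardizer=None) -> None:
    """Write a classifier pool: an array of genomes plus an optional
    manifest (per-genome provenance records) and feature standardizer."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "genomes": [genome_to_dict(g) for g in genomes],
        "manifest": manifest,
        "standardizer": standardizer,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_pool(path):
    """Read a pool file; returns ``(genomes, manifest, standardizer)``."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise GenomeParseError(f"invalid JSON: {exc}") from exc
    try:
        records = payload["genomes"]
    except (KeyError, TypeError) as exc:
        raise GenomeParseError("pool file lacks a 'genomes' array") from exc
    genomes = [genome_from_dict(d) for d in records]
    return genomes, payload.get("manifest"), payload.get("standardizer")
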