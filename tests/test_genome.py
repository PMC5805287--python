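import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewnn.genome import (GenomeError, GenomeParseError, count_genes,
                         deserialize, genome_to_dict, genomes_equal,
                         init_genome, load_pool, mutate, save_pool, serialize)
from ewnn.wavelets import network_output

from conftest import build_genome, build_wavelon


class TestInit:
    def test_structure_matches_request(self):
        g = init_genome(6, 4, ("morlet", "mexican_hat", "gauss1", "haar"), rng=1)
        assert g.n_wavelons == 4
        assert g.n_features == 6
        for wv in g.wavelons:
            for arr in (wv.features, wv.switches, wv.weights, wv.scales,
                        wv.translations, wv.rotations):
                assert len(arr) == 6
        g.validate()

    def test_same_seed_same_genome(self):
        a = init_genome(4, 3, rng=77, n_inputs=5)
        b = init_genome(4, 3, rng=77, n_inputs=5)
        assert genomes_equal(a, b)
        assert serialize(a) == serialize(b)

    def test_empty_wavelet_set_rejected(self):
        with pytest.raises(GenomeError, match="wavelet_set"):
            init_genome(2, 2, wavelet_set=(), rng=0)

    def test_monte_carlo_range_audit(self):
        rng = np.random.default_rng(5)
        lo = {k: np.inf for k in ("w", "alpha", "R", "wt", "a", "theta")}
        hi = {k: -np.inf for k in lo}
        for _ in range(10_000):
            g = init_genome(3, 2, rng=rng, n_inputs=2)
            for wv in g.wavelons:
                lo["w"], hi["w"] = min(lo["w"], wv.weights.min()), max(hi["w"], wv.weights.max())
                lo["alpha"], hi["alpha"] = min(lo["alpha"], wv.scales.min()), max(hi["alpha"], wv.scales.max())
                lo["R"], hi["R"] = min(lo["R"], wv.rotations.min()), max(hi["R"], wv.rotations.max())
                lo["wt"], hi["wt"] = min(lo["wt"], wv.weight), max(hi["wt"], wv.weight)
            lo["a"], hi["a"] = min(lo["a"], g.shortcut_weights.min()), max(hi["a"], g.shortcut_weights.max())
            lo["theta"], hi["theta"] = min(lo["theta"], g.bias), max(hi["theta"], g.bias)
        for k in ("w", "R", "wt", "a", "theta"):
            assert -1.0 <= lo[k] and hi[k] <= 1.0
            assert lo[k] < -0.99 and hi[k] > 0.99  # the full range is explored
        assert 0.0 <= lo["alpha"] and hi["alpha"] <= 1.0


class TestMutate:
    def test_rate_zero_is_identity(self):
        g = init_genome(4, 3, rng=3)
        assert genomes_equal(mutate(g, 0.0, rng=1), g)

    def test_parent_unmodified(self):
        g = init_genome(4, 3, rng=3)
        snapshot = serialize(g)
        mutate(g, 1.0, rng=1)
        assert serialize(g) == snapshot

    def test_rate_one_inverts_all_binary_genes(self):
        g = init_genome(3, 2, rng=9)
        for wv in g.wavelons:
            wv.switches[:] = 1
            wv.active = 1
        m = mutate(g, 1.0, rng=4)
        for wv in m.wavelons:
            assert np.all(wv.switches == 0)
            assert wv.active == 0

    def test_rate_one_changes_every_two_member_categorical(self):
        # with exactly two features and two wavelets, every categorical gene
        # must switch to the other member
        g = init_genome(2, 3, ("morlet", "haar"), rng=11, n_inputs=4)
        m = mutate(g, 1.0, rng=5)
        for wv_old, wv_new in zip(g.wavelons, m.wavelons):
            assert np.all(wv_new.features == 1 - wv_old.features)
            assert wv_new.wavelet != wv_old.wavelet

    def test_mutation_rate_is_per_gene(self):
        # every gene strictly inside its range, none exactly zero, so a hit
        # always changes the value: total changes ~ Binomial(G * K, rate)
        wavelons = [
            build_wavelon([0, 1, 2, 0], [1, 0, 1, 0],
                          weights=[0.3] * 4, scales=[0.3] * 4,
                          translations=[0.3] * 4, rotations=[0.3] * 4,
                          wavelet="morlet", weight=0.3, active=1)
            for _ in range(2)
        ]
        g = build_genome(wavelons, n_features=3, shortcut=[0.3, 0.3, 0.3],
                         bias=0.3, wavelet_set=("morlet", "haar"))
        G = count_genes(g)
        assert G == 2 * (6 * 4 + 3) + 3 + 1
        rate, K = 0.05, 1500
        rng = np.random.default_rng(12)
        changes = 0
        for _ in range(K):
            m = mutate(g, rate, rng=rng)
            a, b = genome_to_dict(g), genome_to_dict(m)
            for wa, wb in zip(a["wavelons"], b["wavelons"]):
                for key in ("features", "switches", "weights", "scales",
                            "translations", "rotations"):
                    changes += sum(x != y for x, y in zip(wa[key], wb[key]))
                changes += (wa["wavelet"] != wb["wavelet"])
                changes += (wa["weight"] != wb["weight"])
                changes += (wa["active"] != wb["active"])
            changes += sum(x != y for x, y in
                           zip(a["shortcut_weights"], b["shortcut_weights"]))
            changes += (a["bias"] != b["bias"])
        expected = rate * G * K
        se = np.sqrt(G * K * rate * (1 - rate))
        assert abs(changes - expected) < 3 * se

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), rate=st.floats(0.0, 1.0),
           magnitude=st.floats(0.0, 1.0))
    def test_ranges_preserved_under_repeated_mutation(self, seed, rate, magnitude):
        rng = np.random.default_rng(seed)
        g = init_genome(3, 2, rng=rng, n_inputs=3)
        for _ in range(3):
            g = mutate(g, rate, magnitude, rng=rng)
        g.validate()  # raises if any bounded gene escaped its range

    def test_invalid_rate_rejected(self):
        g = init_genome(2, 1, rng=0)
        with pytest.raises(ValueError):
            mutate(g, 1.5, rng=0)


class TestSerialization:
    def test_round_trip_is_exact(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            g = init_genome(4, 3, rng=rng, n_inputs=2)
            g = mutate(g, 0.5, rng=rng)  # include unclamped translations
            assert genomes_equal(deserialize(serialize(g)), g)

    def test_handwritten_minimal_genome(self):
        text = json.dumps({
            "schema_version": 1,
            "n_features": 2,
            "wavelet_set": ["mexican_hat"],
            "bias": 0.25,
            "shortcut_weights": [0.0, 0.0],
            "wavelons": [{
                "features": [0, 1], "switches": [1, 0],
                "weights": [1.0, 0.0], "scales": [1.0, 1.0],
                "translations": [0.0, 0.0], "rotations": [0.0, 0.0],
                "wavelet": "mexican_hat", "weight": 1.0, "active": 1,
            }],
        })
        g = deserialize(text)
        # wavelon reduces to psi(x0): output = 0.25 + psi(0) = 1.25
        assert network_output(g, [0.0, 5.0]) == pytest.approx(1.25)

    def test_invalid_switch_value_is_parse_error(self):
        g = init_genome(2, 1, rng=0)
        d = genome_to_dict(g)
        d["wavelons"][0]["switches"][0] = 2
        with pytest.raises(GenomeParseError, match="switch"):
            deserialize(json.dumps(d))

    def test_missing_field_is_parse_error(self):
        g = init_genome(2, 1, rng=0)
        d = genome_to_dict(g)
        del d["wavelons"][0]["scales"]
        with pytest.raises(GenomeParseError, match="scales"):
            deserialize(json.dumps(d))

    def test_garbage_text_is_parse_error(self):
        with pytest.raises(GenomeParseError, match="JSON"):
            deserialize("not json {")

    def test_pool_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        genomes = [init_genome(3, 2, rng=rng) for _ in range(4)]
        manifest = [{"fold": 0, "run": r, "seed": r} for r in range(4)]
        path = tmp_path / "pool.json"
        save_pool(path, genomes, manifest=manifest,
                  standardizer={"mean": [0.0] * 3, "sd": [1.0] * 3})
        loaded, mani, std = load_pool(path)
        assert len(loaded) == 4
        assert all(genomes_equal(a, b) for a, b in zip(genomes, loaded))
        assert mani == manifest
        assert std["sd"] == [1.0, 1.0, 1.0]
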