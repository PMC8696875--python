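"""The logistic MLP: published weights, forward pass, splitting, training."""

import json
import math

import numpy as np
import pandas as pd
import pytest

import honeypower as hp
from honeypower.ann import (
    DegenerateRangeError,
    NormalizationSpec,
    _largest_remainder_sizes,
    logistic,
)
from .conftest import random_weights


class TestPublishedWeights:
    def test_spot_values_match_the_printed_tables(self, published):
        assert published.w1[0, 0] == -5.138      # L* -> neuron 1
        assert published.w1[2, 9] == -0.243      # free acidity -> neuron 10
        assert published.w2[5] == 43.337         # neuron 6 -> output
        assert published.b2 == -4.963

    def test_parameter_count_is_51(self, published):
        assert hp.count_parameters(published) == 51

    @pytest.mark.parametrize("n_in,n_hidden,expected", [(1, 1, 4), (3, 5, 26)])
    def test_parameter_count_small_networks(self, rng, n_in, n_hidden, expected):
        w = random_weights(rng, n_in=n_in, n_hidden=n_hidden)
        assert hp.count_parameters(w) == expected

    def test_inconsistent_shapes_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            hp.MLPWeights(np.zeros((3, 10)), np.zeros(9), np.zeros(10), 0.0)


class TestForward:
    def test_zero_output_layer_gives_half(self, rng):
        w = random_weights(rng)
        w.w2 = np.zeros_like(w.w2)
        w.b2 = 0.0
        assert hp.forward(rng.uniform(0, 1, 3), w) == pytest.approx(0.5)

    def test_zero_hidden_weights_make_output_constant(self, rng):
        w = random_weights(rng)
        w.w1 = np.zeros_like(w.w1)
        expected = logistic(w.w2 @ logistic(w.b1) + w.b2)
        for _ in range(5):
            assert hp.forward(rng.uniform(0, 1, 3), w) == pytest.approx(expected)

    def test_forward_matches_per_neuron_loop_oracle(self, rng):
        """Vectorised forward vs explicit scalar loops, to 1e-12."""
        for _ in range(20):
            w = random_weights(rng, n_hidden=7)
            x = rng.uniform(-1, 2, 3)
            acc = w.b2
            for j in range(7):
                z = sum(w.w1[i, j] * x[i] for i in range(3)) + w.b1[j]
                acc += w.w2[j] * (1.0 / (1.0 + math.exp(-z)))
            expected = 1.0 / (1.0 + math.exp(-acc))
            assert hp.forward(x, w) == pytest.approx(expected, abs=1e-12)

    def test_output_strictly_inside_unit_interval(self, published, rng):
        x = rng.uniform(-5, 5, (200, 3))
        y = hp.forward(x, published)
        assert (y > 0).all() and (y < 1).all()

    def test_batch_forward_equals_row_loop(self, published, rng):
        x = rng.uniform(0, 1, (50, 3))
        batch = hp.forward(x, published)
        rows = np.array([hp.forward(x[i], published) for i in range(50)])
        np.testing.assert_allclose(batch, rows, atol=1e-15)


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        spec = NormalizationSpec({"v": (10.0, 30.0)})
        assert spec.normalize(10.0, "v") == 0.0
        assert spec.normalize(30.0, "v") == 1.0
        assert spec.normalize(20.0, "v") == 0.5

    def test_round_trip_identity(self, rng):
        spec = NormalizationSpec({"v": (-4.0, 9.0)})
        x = rng.uniform(-20, 20, 100)
        np.testing.assert_allclose(spec.denormalize(spec.normalize(x, "v"), "v"), x,
                                   atol=1e-12)

    def test_degenerate_spec_rejected(self):
        with pytest.raises(DegenerateRangeError, match="v"):
            NormalizationSpec({"v": (3.0, 3.0)})


class TestSplit:
    def test_100_rows_split_60_20_20(self):
        table = pd.DataFrame({"x": range(100)})
        parts = hp.split_data(table, hp.SplitSpec(seed=1))
        assert [len(p) for p in parts] == [60, 20, 20]

    def test_10_rows_split_6_2_2(self):
        table = pd.DataFrame({"x": range(10)})
        parts = hp.split_data(table, hp.SplitSpec(seed=1))
        assert [len(p) for p in parts] == [6, 2, 2]

    @pytest.mark.parametrize("n", [5, 7, 23, 101])
    def test_partition_is_disjoint_and_exhaustive(self, n):
        table = pd.DataFrame({"x": range(n)})
        parts = hp.split_data(table, hp.SplitSpec(seed=3))
        seen = np.concatenate([p["x"].to_numpy() for p in parts])
        assert sorted(seen) == list(range(n))

    def test_same_seed_same_partition(self):
        table = pd.DataFrame({"x": range(37)})
        a = hp.split_data(table, hp.SplitSpec(seed=5))
        b = hp.split_data(table, hp.SplitSpec(seed=5))
        for pa, pb in zip(a, b):
            pd.testing.assert_frame_equal(pa, pb)

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="too few"):
            hp.split_data(pd.DataFrame({"x": [1, 2]}), hp.SplitSpec())

    def test_largest_remainder_always_sums(self):
        for n in range(5, 60):
            assert sum(_largest_remainder_sizes(n, (0.6, 0.2, 0.2))) == n


class TestEvaluate:
    def test_perfect_prediction(self):
        r2, sos = hp.evaluate([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert r2 == 1.0 and sos == 0.0

    def test_mean_prediction_gives_zero_r2(self):
        obs = np.array([0.2, 0.4, 0.9])
        r2, _ = hp.evaluate(np.full(3, obs.mean()), obs)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_example(self):
        r2, sos = hp.evaluate([0.5, 0.5], [0.0, 1.0])
        assert sos == pytest.approx(0.5)
        assert r2 == pytest.approx(0.0)

    def test_zero_variance_observations_rejected(self):
        with pytest.raises(DegenerateRangeError):
            hp.evaluate([0.1, 0.2], [0.5, 0.5])


class TestTraining:
    def test_noiseless_self_recovery(self, published):
        """The published function is exactly realisable, so a noiseless fit
        should be essentially perfect."""
        table = hp.generate_from_network(n=300, noise_sd=0.0, seed=3)
        _, _, report = hp.train(table, restarts=5, seed=5)
        assert report.r2["train"] >= 0.999

    def test_constant_target_rejected(self):
        table = hp.generate_from_network(n=50, noise_sd=0.0, seed=1)
        table["power_of_honey"] = 0.5
        with pytest.raises(DegenerateRangeError):
            hp.train(table, restarts=1)

    def test_too_few_rows_refused(self):
        table = hp.generate_from_network(n=10, noise_sd=0.0, seed=1)
        with pytest.raises(ValueError, match="too few rows"):
            hp.train(table)

    def test_report_is_complete(self):
        table = hp.generate_from_network(n=120, noise_sd=0.02, seed=4)
        _, _, report = hp.train(table, restarts=2, seed=2)
        assert set(report.r2) == {"train", "validation", "test"}
        assert all(v >= 0 for v in report.sos.values())
        assert all(v <= 1 for v in report.r2.values())


class TestPredictAndSerialize:
    def test_predict_matches_row_by_row_oracle(self, published, rng):
        norm = hp.DEFAULT_NORMALIZATION
        rows = pd.DataFrame({
            "free_acidity": rng.uniform(1, 55, 20),
            "colour_L": rng.uniform(15, 95, 20),
            "colour_a": rng.uniform(-8, 15, 20),
        })
        batch = hp.predict_power(rows, published, norm)
        for i in range(20):
            x = np.array([
                norm.normalize(rows["colour_L"][i], "colour_L"),
                norm.normalize(rows["colour_a"][i], "colour_a"),
                norm.normalize(rows["free_acidity"][i], "free_acidity"),
            ])
            expected = norm.denormalize(hp.forward(x, published), "power_of_honey")
            assert batch[i] == pytest.approx(expected, abs=1e-12)

    def test_prediction_at_minima_equals_forward_at_origin(self, published):
        norm = hp.DEFAULT_NORMALIZATION
        rows = pd.DataFrame({
            "free_acidity": [norm.bounds["free_acidity"][0]],
            "colour_L": [norm.bounds["colour_L"][0]],
            "colour_a": [norm.bounds["colour_a"][0]],
        })
        expected = norm.denormalize(hp.forward(np.zeros(3), published), "power_of_honey")
        assert hp.predict_power(rows, published, norm)[0] == pytest.approx(expected)

    def test_out_of_range_inputs_warn_not_fail(self, published):
        rows = pd.DataFrame({"free_acidity": [500.0], "colour_L": [50.0], "colour_a": [2.0]})
        with pytest.warns(UserWarning, match="extrapolation"):
            hp.predict_power(rows, published, hp.DEFAULT_NORMALIZATION)

    def test_model_json_round_trip(self, tmp_path, published):
        path = tmp_path / "model.json"
        hp.save_model(path, published, hp.DEFAULT_NORMALIZATION, metadata={"note": "x"})
        w, norm = hp.load_model(path)
        np.testing.assert_array_equal(w.w1, published.w1)
        np.testing.assert_array_equal(w.w2, published.w2)
        assert w.b2 == published.b2
        assert norm.bounds == hp.DEFAULT_NORMALIZATION.bounds

    def test_corrupt_parameter_count_rejected(self, tmp_path, published):
        path = tmp_path / "model.json"
        hp.save_model(path, published, hp.DEFAULT_NORMALIZATION)
        doc = json.loads(path.read_text())
        doc["n_parameters"] = 50
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="parameter count"):
            hp.load_model(path)
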