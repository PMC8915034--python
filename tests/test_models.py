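import numpy as np
import pytest

from ecgkit.models import (
    ArchitectureSpec,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    TrainConfig,
    build_and_train,
    build_model,
    conv_cost_profile,
    count_trainable_parameters,
    flatten_length,
    model1_spec,
    model2_spec,
    model3_spec,
    predict_scores,
    propagate_shapes,
)
from ecgkit.preprocess import BeatSegment, Dataset


class TestArchitectureSpecs:
    def test_model1_layer_parameters(self):
        spec = model1_spec()
        convs = [l for l in spec.layers if isinstance(l, Conv1D)]
        assert [c.filters for c in convs] == [400, 256, 178, 88, 44]
        assert [c.kernel for c in convs] == [20, 15, 7, 5, 3]
        drops = [l.rate for l in spec.layers if isinstance(l, Dropout)]
        assert drops == [0.5, 0.5, 0.5, 0.25, 0.25]

    def test_model2_layer_parameters(self):
        spec = model2_spec()
        convs = [l for l in spec.layers if isinstance(l, Conv1D)]
        assert [c.filters for c in convs] == [600, 400, 256, 178, 88]
        assert [c.kernel for c in convs] == [20, 15, 10, 7, 20]
        assert all(l.rate == 0.25 for l in spec.layers if isinstance(l, Dropout))

    def test_model3_layer_parameters(self):
        spec = model3_spec()
        convs = [l for l in spec.layers if isinstance(l, Conv1D)]
        assert [c.filters for c in convs] == [256, 128, 72, 36]
        assert all(c.kernel == 5 for c in convs)
        denses = [l for l in spec.layers if isinstance(l, Dense)]
        assert [d.units for d in denses] == [50, 32, 1]
        assert [d.activation for d in denses] == ["relu", "relu", "sigmoid"]

    @pytest.mark.parametrize(
        "factory, flat",
        [(model1_spec, 2772), (model2_spec, 4664), (model3_spec, 4716)],
    )
    def test_flatten_lengths(self, factory, flat):
        assert flatten_length(factory()) == flat

    def test_model1_shape_chain(self):
        # valid conv then floor pooling: 2160 -> ... -> 63 x 44
        spec = model1_spec()
        lengths = [s[0] for s, l in zip(propagate_shapes(spec), spec.layers)
                   if isinstance(l, (Conv1D, MaxPool1D))]
        assert lengths == [2141, 1070, 1056, 528, 522, 261, 257, 128, 126, 63]

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="Dense"):
            ArchitectureSpec("bad", (Conv1D(4, 3), Flatten(), Dense(2, "relu")))
        with pytest.raises(ValueError, match="Flatten"):
            ArchitectureSpec("bad", (Conv1D(4, 3), Dense(1, "sigmoid")))


class TestParameterCounting:
    def test_single_conv_layer(self):
        # (K*D + 1) * L = (3*1 + 1)*4
        spec = ArchitectureSpec(
            "tiny", (Conv1D(4, 3), Flatten(), Dense(1, "sigmoid")), input_length=10
        )
        conv_params = (3 * 1 + 1) * 4
        dense_params = (8 * 4 + 1) * 1
        assert count_trainable_parameters(spec) == conv_params + dense_params

    @pytest.mark.parametrize(
        "factory, expected",
        [
            (model1_spec, 1_956_651),
            (model2_spec, 5_274_443),
            (model3_spec, 462_167),
        ],
    )
    def test_published_totals(self, factory, expected):
        assert count_trainable_parameters(factory()) == expected

    def test_nonpositive_length_names_layer(self):
        with pytest.raises(ValueError, match="Conv1D"):
            ArchitectureSpec(
                "bad", (Conv1D(4, 50), Flatten(), Dense(1, "sigmoid")), input_length=20
            )


class TestCostProfile:
    @pytest.mark.parametrize("factory", [model1_spec, model2_spec, model3_spec])
    def test_exact_multiplies_and_kndl_bound(self, factory):
        spec = factory()
        for row in conv_cost_profile(spec):
            exact = row["K"] * (row["N"] - row["K"] + 1) * row["D"] * row["L"]
            assert row["multiplies"] == exact
            assert row["multiplies"] <= row["bound_KNDL"]
            # the bound is asymptotically tight: within K/N of exact
            assert row["bound_KNDL"] - row["multiplies"] <= (row["K"] - 1) * row["K"] * row["D"] * row["L"]

    def test_backend_measured_count_matches_analytic(self):
        spec = model3_spec()
        model = build_model(spec)
        analytic = sum(r["multiplies"] for r in conv_cost_profile(spec))
        dense_mults = 4716 * 50 + 50 * 32 + 32 * 1
        assert model.forward_multiply_count() == analytic + dense_mults


@pytest.fixture(scope="module")
def tiny_spec():
    """A small but structurally complete network for training mechanics."""
    return ArchitectureSpec(
        "tiny",
        (
            Conv1D(8, 16),
            Dropout(0.25),
            MaxPool1D(),
            Conv1D(8, 8),
            Dropout(0.25),
            MaxPool1D(),
            Flatten(),
            Dense(8, "relu"),
            Dense(1, "sigmoid"),
        ),
        input_length=2160,
    )


@pytest.fixture(scope="module")
def tiny_dataset():
    """Linearly separable segments: class shifts the mean of a band."""
    rng = np.random.default_rng(77)
    segments = []
    for i in range(160):
        label = i % 2
        x = rng.standard_normal(2160)
        x[400:800] += 3.0 * label
        segments.append(BeatSegment(x, label, i))
    return Dataset(train=segments[:128], test=segments[128:], seed=0)


class TestBackendTraining:
    @pytest.mark.parametrize("factory", [model1_spec, model2_spec, model3_spec])
    def test_backend_parameter_total_matches_analytic(self, factory):
        spec = factory()
        model = build_model(spec)
        assert model.n_parameters == count_trainable_parameters(spec)

    def test_training_reduces_loss(self, tiny_spec, tiny_dataset):
        _, history = build_and_train(
            tiny_spec, tiny_dataset, TrainConfig(epochs=3, batch_size=32, seed=1)
        )
        assert history[-1]["loss"] < history[0]["loss"]

    def test_training_deterministic(self, tiny_spec, tiny_dataset):
        config = TrainConfig(epochs=2, batch_size=32, seed=3)
        _, h1 = build_and_train(tiny_spec, tiny_dataset, config)
        _, h2 = build_and_train(tiny_spec, tiny_dataset, config)
        assert h1 == h2

    def test_scores_in_unit_interval_and_deterministic(self, tiny_spec, tiny_dataset):
        model, _ = build_and_train(
            tiny_spec, tiny_dataset, TrainConfig(epochs=1, batch_size=32, seed=5)
        )
        x, _ = tiny_dataset.arrays("test")
        s1 = predict_scores(model, x)
        s2 = predict_scores(model, x)
        assert ((s1 >= 0) & (s1 <= 1)).all()
        np.testing.assert_array_equal(s1, s2)

    def test_wrong_segment_length_rejected(self, tiny_spec, tiny_dataset):
        model, _ = build_and_train(
            tiny_spec, tiny_dataset, TrainConfig(epochs=1, batch_size=64, seed=6)
        )
        with pytest.raises(ValueError, match="length"):
            predict_scores(model, np.zeros((4, 100)))

    def test_single_class_training_rejected(self, tiny_spec):
        segments = [BeatSegment(np.zeros(2160), 0, i) for i in range(8)]
        dataset = Dataset(train=segments, test=[], seed=0)
        with pytest.raises(ValueError, match="both classes"):
            build_and_train(tiny_spec, dataset, TrainConfig(epochs=1, seed=0))
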