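import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import resttremor as rt
from resttremor import models as m


class TestCanonicalSpecs:
    def test_context_spec_layout(self):
        spec = rt.context_cnn_spec()
        assert len(spec.head_names) == 1
        convs = [l for l in spec.trunk if l.kind == "conv1d"]
        assert [c.params[0] for c in convs] == [128, 96]
        assert [l.params[0] for l in spec.trunk if l.kind == "dense"] == [190]
        assert all(l.kind != "dropout" for l in spec.trunk)

    def test_multitask_raw_spec_layout(self):
        spec = rt.multitask_raw_spec()
        assert set(spec.head_names) == {"context", "tremor"}
        convs = [l for l in spec.trunk if l.kind == "conv1d"]
        assert [c.params[0] for c in convs] == [128, 128]
        for branch in spec.heads.values():
            assert [l.params[0] for l in branch if l.kind == "dropout"] == [0.2]
            assert [l.params[0] for l in branch if l.kind == "dense"] == [190]

    def test_multitask_fft_spec_layout(self):
        spec = rt.multitask_fft_spec()
        assert spec.input_shape == (64, 1)
        assert len(spec.head_names) == 2
        convs = [l for l in spec.trunk if l.kind == "conv1d"]
        assert [c.params[0] for c in convs] == [128, 96]


class TestParameterCount:
    @pytest.mark.parametrize("spec_fn,expected", [
        (rt.multitask_raw_spec, 183_802),
        (rt.context_cnn_spec, 120_221),
        (rt.multitask_fft_spec, 136_794),
    ])
    def test_canonical_totals(self, spec_fn, expected):
        assert rt.count_trainable_parameters(spec_fn()) == expected

    @pytest.mark.parametrize("spec_fn", [rt.context_cnn_spec,
                                         rt.multitask_raw_spec,
                                         rt.multitask_fft_spec])
    def test_closed_form_matches_built_network(self, spec_fn):
        spec = spec_fn()
        net = rt.build_network(spec, np.random.default_rng(0))
        assert net.n_parameters() == rt.count_trainable_parameters(spec)

    @given(st.data())
    @settings(deadline=None, max_examples=25)
    def test_closed_form_matches_built_for_random_specs(self, data):
        length = data.draw(st.sampled_from([32, 64, 128]))
        channels = data.draw(st.integers(1, 3))
        trunk = [m.conv1d(data.draw(st.integers(4, 32)), data.draw(st.integers(2, 8))),
                 m.maxpool(2),
                 m.conv1d(data.draw(st.integers(4, 32)), data.draw(st.integers(2, 8))),
                 m.global_average_pool()]
        if data.draw(st.booleans()):
            trunk.append(m.dense(data.draw(st.integers(4, 64))))
        n_heads = data.draw(st.integers(1, 2))
        heads = {}
        for i in range(n_heads):
            branch = []
            if data.draw(st.booleans()):
                branch.append(m.dense(data.draw(st.integers(4, 64))))
                branch.append(m.dropout(0.2))
            branch.append(m.head())
            heads[f"h{i}"] = tuple(branch)
        spec = m.ModelSpec(name="random", input_shape=(length, channels),
                           trunk=tuple(trunk), heads=heads)
        net = rt.build_network(spec, np.random.default_rng(0))
        assert net.n_parameters() == rt.count_trainable_parameters(spec)

    def test_unknown_layer_kind_rejected(self):
        spec = m.ModelSpec(name="bad", input_shape=(64, 1),
                           trunk=(m.LayerSpec("wavelet"),), heads={"h": (m.head(),)})
        with pytest.raises(ValueError):
            rt.count_trainable_parameters(spec)


def _toy_dataset(n=200, seed=0):
    """Separable two-head toy windows: head labels from band energy."""
    rng = np.random.default_rng(seed)
    x = rng.normal(scale=0.05, size=(n, 64, 1))
    ctx = rng.integers(0, 2, size=n)
    trm = rng.integers(0, 2, size=n)
    x[ctx == 1, 2:6, 0] += 1.0
    x[trm == 1, 10:14, 0] += 1.0
    return x, {"context": ctx, "tremor": trm}


class TestTraining:
    def test_loss_decreases_and_history_bounded(self):
        x, labels = _toy_dataset()
        cfg = m.TrainConfig(learning_rate=0.0046, max_epochs=3,
                            early_stop_patience=2, seed=0)
        model = m.train(rt.multitask_fft_spec(), x, labels, cfg)
        hist = model.history["train_loss"]
        assert len(hist) <= 3
        assert np.all(np.isfinite(hist)) and np.all(np.isfinite(model.history["val_loss"]))
        assert hist[-1] <= hist[0]

    def test_same_seed_identical_weights(self):
        x, labels = _toy_dataset()
        cfg = m.TrainConfig(learning_rate=0.0046, max_epochs=3,
                            early_stop_patience=2, seed=11)
        w1 = m.train(rt.multitask_fft_spec(), x, labels, cfg).weights
        w2 = m.train(rt.multitask_fft_spec(), x, labels, cfg).weights
        assert max(np.max(np.abs(a - b)) for a, b in zip(w1, w2)) == 0.0

    def test_early_stopping_restores_best_epoch(self):
        x, labels = _toy_dataset(n=120)
        cfg = m.TrainConfig(learning_rate=0.05, max_epochs=60,
                            early_stop_patience=5, seed=0)
        model = m.train(rt.multitask_fft_spec(), x, labels, cfg)
        val = model.history["val_loss"]
        assert model.best_epoch == int(np.argmin(val))
        if len(val) < 60:  # stopped early
            assert model.best_epoch < len(val) - 1
            assert len(val) - 1 - model.best_epoch >= 5

    def test_degenerate_labels_rejected(self):
        x, labels = _toy_dataset()
        labels = dict(labels, tremor=np.ones(len(x), dtype=int))
        cfg = m.TrainConfig(max_epochs=2, early_stop_patience=1, seed=0)
        with pytest.raises(m.DegenerateLabelsError):
            m.train(rt.multitask_fft_spec(), x, labels, cfg)

    def test_masked_labels_are_ignored(self):
        x, labels = _toy_dataset()
        labels = {k: v.copy() for k, v in labels.items()}
        labels["tremor"][:20] = -1
        cfg = m.TrainConfig(max_epochs=2, early_stop_patience=1, seed=0)
        model = m.train(rt.multitask_fft_spec(), x, labels, cfg)
        assert np.all(np.isfinite(model.history["train_loss"]))


@pytest.fixture(scope="module")
def trained():
    x, labels = _toy_dataset()
    cfg = m.TrainConfig(learning_rate=0.0046, max_epochs=8,
                        early_stop_patience=4, seed=0)
    return m.train(rt.multitask_fft_spec(), x, labels, cfg), x, labels


class TestPrediction:
    def test_probabilities_in_unit_interval_two_heads(self, trained):
        model, x, _ = trained
        probs = m.predict_proba(model, x)
        assert set(probs) == {"context", "tremor"}
        for p in probs.values():
            assert p.shape == (len(x),)
            assert np.all((p >= 0) & (p <= 1))

    def test_repeated_prediction_identical_dropout_inactive(self, trained):
        model, x, _ = trained
        p1 = m.predict_proba(model, x)
        p2 = m.predict_proba(model, x)
        for name in p1:
            assert np.array_equal(p1[name], p2[name])

    def test_separates_classes_after_training(self, trained):
        model, x, labels = trained
        probs = m.predict_proba(model, x)
        for name in ("context", "tremor"):
            y = labels[name]
            assert probs[name][y == 1].mean() > probs[name][y == 0].mean()

    def test_shape_mismatch_rejected(self, trained):
        model, _, _ = trained
        with pytest.raises(ValueError):
            m.predict_proba(model, np.zeros((4, 128, 3)))

    def test_save_roundtrip(self, trained, tmp_path):
        model, x, _ = trained
        model.save(tmp_path / "w.npz", tmp_path / "w.json")
        loaded = np.load(tmp_path / "w.npz")
        restored = m.TrainedModel(spec=model.spec,
                                  weights=[loaded[f"p{i}"] for i in range(len(loaded.files))],
                                  history={}, best_epoch=model.best_epoch)
        p1, p2 = m.predict_proba(model, x), m.predict_proba(restored, x)
        for name in p1:
            assert np.array_equal(p1[name], p2[name])
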