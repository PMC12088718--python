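"""Properties of the attention MIL classifier: attention normalization,
permutation behaviour, aggregation rules, training protocol mechanics."""

import numpy as np
import pytest

from milcta import (
    BagArray,
    ConfigurationError,
    MILAttentionClassifier,
    add_positional_encoding,
    augment_bag,
    compute_class_weights,
)
from milcta._autograd import Tensor
from milcta._nn import GatedAttentionPool, sinusoidal_positional_encoding


def _make_bags(rng, n_bags=8, bag_size=6, size=16, prefix="p"):
    bags = []
    for i in range(n_bags):
        label = i % 2
        x = rng.random((bag_size, size, size)).astype(np.float32)
        if label:
            x[0, 4:9, 4:9] += 1.0  # key instance carries a bright patch
        bags.append(
            BagArray(
                patient_id=f"{prefix}{i}",
                bag_index=0,
                x=np.clip(x, 0, 2),
                label=label,
                entries=[f"{prefix}{i}:{j}" for j in range(bag_size)],
                replicated_flags=[False] * bag_size,
            )
        )
    return bags


def _small_clf(**kw):
    defaults = dict(
        backbone="small_cnn",
        small_cnn_channels=(2, 4),
        embed_dim=16,
        n_heads=2,
        attn_dim=8,
        bag_size=6,
        max_epochs=2,
        batch_bags=4,
        pretrain="none",
        random_state=0,
    )
    defaults.update(kw)
    return MILAttentionClassifier(**defaults)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    bags = _make_bags(rng)
    clf = _small_clf()
    clf.fit(bags)
    return clf, bags


class TestAttentionPooling:
    def test_identical_instances_get_uniform_attention(self):
        pool = GatedAttentionPool(8, 6, np.random.default_rng(0))
        h = np.tile(np.random.default_rng(1).random((1, 1, 8)), (2, 5, 1))
        _, attn = pool(Tensor(h))
        np.testing.assert_allclose(attn.data, 1.0 / 5, atol=1e-6)

    def test_attention_sums_to_one_and_is_shift_invariant(self):
        rng = np.random.default_rng(2)
        pool = GatedAttentionPool(8, 6, rng)
        h = rng.random((3, 7, 8))
        pooled, attn = pool(Tensor(h))
        np.testing.assert_allclose(attn.data.sum(axis=1), 1.0, atol=1e-6)
        assert (attn.data >= 0).all()
        # shifting all scores by a constant leaves softmax unchanged
        pool.w.b.data += 5.0
        _, attn2 = pool(Tensor(h))
        np.testing.assert_allclose(attn2.data, attn.data, atol=1e-5)

    def test_pooled_embedding_is_attention_weighted_sum(self):
        rng = np.random.default_rng(3)
        pool = GatedAttentionPool(8, 6, rng)
        h = rng.random((1, 4, 8))
        pooled, attn = pool(Tensor(h))
        manual = (attn.data[0][:, None] * h[0]).sum(axis=0)
        np.testing.assert_allclose(pooled.data[0], manual, atol=1e-6)


class TestPositionalEncoding:
    def test_none_mode_is_identity(self, rng):
        f = rng.random((6, 16))
        np.testing.assert_array_equal(add_positional_encoding(f, "none"), f)

    def test_position_zero_even_channels_unchanged(self, rng):
        f = rng.random((6, 16)).astype(np.float32)
        out = add_positional_encoding(f, "sinusoidal")
        np.testing.assert_allclose(out[0, 0::2], f[0, 0::2], atol=1e-6)  # sin(0) = 0
        assert not np.allclose(out[0, 1::2], f[0, 1::2])  # cos(0) = 1 added

    def test_equal_rows_become_distinct(self):
        f = np.ones((6, 16), dtype=np.float32)
        out = add_positional_encoding(f, "sinusoidal")
        assert not np.allclose(out[0], out[3])

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            add_positional_encoding(rng.random((4, 8)), "learned")

    def test_encoding_closed_form(self):
        pe = sinusoidal_positional_encoding(36, 8)
        assert pe.shape == (36, 8)
        np.testing.assert_allclose(pe[5, 0], np.sin(5.0), atol=1e-6)
        np.testing.assert_allclose(pe[5, 1], np.cos(5.0), atol=1e-6)


class TestPredictionContracts:
    def test_bag_prediction_invariants(self, fitted):
        clf, bags = fitted
        pred = clf.predict_bag(bags[0])
        assert 0.0 <= pred.bag_prob <= 1.0
        assert pred.attention.sum() == pytest.approx(1.0, abs=1e-5)
        assert len(pred.attention) == 6

    def test_eval_mode_is_deterministic(self, fitted):
        clf, bags = fitted
        a = clf.predict_bag(bags[1])
        b = clf.predict_bag(bags[1])
        assert a.bag_prob == b.bag_prob
        np.testing.assert_array_equal(a.attention, b.attention)

    def test_permutation_equivariance_without_positional_encoding(self, rng):
        bags = _make_bags(np.random.default_rng(5))
        clf = _small_clf(positional_encoding="none")
        clf.fit(bags)
        bag = bags[3]
        perm = np.random.default_rng(6).permutation(6)
        permuted = BagArray("q", 0, bag.x[perm], bag.label, [bag.entries[i] for i in perm], [False] * 6)
        a = clf.predict_bag(bag)
        b = clf.predict_bag(permuted)
        assert b.bag_prob == pytest.approx(a.bag_prob, abs=1e-5)
        np.testing.assert_allclose(b.attention, a.attention[perm], atol=1e-5)

    def test_patient_probability_is_max_over_bags(self, fitted):
        clf, bags = fitted
        two = [
            BagArray("pt", 0, bags[0].x, 1, [f"s{j}" for j in range(6)], [False] * 6),
            BagArray("pt", 1, bags[1].x, 1, [f"s{j+6}" for j in range(6)], [False] * 6),
        ]
        case = clf.predict_patient(two)
        probs = [clf.predict_bag(b).bag_prob for b in two]
        assert case.patient_prob == pytest.approx(max(probs), abs=1e-6)
        assert case.contributing_bag_index == int(np.argmax(probs))
        assert case.case_attention.sum() == pytest.approx(1.0, abs=1e-6)

    def test_single_bag_case_attention_matches_bag_attention(self, fitted):
        clf, bags = fitted
        bag = bags[2]
        case = clf.predict_patient([bag])
        bag_pred = clf.predict_bag(bag)
        by_id = dict(zip(bag.entries, bag_pred.attention))
        expected = np.array([by_id[s] for s in case.slice_ids])
        np.testing.assert_allclose(case.case_attention, expected / expected.sum(), atol=1e-6)

    def test_replicated_entries_do_not_inflate_case_attention(self, fitted):
        clf, bags = fitted
        x = bags[0].x.copy()
        x[3] = x[0]  # entry replicated at two positions
        bag = BagArray("pr", 0, x, 1, ["a", "b", "c", "a", "d", "e"], [False, False, False, True, False, False])
        case = clf.predict_patient([bag])
        pred = clf.predict_bag(bag)
        # slice "a" gets the max of its two occurrences, not the sum
        a_max = max(pred.attention[0], pred.attention[3])
        others = {"b": 1, "c": 2, "d": 4, "e": 5}
        raw = {"a": a_max, **{k: pred.attention[v] for k, v in others.items()}}
        total = sum(raw.values())
        idx = case.slice_ids.index("a")
        assert case.case_attention[idx] == pytest.approx(raw["a"] / total, abs=1e-6)

    def test_empty_patient_rejected(self, fitted):
        clf, _ = fitted
        with pytest.raises(ValueError):
            clf.predict_patient([])

    def test_predict_proba_shape_and_range(self, fitted):
        clf, bags = fitted
        proba = clf.predict_proba(bags)
        assert proba.shape == (len(bags), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)


class TestClassWeights:
    def test_balanced_classes_weigh_one(self):
        assert compute_class_weights([0, 1] * 10) == {0: 1.0, 1: 1.0}

    def test_imbalanced_formula(self):
        w = compute_class_weights([1] * 25 + [0] * 75)
        assert w[1] == pytest.approx(2.0)
        assert w[0] == pytest.approx(100 / 150)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights([1, 1, 1])


class TestAugmentation:
    def test_zero_ranges_are_identity(self, rng):
        x = rng.random((4, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(augment_bag(x, 0.0, 0.0), x)

    def test_slice_order_is_preserved(self, rng):
        x = np.zeros((5, 16, 16), dtype=np.float32)
        for i in range(5):
            x[i, 8, 8] = i + 1  # identifiable center marker
        out = augment_bag(x, 0.05, 0.05, rng=np.random.default_rng(0))
        for i in range(5):
            assert out[i].max() <= i + 1 + 1e-6
            assert out[i].max() > 0.3 * (i + 1)  # marker still in slice i

    def test_rotation_is_a_hard_error(self, rng):
        with pytest.raises(ConfigurationError):
            augment_bag(rng.random((2, 8, 8)), rotation_range=10.0)


class TestTrainingProtocol:
    def test_embed_dim_head_divisibility_enforced(self):
        with pytest.raises(ConfigurationError):
            _small_clf(embed_dim=10, n_heads=4).fit(_make_bags(np.random.default_rng(0)))

    def test_leakage_between_train_and_val_rejected(self):
        bags = _make_bags(np.random.default_rng(0))
        clf = _small_clf()
        with pytest.raises(ValueError, match="leakage"):
            clf.fit(bags, X_val=bags[:2])

    def test_flat_validation_loss_stops_after_patience(self):
        bags = _make_bags(np.random.default_rng(1))
        clf = _small_clf(max_epochs=50, early_stop_patience=7, plateau_patience=5, lr=1e-4)
        clf._eval_loss = lambda X, y: 0.5  # flat from the first epoch
        clf.fit(bags[:6], X_val=_make_bags(np.random.default_rng(9), n_bags=2, prefix="v"))
        assert clf.n_epochs_ == 1 + 7

    def test_plateau_reduces_learning_rate_by_factor(self):
        bags = _make_bags(np.random.default_rng(1))
        clf = _small_clf(max_epochs=50, early_stop_patience=7, plateau_patience=5, lr=1e-4, plateau_factor=0.2)
        clf._eval_loss = lambda X, y: 0.5
        clf.fit(bags[:6], X_val=_make_bags(np.random.default_rng(9), n_bags=2, prefix="v"))
        lrs = clf.history_["lr"]
        assert lrs[0] == pytest.approx(1e-4)
        assert lrs[-1] == pytest.approx(2e-5)  # one plateau event: 1e-4 × 0.2

    def test_improving_validation_runs_to_max_epochs(self):
        bags = _make_bags(np.random.default_rng(1))
        clf = _small_clf(max_epochs=12)
        seq = iter(np.linspace(1.0, 0.1, 50))
        clf._eval_loss = lambda X, y: float(next(seq))
        clf.fit(bags[:6], X_val=_make_bags(np.random.default_rng(9), n_bags=2, prefix="v"))
        assert clf.n_epochs_ == 12

    def test_fit_is_deterministic_given_seed(self):
        bags = _make_bags(np.random.default_rng(2))
        probs = []
        for _ in range(2):
            clf = _small_clf(random_state=77, max_epochs=2)
            clf.fit(bags)
            probs.append(clf.predict_proba(bags)[:, 1])
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_sklearn_param_interface(self):
        clf = _small_clf()
        params = clf.get_params()
        assert params["n_heads"] == 2
        clone = MILAttentionClassifier(**params)
        assert clone.get_params() == params


class TestFrozenBackbone:
    def test_vgg_frozen_layers_are_immutable_under_training(self):
        rng = np.random.default_rng(0)
        bags = _make_bags(rng, n_bags=4, bag_size=4, size=32)
        clf = MILAttentionClassifier(
            backbone="vgg16_style",
            vgg_width_scale=0.06,
            frozen_layers=15,
            embed_dim=16,
            n_heads=2,
            attn_dim=8,
            bag_size=4,
            max_epochs=1,
            batch_bags=2,
            pretrain="none",
            random_state=0,
        )
        clf.fit(bags)
        net = clf.net_
        # layer indices count conv and pooling layers; the first 15 cover
        # convs 0..10 of the 13-conv stack
        before = [c.w.data.copy() for c in net.encoder.convs]
        clf2 = MILAttentionClassifier(**clf.get_params())
        clf2.fit(bags)  # same seed → identical init; training touches only unfrozen
        for i, c in enumerate(net.encoder.convs):
            frozen = not c.w.requires_grad
            assert frozen == (i <= 10)
        # frozen parameters identical across both training runs and equal to init
        init_rng_check = [c.w.requires_grad for c in clf2.net_.encoder.convs]
        assert init_rng_check == [c.w.requires_grad for c in net.encoder.convs]

    def test_frozen_weights_bitwise_unchanged_by_a_training_step(self):
        rng = np.random.default_rng(0)
        bags = _make_bags(rng, n_bags=4, bag_size=4, size=32)
        clf = MILAttentionClassifier(
            backbone="vgg16_style", vgg_width_scale=0.06, frozen_layers=15,
            embed_dim=16, n_heads=2, attn_dim=8, bag_size=4, max_epochs=0,
            batch_bags=2, pretrain="none", random_state=0,
        )
        clf.fit(bags)
        frozen_before = [c.w.data.copy() for c in clf.net_.encoder.convs if not c.w.requires_grad]
        free_before = [c.w.data.copy() for c in clf.net_.encoder.convs if c.w.requires_grad]
        net = clf.net_
        clf.max_epochs = 1
        clf._build_net = lambda input_size, rng: net  # continue with same net
        clf.fit(bags)
        frozen_after = [c.w.data for c in net.encoder.convs if not c.w.requires_grad]
        free_after = [c.w.data for c in net.encoder.convs if c.w.requires_grad]
        for a, b in zip(frozen_before, frozen_after):
            assert a.tobytes() == b.tobytes()
        assert any(a.tobytes() != b.tobytes() for a, b in zip(free_before, free_after))


class TestPretraining:
    def test_pretext_images_have_expected_structure(self):
        from milcta import make_pretext_image

        rng = np.random.default_rng(0)
        labels = []
        for _ in range(50):
            img, y = make_pretext_image(rng, 32)
            labels.append(y)
            assert img.shape == (32, 32)
            assert img.min() >= 0.0 and img.max() <= 1.0
            assert (img > 0).any()
        assert 10 < sum(labels) < 40  # roughly balanced

    def test_pretraining_reduces_pretext_loss(self):
        from milcta._nn import SmallCNN
        from milcta import pretrain_encoder

        rng = np.random.default_rng(0)
        enc = SmallCNN(16, rng, channels=(2, 4))
        losses = pretrain_encoder(enc, 16, (32, 32), rng, n_images=200, epochs=3)
        assert len(losses) == 3
        assert losses[-1] < losses[0]


class TestCheckpoint:
    def test_save_load_roundtrip_preserves_predictions(self, fitted, tmp_path):
        clf, bags = fitted
        clf.save(tmp_path / "model.npz")
        loaded = MILAttentionClassifier.load(tmp_path / "model.npz")
        np.testing.assert_allclose(
            loaded.predict_proba(bags), clf.predict_proba(bags), atol=1e-6
        )
        assert loaded.n_epochs_ == clf.n_epochs_

    def test_unfitted_save_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            _small_clf().save(tmp_path / "m.npz")
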