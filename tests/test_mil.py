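import numpy as np
import pytest

from duomil.mil import (
    ProxyLabelSet,
    SlidePatches,
    TrainConfig,
    assign_proxy_labels,
    masked_bce_grad,
    masked_bce_loss,
    predict_slide,
    sample_bag,
    train,
)
from duomil.nn import TinyConvNet


def proxy_oracle(preds, slide_label, alpha, beta):
    """Brute-force sort-all-take-extremes reference implementation."""
    b = len(preds)
    labels = np.zeros((b, 2), dtype=int)
    mask = np.zeros(b, dtype=int)
    if slide_label == "normal":
        labels[:, 0] = 1
        mask[:] = 1
        return labels, mask
    order = sorted(range(b), key=lambda i: (preds[i][0], i))
    for i in order[:alpha]:
        labels[i, 1] = 1
        mask[i] = 1
    for i in order[b - beta :] if beta else []:
        labels[i, 0] = 1
        mask[i] = 1
    return labels, mask


class TestSampleBag:
    def test_single_tile_fills_whole_bag(self):
        bag = sample_bag([0], 100, np.random.default_rng(0))
        assert np.all(bag.patch_refs == 0)

    def test_reproducible_under_seed(self):
        a = sample_bag(list(range(1000)), 100, np.random.default_rng(5))
        b = sample_bag(list(range(1000)), 100, np.random.default_rng(5))
        assert np.array_equal(a.patch_refs, b.patch_refs)

    def test_empirical_frequencies_binomial(self):
        bag = sample_bag(list(range(5)), 10000, np.random.default_rng(1))
        counts = np.bincount(bag.patch_refs, minlength=5)
        sigma = np.sqrt(10000 * 0.2 * 0.8)
        assert np.all(np.abs(counts - 2000) < 3 * sigma)

    def test_empty_tile_list_raises(self):
        with pytest.raises(ValueError, match="no tissue tiles"):
            sample_bag([], 10, np.random.default_rng(0))


class TestAssignProxyLabels:
    def test_normal_slide_all_negative_all_active(self):
        preds = np.random.default_rng(0).random((100, 2))
        proxy = assign_proxy_labels(preds, "normal", 10, 0)
        assert np.all(proxy.labels[:, 0] == 1)
        assert np.all(proxy.labels[:, 1] == 0)
        assert proxy.mask.sum() == 100

    def test_positive_slide_top_alpha_selected(self):
        rng = np.random.default_rng(1)
        preds = rng.random((100, 2))
        proxy = assign_proxy_labels(preds, "coeliac", 10, 0)
        assert proxy.labels[:, 1].sum() == 10
        assert proxy.mask.sum() == 10
        chosen = np.flatnonzero(proxy.labels[:, 1])
        worst = np.sort(preds[:, 0])[:10]
        assert np.allclose(np.sort(preds[chosen, 0]), worst)

    def test_tie_break_on_equal_scores(self):
        preds = np.array([[0.9, 0], [0.1, 0], [0.1, 0], [0.8, 0]], dtype=float)
        proxy = assign_proxy_labels(preds, "coeliac", 2, 1)
        assert np.array_equal(proxy.labels[:, 1], [0, 1, 1, 0])
        assert np.array_equal(proxy.labels[:, 0], [1, 0, 0, 0])
        assert np.array_equal(proxy.mask, [1, 1, 1, 0])

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            b = int(rng.integers(4, 40))
            # coarse quantisation forces frequent ties
            preds = np.round(rng.random((b, 2)), 1)
            alpha = int(rng.integers(1, b))
            beta = int(rng.integers(0, b - alpha + 1))
            label = "coeliac" if rng.random() < 0.7 else "normal"
            proxy = assign_proxy_labels(preds, label, alpha, beta)
            labels_ref, mask_ref = proxy_oracle(preds, label, alpha, beta)
            assert np.array_equal(proxy.labels, labels_ref)
            assert np.array_equal(proxy.mask, mask_ref)

    def test_alpha_beta_exceeding_bag_raises(self):
        preds = np.zeros((4, 2))
        with pytest.raises(ValueError):
            assign_proxy_labels(preds, "coeliac", 3, 2)


class TestMaskedBce:
    def test_zero_logits_give_log_two(self):
        logits = np.zeros((10, 2))
        proxy = assign_proxy_labels(np.full((10, 2), 0.5), "normal", 1, 0)
        assert masked_bce_loss(logits, proxy) == pytest.approx(np.log(2))

    def test_perfect_confident_logits_drive_loss_to_zero(self):
        labels = np.zeros((6, 2), dtype=int)
        labels[:, 0] = 1
        proxy = ProxyLabelSet(labels=labels, mask=np.ones(6, dtype=int))
        logits = np.where(labels == 1, 50.0, -50.0)
        assert masked_bce_loss(logits, proxy) < 1e-12

    def test_single_active_row_equals_hand_computation(self):
        logits = np.array([[0.3, -0.7], [1.2, 0.1], [-0.4, 2.0]])
        labels = np.array([[0, 0], [1, 0], [0, 0]])
        proxy = ProxyLabelSet(labels=labels, mask=np.array([0, 1, 0]))
        p = 1 / (1 + np.exp(-logits[1]))
        hand = -(np.log(p[0]) + np.log(1 - p[1])) / 2
        assert masked_bce_loss(logits, proxy) == pytest.approx(hand)

    def test_all_masked_raises(self):
        proxy = ProxyLabelSet(labels=np.zeros((3, 2), dtype=int),
                              mask=np.zeros(3, dtype=int))
        with pytest.raises(ValueError, match="no active"):
            masked_bce_loss(np.zeros((3, 2)), proxy)

    def test_masked_logits_have_exactly_zero_gradient(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(0, 1, (20, 2))
        proxy = assign_proxy_labels(rng.random((20, 2)), "coeliac", 3, 2)
        grad = masked_bce_grad(logits, proxy)
        masked = proxy.mask == 0
        assert np.all(grad[masked] == 0.0)
        # finite difference: perturbing a masked logit leaves the loss as is
        base = masked_bce_loss(logits, proxy)
        i = int(np.flatnonzero(masked)[0])
        bumped = logits.copy()
        bumped[i] += 10.0
        assert masked_bce_loss(bumped, proxy) == base

    def test_gradient_matches_finite_differences_on_active_rows(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(0, 1, (8, 2))
        proxy = assign_proxy_labels(rng.random((8, 2)), "coeliac", 2, 1)
        grad = masked_bce_grad(logits, proxy)
        eps = 1e-6
        for i in range(8):
            for j in range(2):
                bumped = logits.copy()
                bumped[i, j] += eps
                num = (masked_bce_loss(bumped, proxy)
                       - masked_bce_loss(logits, proxy)) / eps
                assert grad[i, j] == pytest.approx(num, abs=1e-5)


def _toy_slides(rng, n_per_class=3, n_tiles=12):
    """Tiny feature-space slides with a linear class signal on channel 0."""
    slides = []
    for i in range(n_per_class * 2):
        label = "normal" if i % 2 == 0 else "coeliac"
        feats = rng.normal(0, 0.3, (n_tiles, 4, 8, 8))
        if label == "coeliac":
            feats[: n_tiles // 3, 0] += 1.5  # a third of tiles carry lesion
        slides.append(SlidePatches(slide_id=f"s{i}", label=label,
                                   features=feats, case_id=f"c{i}"))
    return slides


class TestTrain:
    def test_zero_epochs_leaves_model_unchanged(self):
        rng = np.random.default_rng(0)
        slides = _toy_slides(rng)
        model = TinyConvNet(seed=1, channels=(2, 3, 4))
        before = [p.value.copy() for p in model.parameters()]
        train(slides, model, TrainConfig(epochs=0, bag_size=8, alpha=2, seed=0))
        for p, b in zip(model.parameters(), before):
            assert np.array_equal(p.value, b)

    def test_same_seed_identical_loss_logs(self):
        rng = np.random.default_rng(0)
        slides = _toy_slides(rng)
        logs = []
        for _ in range(2):
            model = TinyConvNet(seed=2, channels=(2, 3, 4))
            logs.append(train(slides, model,
                              TrainConfig(epochs=2, bag_size=8, alpha=2, seed=9)))
        assert logs[0].losses == logs[1].losses
        assert logs[0].slide_ids == logs[1].slide_ids

    def test_loss_decreases_over_training(self):
        rng = np.random.default_rng(1)
        slides = _toy_slides(rng, n_per_class=4, n_tiles=18)
        model = TinyConvNet(seed=3, channels=(4, 6, 8))
        log = train(slides, model,
                    TrainConfig(epochs=10, bag_size=12, alpha=3, seed=4))
        means = log.epoch_means()
        assert means[-1] < means[0]
        assert len(log.losses) == 10 * len(slides)

    def test_single_class_training_rejected(self):
        rng = np.random.default_rng(0)
        slides = [s for s in _toy_slides(rng) if s.label == "normal"]
        with pytest.raises(ValueError, match="both classes"):
            train(slides, TinyConvNet(seed=0, channels=(2, 3, 4)),
                  TrainConfig(epochs=1, bag_size=8, alpha=2))


class TestPredictSlide:
    def test_shapes_and_determinism_on_duplicates(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(0, 0.3, (5, 4, 8, 8))
        feats[3] = feats[0]  # duplicate tile
        slide = SlidePatches(slide_id="s", label="normal", features=feats)
        model = TinyConvNet(seed=1, channels=(2, 3, 4))
        for p in model.parameters():
            p.value += 0.001  # small: the gained head saturates quickly
        preds = predict_slide(model, slide)
        assert preds.shape == (5, 2)
        assert np.all((preds > 0) & (preds < 1))
        assert np.array_equal(preds[0], preds[3])

    def test_empty_slide_raises(self):
        slide = SlidePatches(slide_id="s", label="normal",
                             features=np.empty((0, 4, 8, 8)))
        with pytest.raises(ValueError, match="no tissue"):
            predict_slide(TinyConvNet(seed=0, channels=(2, 3, 4)), slide)


class TestTrainConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            TrainConfig(alpha=0)
        with pytest.raises(ValueError):
            TrainConfig(alpha=60, beta=50, bag_size=100)
        cfg = TrainConfig()
        assert (cfg.alpha, cfg.beta, cfg.bag_size, cfg.epochs) == (10, 0, 100, 10)
        assert cfg.learning_rate == cfg.weight_decay == 1e-4
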