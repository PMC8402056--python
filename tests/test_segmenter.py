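import numpy as np
import pytest

from earcount.backbones import build_model
from earcount.preprocess import augment, flip_annotated
from earcount.segmenter import (
    LCFCNCounter,
    TrainConfig,
    count_blobs,
    load_model,
    predict_count,
    save_model,
    train_model,
)
from earcount.synthetic import EarGeometry, FieldSimConfig, simulate_dataset

from .conftest import recovery_config
from .oracles import flood_label


def small_dataset(n=6, seed=33):
    cfg = FieldSimConfig(
        image_size=(64, 64),
        count_law=("uniform", 2, 6),
        ear_geometry=EarGeometry(length=(7, 13), width=(2.5, 4.5)),
        overlap_fraction=0.0,
        seed=seed,
    )
    return simulate_dataset(cfg, n, master_seed=seed)


class TestBuildModel:
    def test_tiny_output_is_per_pixel_two_class(self):
        model = build_model("tiny", seed=0)
        x = np.random.default_rng(0).normal(size=(1, 3, 64, 64)).astype(np.float32)
        y = model.forward(x, train=False)
        assert y.shape == (1, 2, 64, 64)
        assert model.n_parameters() < 100_000

    @pytest.mark.parametrize("backbone", ["vgg16-fcn", "resnet50-fcn"])
    def test_deep_backbones_preserve_resolution(self, backbone):
        model = build_model(backbone, seed=0)
        y = model.forward(np.zeros((1, 3, 96, 96), np.float32), train=False)
        assert y.shape == (1, 2, 96, 96)

    def test_stride_contract_enforced(self):
        model = build_model("resnet50-fcn", seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 3, 50, 50), np.float32))

    def test_same_seed_same_initial_parameters(self):
        a, b = build_model("tiny", seed=4), build_model("tiny", seed=4)
        assert all(
            np.array_equal(p["value"], q["value"])
            for p, q in zip(a.parameters(), b.parameters())
        )

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            build_model("alexnet")


class TestCountBlobs:
    def test_all_zero_mask(self):
        _, n = count_blobs(np.zeros((5, 5), dtype=np.uint8))
        assert n == 0

    def test_diagonal_pair_connectivity_semantics(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[1, 1] = mask[2, 2] = 1
        assert count_blobs(mask, connectivity=8)[1] == 1
        assert count_blobs(mask, connectivity=4)[1] == 2

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            count_blobs(np.full((3, 3), 2))

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_random_masks_match_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(10)
        for _ in range(40):
            mask = rng.random((16, 16)) < 0.4
            _, n = count_blobs(mask, connectivity)
            assert n == flood_label(mask, connectivity)[1]


class TestTraining:
    def test_zero_epochs_leaves_model_unchanged(self):
        data = small_dataset()
        model = build_model("tiny", seed=1)
        before = [p["value"].copy() for p in model.parameters()]
        model, log = train_model(model, data, TrainConfig(epochs=0))
        assert log.empty
        assert all(
            np.array_equal(b, p["value"])
            for b, p in zip(before, model.parameters())
        )

    def test_training_is_deterministic_given_seed(self):
        data = small_dataset()
        logs = []
        for _ in range(2):
            est = LCFCNCounter(
                epochs=2, learning_rate=1e-4, max_grad_norm=20.0, seed=5
            ).fit(data)
            logs.append(est.loss_log_)
        assert logs[0].equals(logs[1])

    def test_loss_halves_on_easy_synthetic_data(self):
        cfg = recovery_config(44)
        data = simulate_dataset(cfg, 20, master_seed=44)
        est = LCFCNCounter(
            epochs=50, learning_rate=1e-4, max_grad_norm=20.0, seed=2
        ).fit(data)
        log = est.loss_log_
        assert log["total"].iloc[-1] <= 0.5 * log["total"].iloc[0]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_model(build_model("tiny"), [], TrainConfig(epochs=1))


class TestPredict:
    def test_forced_background_model_counts_zero(self):
        class AllBackground:
            stride = 1

            def forward(self, x, train=False):
                n, _, h, w = x.shape
                logits = np.zeros((n, 2, h, w), np.float32)
                logits[:, 0] = 5.0
                return logits

        pred = predict_count(
            AllBackground(), np.zeros((16, 16, 3), np.uint8),
            mean=np.zeros(3), std=np.ones(3),
        )
        assert pred.blob_count == 0 and pred.blob_centroids == []

    def test_two_square_mask_counts_two(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[0:2, 0:2] = 1
        mask[5:7, 5:7] = 1
        assert count_blobs(mask)[1] == 2

    def test_centroids_inside_blob_bounding_boxes(self, recovery_run):
        est = recovery_run["estimator"]
        pred = est.predict_single(recovery_run["test"][0])
        labels, n = count_blobs(pred.binary_mask, est.connectivity)
        assert pred.blob_count == n
        for k, (r, c) in enumerate(pred.blob_centroids, start=1):
            rows, cols = np.nonzero(labels == k)
            assert rows.min() - 0.5 <= r <= rows.max() + 0.5
            assert cols.min() - 0.5 <= c <= cols.max() + 0.5


class TestEstimatorContract:
    def test_get_set_params_round_trip(self):
        est = LCFCNCounter(epochs=3, learning_rate=0.01)
        params = est.get_params()
        clone = LCFCNCounter(**params)
        assert clone.get_params() == params

    def test_arrays_with_point_lists(self):
        data = small_dataset(4)
        est = LCFCNCounter(epochs=1, learning_rate=1e-4, seed=0)
        est.fit([d.pixels for d in data], [d.points for d in data])
        out = est.predict([d.pixels for d in data])
        assert out.shape == (4,) and (out >= 0).all()

    def test_score_is_negative_mae(self, recovery_run):
        est = recovery_run["estimator"]
        score = est.score(recovery_run["test"], recovery_run["truths"])
        assert score == pytest.approx(-recovery_run["report"].mae)


def test_model_serialization_round_trip(tmp_path):
    data = small_dataset(4)
    est = LCFCNCounter(epochs=1, learning_rate=1e-4, seed=3).fit(data)
    config = est._config()
    save_model(tmp_path, est.model_, config, est.norm_mean_, est.norm_std_)
    model, config2, mean, std = load_model(tmp_path)
    assert config2.seed == config.seed
    direct = est.predict_single(data[0]).blob_count
    reloaded = predict_count(model, data[0].pixels, mean, std).blob_count
    assert direct == reloaded


def test_flip_equivariance_after_flip_augmented_training():
    """A counter trained with flip augmentation should count flipped scenes
    like the originals (stochastic sanity property, ±1 on 90% of images)."""
    data = small_dataset(20, seed=55)
    est = LCFCNCounter(
        epochs=40, learning_rate=1e-4, max_grad_norm=20.0, seed=1
    ).fit(augment(data, {"flip"}))
    check = small_dataset(10, seed=56)
    agree = sum(
        abs(
            est.predict_single(item).blob_count
            - est.predict_single(flip_annotated(item)).blob_count
        )
        <= 1
        for item in check
    )
    assert agree >= 9
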