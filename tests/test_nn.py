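import numpy as np
import pytest

from deepcombi import PhenotypeVector, encode_one_hot, standardize
from deepcombi.data import GenotypeMatrix, default_snp_meta, stratified_split
from deepcombi import nn
from deepcombi.nn import (
    NetworkParameters,
    TrainingConfig,
    balanced_class_weights,
    forward,
    init_parameters,
    loss,
    loss_and_gradients,
    predict,
    pvalue_prefilter,
    softmax,
    train,
)


def _toy_separable(n=200, seed=0, noise_snps=3):
    """Labels fully determined by the first SNP's allele count."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    counts = rng.integers(0, 3, size=(n, 1 + noise_snps))
    counts[:, 0] = 2 * y
    g = GenotypeMatrix(counts, default_snp_meta(1 + noise_snps))
    return g, PhenotypeVector(y)


class TestLoss:
    def test_confident_predictions_vanish(self):
        y = np.array([0, 1, 1, 0])
        p = np.array([1e-9, 1 - 1e-9, 1 - 1e-9, 1e-9])
        assert loss(y, p) < 1e-6

    def test_coin_flip_costs_log2_per_sample(self):
        y = np.array([0, 1] * 10)
        assert loss(y, np.full(20, 0.5)) == pytest.approx(np.log(2), abs=1e-12)

    def test_penalty_arithmetic_on_unit_weights(self):
        params = NetworkParameters(
            [np.ones((2, 2))], [np.zeros(2)]
        )
        y = np.array([0, 1])
        p = np.array([0.5, 0.5])
        base = loss(y, p)
        assert loss(y, p, params, tau=1.0) == pytest.approx(base + 4.0)
        assert loss(y, p, params, tau=1.0, upsilon=1.0) == pytest.approx(base + 8.0)

    def test_class_weighting_equals_duplication(self, rng):
        # weighting with n/(2*n_class) == literally duplicating the minority
        y = np.r_[np.zeros(20, int), np.ones(10, int)]
        p = rng.uniform(0.05, 0.95, size=30)
        weighted = loss(y, p, class_weights=balanced_class_weights(y))
        y_dup = np.r_[y, np.ones(10, int)]
        p_dup = np.r_[p, p[20:]]
        duplicated = loss(y_dup, p_dup)
        assert weighted == pytest.approx(duplicated, abs=1e-10)


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((12, 5))
        y = rng.integers(0, 2, size=12)
        w = np.ones(12)
        params = init_parameters(5, 4, rng, dtype=np.float64)
        # keep weights away from the L1 kink and pre-activations off the
        # ReLU kink (zero biases put fully-dead rows exactly at z = 0)
        for W in params.weights:
            W += 0.05 * np.sign(W) + 0.01
        for b in params.biases:
            b += 0.1
        tau, ups = 0.01, 0.02

        def f():
            return loss_and_gradients(params, x, y, w, tau, ups)[0]

        _, gw, gb, _ = loss_and_gradients(params, x, y, w, tau, ups)
        h = 1e-6
        for tensors, grads in ((params.weights, gw), (params.biases, gb)):
            for T, G in zip(tensors, grads):
                flat = T.reshape(-1)
                for idx in range(0, flat.size, max(1, flat.size // 10)):
                    orig = flat[idx]
                    flat[idx] = orig + h
                    up = f()
                    flat[idx] = orig - h
                    down = f()
                    flat[idx] = orig
                    num = (up - down) / (2 * h)
                    denom = max(abs(num), abs(G.reshape(-1)[idx]), 1e-8)
                    assert abs(num - G.reshape(-1)[idx]) / denom < 1e-5


class TestTraining:
    @pytest.fixture(scope="class")
    def separable_model(self):
        g, y = _toy_separable()
        x, stats = standardize(encode_one_hot(g))
        split = stratified_split(y, 0.8, seed=1)
        cfg = TrainingConfig(epochs=120, seed=1)
        model = train(
            x[split.train_indices].astype(np.float32), y.labels[split.train_indices], cfg
        )
        return model, x, y, split

    def test_separable_toy_high_accuracy(self, separable_model):
        model, x, y, split = separable_model
        acc = nn.accuracy(model, x[split.test_indices], y.labels[split.test_indices])
        assert acc >= 0.95

    def test_training_accuracy_improves(self, separable_model):
        model = separable_model[0]
        assert model.history["accuracy"][-1] >= model.history["accuracy"][0]
        assert len(model.history["val_loss"]) == 120

    def test_permuted_labels_give_chance_accuracy(self):
        g, y = _toy_separable(seed=3)
        rng = np.random.default_rng(9)
        y_perm = PhenotypeVector(rng.permutation(y.labels))
        x, _ = standardize(encode_one_hot(g))
        split = stratified_split(y_perm, 0.8, seed=2)
        cfg = TrainingConfig(epochs=60, seed=2)
        model = train(x[split.train_indices], y_perm.labels[split.train_indices], cfg)
        acc = nn.accuracy(model, x[split.test_indices], y_perm.labels[split.test_indices])
        n_test = len(split.test_indices)
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / n_test)

    def test_deterministic_under_seed(self):
        g, y = _toy_separable(seed=5, n=60)
        x, _ = standardize(encode_one_hot(g))
        cfg = TrainingConfig(epochs=10, seed=42)
        m1 = train(x, y.labels, cfg)
        m2 = train(x, y.labels, cfg)
        for a, b in zip(m1.params.weights, m2.params.weights):
            assert np.array_equal(a, b)

    def test_divergence_aborts_with_diagnostics(self):
        g, y = _toy_separable(seed=6, n=60)
        x, _ = standardize(encode_one_hot(g))
        cfg = TrainingConfig(epochs=50, seed=0, learning_rate=1e30, dropout=0.0)
        with pytest.raises(RuntimeError, match="diverged"):
            train(x, y.labels, cfg)

    def test_single_class_rejected(self):
        x = np.zeros((10, 6), dtype=np.float32)
        with pytest.raises(ValueError, match="both classes"):
            train(x, np.zeros(10, dtype=int), TrainingConfig(epochs=1))


class TestPredict:
    def _hand_network(self):
        # 2 -> 1 -> 1 -> 2 with simple integer weights, zero biases
        return NetworkParameters(
            [np.array([[2.0], [1.0]]), np.array([[1.0]]), np.array([[1.0, -1.0]])],
            [np.zeros(1), np.zeros(1), np.zeros(2)],
        )

    def test_forward_matches_hand_computation(self):
        params = self._hand_network()
        x = np.array([[1.0, 1.0]])
        acts = forward(params, x)
        # hidden1 = relu(2*1 + 1*1) = 3; hidden2 = relu(3) = 3; logits (3, -3)
        assert acts[1][0, 0] == pytest.approx(3.0)
        assert tuple(acts[-1][0]) == pytest.approx((3.0, -3.0))

    def test_softmax_outputs_sum_to_one(self, rng):
        logits = rng.standard_normal((40, 2))
        assert np.allclose(softmax(logits).sum(axis=1), 1.0, atol=1e-10)

    def test_prediction_invariant_to_logit_shift(self):
        params = self._hand_network()
        model = nn.TrainedModel(params, None, None)
        x = np.array([[1.0, 1.0], [0.2, -1.0]], dtype=np.float32)
        labels1, probs1, _ = predict(model, x)
        shifted = params.copy()
        shifted.biases[2] += 7.0
        labels2, probs2, _ = predict(nn.TrainedModel(shifted, None, None), x)
        assert np.array_equal(labels1, labels2)
        assert np.allclose(probs1, probs2, atol=1e-5)

    def test_width_mismatch_rejected(self):
        model = nn.TrainedModel(self._hand_network(), None, None)
        with pytest.raises(ValueError, match="width"):
            predict(model, np.zeros((3, 5), dtype=np.float32))


class TestPrefilter:
    def test_kappa_one_keeps_everything(self, small_dataset):
        mask, g = pvalue_prefilter(
            small_dataset.genotypes, small_dataset.phenotypes, kappa=1.0
        )
        assert mask.all()
        assert g.n_snps == small_dataset.genotypes.n_snps

    def test_kappa_zero_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="kappa"):
            pvalue_prefilter(small_dataset.genotypes, small_dataset.phenotypes, 0.0)

    def test_causal_snp_survives_prefilter(self):
        from deepcombi import SimulationConfig, simulate_dataset

        kept = 0
        for seed in range(10):
            ds = simulate_dataset(
                SimulationConfig(n_subjects=300, n_noise_snps=300, seed=40 + seed)
            )
            mask, _ = pvalue_prefilter(ds.genotypes, ds.phenotypes, kappa=1e-2)
            kept += bool(mask[ds.causal_index])
        assert kept >= 9
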