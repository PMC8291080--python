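import numpy as np
import pytest

from deepcombi import (
    LRPConfig,
    SelectionConfig,
    collapse_onehot,
    global_relevance,
    lrp_backward,
    moving_average_filter,
    select_top_k,
)
from deepcombi.nn import NetworkParameters, TrainedModel


def _model(weights, biases=None):
    if biases is None:
        biases = [np.zeros(w.shape[1]) for w in weights]
    return TrainedModel(NetworkParameters(list(weights), list(biases)), None, None)


def _brute_force_alpha_beta(activations, weights, relevance_out, alpha, beta):
    """Nested-loop reference implementation of the alpha-beta rule for one layer."""
    S, T = weights.shape
    r_in = np.zeros(S)
    for s in range(S):
        for t in range(T):
            z = [activations[s2] * weights[s2, t] for s2 in range(S)]
            zp = sum(v for v in z if v > 0)
            zn = sum(v for v in z if v < 0)
            own = activations[s] * weights[s, t]
            share = 0.0
            if own > 0 and zp != 0:
                share += alpha * own / zp
            if own < 0 and zn != 0:
                share -= beta * own / zn
            r_in[s] += share * relevance_out[t]
    return r_in


class TestAlphaBetaRule:
    def test_single_linear_layer_hand_example(self):
        # weights (2,1), inputs (1,1), alpha=1 beta=0: output relevance 3
        # splits proportionally into (2, 1)
        model = _model([np.array([[2.0], [1.0]]),
                        np.array([[1.0]]),
                        np.array([[1.0, 0.0]])])
        x = np.array([[1.0, 1.0]], dtype=np.float32)
        r0 = lrp_backward(model, x, LRPConfig(alpha=1, beta=0))
        assert r0[0] == pytest.approx([2.0, 1.0], abs=1e-6)

    def test_conservation_on_positive_network(self, rng):
        # bias-free positive weights, positive inputs, alpha-beta=(1,0):
        # total input relevance equals the propagated winning score
        for _ in range(10):
            weights = [
                rng.uniform(0.1, 1.0, size=(6, 5)),
                rng.uniform(0.1, 1.0, size=(5, 4)),
                rng.uniform(0.1, 1.0, size=(4, 2)),
            ]
            model = _model(weights)
            x = rng.uniform(0.1, 1.0, size=(3, 6)).astype(np.float32)
            r0 = lrp_backward(model, x, LRPConfig(alpha=1, beta=0))
            from deepcombi.nn import forward

            logits = forward(model.params, x)[-1]
            scores = logits.max(axis=1)
            assert np.allclose(r0.sum(axis=1), scores, rtol=1e-6)

    @pytest.mark.parametrize("alpha,beta", [(1.0, 0.0), (2.0, 1.0)])
    def test_matches_brute_force_two_layer(self, alpha, beta, rng):
        weights = [rng.standard_normal((4, 3)), rng.standard_normal((3, 3)),
                   rng.standard_normal((3, 2))]
        model = _model(weights)
        x = rng.standard_normal((1, 4)).astype(np.float32)
        from deepcombi.nn import forward

        acts = [a[0].astype(float) for a in forward(model.params, x)]
        logits = acts[-1]
        winner = int(np.argmax(logits))
        r = np.zeros(2)
        r[winner] = logits[winner]
        for q in (2, 1, 0):
            r = _brute_force_alpha_beta(acts[q], weights[q], r, alpha, beta)
        got = lrp_backward(model, x, LRPConfig(alpha=alpha, beta=beta))
        assert np.allclose(got[0], r, atol=1e-6)

    def test_zero_weight_snp_gets_zero_relevance(self, rng):
        # three input columns with zero outgoing weight receive no relevance
        w1 = rng.uniform(0.1, 1.0, size=(6, 4))
        w1[3:6] = 0.0
        model = _model([w1, rng.uniform(0.1, 1.0, size=(4, 3)),
                        rng.uniform(0.1, 1.0, size=(3, 2))])
        x = rng.uniform(0.5, 1.5, size=(5, 6)).astype(np.float32)
        r0 = lrp_backward(model, x)
        assert np.all(r0[:, 3:6] == 0.0)

    def test_alpha_beta_mismatch_warns(self):
        with pytest.warns(UserWarning, match="conservation"):
            LRPConfig(alpha=2.0, beta=0.5)


class TestCollapse:
    def test_triplet_arithmetic(self):
        out = collapse_onehot(np.array([[1.0, 2, 3, 4, 5, 6]]))
        assert out[0] == pytest.approx([2.0, 5.0])

    def test_constant_and_zero_triplets(self):
        assert collapse_onehot(np.array([[3.0, 3, 3]]))[0, 0] == pytest.approx(3.0)
        assert collapse_onehot(np.array([[0.0, 0, 0]]))[0, 0] == 0.0

    def test_masked_snps_reinserted_as_zero(self):
        mask = np.array([False, True, False])
        out = collapse_onehot(np.array([[3.0, 3, 3]]), mask)
        assert out.shape == (1, 3)
        assert out[0].tolist() == [0.0, 3.0, 0.0]

    def test_width_must_be_triplets(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            collapse_onehot(np.ones((1, 4)))


class TestGlobalRelevance:
    def test_single_subject_absolute_value(self):
        rel = global_relevance(np.array([[-2.0, 1.0]]), SelectionConfig(k=1, l=1))
        assert rel.r.tolist() == [2.0, 1.0]

    def test_zero_maps_stay_zero(self):
        rel = global_relevance(np.zeros((4, 6)), SelectionConfig(k=1, l=1))
        assert np.all(rel.r == 0)
        assert np.all(rel.r_filtered == 0)

    def test_subject_permutation_invariance(self, rng):
        rho = rng.standard_normal((10, 7))
        a = global_relevance(rho, SelectionConfig(k=1, l=3)).r
        b = global_relevance(rho[rng.permutation(10)], SelectionConfig(k=1, l=3)).r
        assert np.allclose(a, b)


class TestMovingAverageFilter:
    def test_window_one_is_identity(self, rng):
        r = rng.random(20)
        for p in (1.0, 2.0, 3.5):
            assert np.allclose(moving_average_filter(r, 1, p), r)

    def test_constant_vector_interior_closed_form(self):
        c, l = 0.7, 5
        out = moving_average_filter(np.full(50, c), l, 2.0)
        assert np.allclose(out[2:-2], c * np.sqrt(l))

    def test_unit_spike_spreads_over_window(self):
        r = np.zeros(100)
        r[50] = 1.0
        out = moving_average_filter(r, 3, 2.0)
        expected = np.zeros(100)
        expected[49:52] = 1.0
        assert np.allclose(out, expected)

    def test_boundary_truncation(self):
        out = moving_average_filter(np.ones(4), 3, 1.0)
        # edge windows hold 2 entries, interior 3
        assert np.allclose(out, [2.0, 3.0, 3.0, 2.0])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            moving_average_filter(np.ones(5), 4, 2.0)


class TestTopK:
    def test_selects_largest(self):
        mask = select_top_k(np.array([0.1, 0.9, 0.5]), 2)
        assert mask.tolist() == [False, True, True]

    def test_tie_break_by_lowest_index(self):
        mask = select_top_k(np.ones(5), 2)
        assert mask.tolist() == [True, True, False, False, False]

    def test_k_clips_to_d(self):
        assert select_top_k(np.array([0.3, 0.1]), 10).all()

    def test_deterministic_over_repeats(self, rng):
        scores = np.round(rng.random(50), 1)  # many ties
        masks = [select_top_k(scores, 7) for _ in range(5)]
        for m in masks[1:]:
            assert np.array_equal(m, masks[0])
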