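"""Binarized network: geometry/counting, XNOR-popcount primitives vs dense
float oracles, integer inference."""

import numpy as np
import pytest

from radarfall.bcnn import (
    FALL,
    NON_FALL,
    BCNNModel,
    NetworkSpec,
    binary_conv2d,
    binary_fc,
    count_parameters,
    infer,
    or_maxpool,
    packed_size_bytes,
    threshold_activate,
    weight_bit_count,
)

TABLE4 = [
    ((32, 32), (2,), 11168),
    ((32, 32), (32, 2), 26656),
    ((64, 64), (2,), 40768),
    ((64, 64), (32, 2), 71616),
    ((16, 16, 16), (2,), 5136),
    ((16, 32, 64), (2,), 23792),
    ((32, 32, 32), (2,), 19488),
    ((32, 32, 32), (32, 2), 20576),
    ((32, 64, 128), (2,), 93664),
]


def _random_model(spec: NetworkSpec, rng: np.random.Generator) -> BCNNModel:
    weights, bn = [], []
    fans = spec.layer_fan_ins()
    c_in = spec.input_shape[0]
    for i, c_out in enumerate(spec.conv_channels):
        k = spec.kernel(i)
        weights.append(rng.integers(0, 2, size=(c_out, c_in, k, k), dtype=np.uint8))
        c_in = c_out
    f_in = spec.flat_features()
    for f_out in spec.fc_sizes:
        weights.append(rng.integers(0, 2, size=(f_out, f_in), dtype=np.uint8))
        f_in = f_out
    for i in range(len(weights) - 1):
        c = weights[i].shape[0]
        bn.append(
            (rng.choice([-1, 1], size=c).astype(np.int64),
             rng.integers(0, fans[i] + 2, size=c).astype(np.int64))
        )
    return BCNNModel(spec=spec, weights=weights, bn=bn)


def _float_forward(model: BCNNModel, bits: np.ndarray) -> tuple[np.ndarray, list]:
    """Dense float reference of the whole network on +/-1 decodings."""
    from scipy.signal import correlate

    spec = model.spec
    fans = spec.layer_fan_ins()
    x = np.where(bits > 0, 1.0, -1.0)
    trace = []
    li = 0
    for _ in spec.conv_channels:
        w = np.where(model.weights[li] > 0, 1.0, -1.0)
        pre = np.stack(
            [sum(correlate(x[ci], w[co, ci], mode="valid", method="direct") for ci in range(x.shape[0]))
             for co in range(w.shape[0])]
        )
        trace.append(pre)
        gs, thr = model.bn[li]
        t_a = (2 * thr - fans[li]).reshape(-1, 1, 1)
        act = np.where(gs.reshape(-1, 1, 1) * (pre - t_a) >= 0, 1.0, -1.0)
        c, h, w_ = act.shape
        x = act[:, : h // 2 * 2, : w_ // 2 * 2].reshape(c, h // 2, 2, w_ // 2, 2).max(axis=(2, 4))
        trace.append(x)
        li += 1
    flat = x.reshape(-1)
    for j in range(len(spec.fc_sizes)):
        w = np.where(model.weights[li] > 0, 1.0, -1.0)
        pre = w @ flat
        trace.append(pre)
        if li < len(model.weights) - 1:
            gs, thr = model.bn[li]
            t_a = 2 * thr - fans[li]
            flat = np.where(gs * (pre - t_a) >= 0, 1.0, -1.0)
        li += 1
    return pre, trace


class TestCounting:
    @pytest.mark.parametrize("conv,fc,expected", TABLE4)
    def test_published_totals(self, conv, fc, expected):
        assert count_parameters(NetworkSpec(conv, fc)) == expected

    def test_degenerate_fc_only(self):
        spec = NetworkSpec((), (2,), input_shape=(1, 1, 1))
        assert count_parameters(spec) == 2  # 1*2 weights, no BN on final layer

    def test_collapsing_geometry_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec((8, 8, 8, 8), (2,))  # spatial size hits zero

    def test_packed_bytes(self):
        spec = NetworkSpec((32, 32, 32), (32, 2))
        assert packed_size_bytes(spec) == -(-20576 // 8) == 2572
        assert packed_size_bytes(spec) <= 2.6 * 1024

    def test_geometry_uniquely_reproduces_totals(self):
        """Brute-force over the natural configuration family: only first
        kernel 5 / later kernel 3 / valid padding / 2 BN params per channel
        / no biases reproduces every published total."""
        matches = []
        for k1 in (3, 5, 7):
            for k2 in (3, 5, 7):
                for same_pad in (False, True):
                    for bn_per in (1, 2, 4):
                        for bias in (False, True):
                            ok = True
                            for conv, fc, expected in TABLE4:
                                total = 0
                                size, c_in = 24, 1
                                try:
                                    for i, c_out in enumerate(conv):
                                        k = k1 if i == 0 else k2
                                        total += k * k * c_in * c_out
                                        total += bn_per * c_out + (c_out if bias else 0)
                                        if not same_pad:
                                            size = size - k + 1
                                        if size <= 0:
                                            raise ValueError
                                        size //= 2
                                        if size <= 0:
                                            raise ValueError
                                        c_in = c_out
                                    f_in = c_in * size * size
                                    for j, f_out in enumerate(fc):
                                        total += f_in * f_out + (f_out if bias else 0)
                                        if j < len(fc) - 1:
                                            total += bn_per * f_out
                                        f_in = f_out
                                except ValueError:
                                    ok = False
                                    break
                                if total != expected:
                                    ok = False
                                    break
                            if ok:
                                matches.append((k1, k2, same_pad, bn_per, bias))
        assert matches == [(5, 3, False, 2, False)]


class TestBinaryConv:
    def test_perfect_agreement_and_disagreement(self):
        x = np.ones((1, 5, 5), dtype=np.uint8)
        w = np.ones((1, 1, 3, 3), dtype=np.uint8)
        assert np.all(binary_conv2d(x, w) == 9)
        assert np.all(binary_conv2d(x, np.zeros_like(w)) == -9)

    @pytest.mark.parametrize("k,c_in", [(3, 1), (3, 32), (5, 1), (5, 32)])
    def test_matches_float_oracle(self, k, c_in):
        from scipy.signal import correlate

        rng = np.random.default_rng(k * 100 + c_in)
        for _ in range(50):
            h = rng.integers(k, k + 6)
            w_ = rng.integers(k, k + 6)
            c_out = int(rng.integers(1, 5))
            x = rng.integers(0, 2, size=(c_in, h, w_), dtype=np.uint8)
            wt = rng.integers(0, 2, size=(c_out, c_in, k, k), dtype=np.uint8)
            got = binary_conv2d(x, wt)
            xf = np.where(x > 0, 1.0, -1.0)
            wf = np.where(wt > 0, 1.0, -1.0)
            ref = np.stack(
                [sum(correlate(xf[ci], wf[co, ci], mode="valid", method="direct") for ci in range(c_in))
                 for co in range(c_out)]
            )
            np.testing.assert_array_equal(got, ref.astype(np.int64))

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            binary_conv2d(np.ones((2, 5, 5), np.uint8), np.ones((1, 1, 3, 3), np.uint8))
        with pytest.raises(ValueError):
            binary_conv2d(np.ones((1, 2, 2), np.uint8), np.ones((1, 1, 3, 3), np.uint8))


class TestThresholdActivate:
    def test_inclusive_at_threshold(self):
        n = 9
        thr = np.array([5])  # T_a = 2*5 - 9 = 1
        pre = np.array([[1]])
        assert threshold_activate(pre, np.array([1]), thr, n)[0, 0] == 1
        assert threshold_activate(np.array([[0]]), np.array([1]), thr, n)[0, 0] == 0

    def test_negative_gamma_flips_strictly(self):
        n = 25
        rng = np.random.default_rng(1)
        thr = rng.integers(0, n + 2, size=4)
        pre = rng.integers(-n, n + 1, size=(4, 6))
        pos = threshold_activate(pre, np.ones(4, np.int64), thr, n)
        neg = threshold_activate(pre, -np.ones(4, np.int64), thr, n)
        t_a = (2 * thr - n).reshape(-1, 1)
        strictly_off = pre != t_a
        assert np.array_equal(pos[strictly_off] ^ 1, neg[strictly_off])
        assert np.all(pos[~strictly_off] == 1) and np.all(neg[~strictly_off] == 1)

    def test_matches_bn_sign_oracle(self):
        """Fold real BN params to popcount thresholds, then check the
        integer decision equals sign(BN(preact)) everywhere."""
        from radarfall.bcnn import popcount_threshold_from_real
        from radarfall.ppu import BnFoldParams, fold_bn_to_threshold

        rng = np.random.default_rng(2)
        n = 45  # odd fan-in: preactivations have the parity of n
        for _ in range(100):
            p = BnFoldParams(
                gamma=rng.choice([-1, 1]) * rng.uniform(0.1, 3),
                beta=rng.normal(0, 2),
                mu=rng.normal(0, 5),
                sigma2=rng.uniform(0, 50),
            )
            t_real, gs0 = fold_bn_to_threshold(p)
            gs, thr = popcount_threshold_from_real(t_real, n, gs0)
            pre = np.arange(-n, n + 1, 2)  # all reachable preactivations
            got = threshold_activate(pre[None, :], np.array([gs]), np.array([thr]), n)[0]
            bn = p.gamma * (pre - p.mu) / np.sqrt(p.sigma2 + p.eps) + p.beta
            np.testing.assert_array_equal(got, (bn >= 0).astype(np.uint8))


class TestOrPool:
    def test_or_semantics(self):
        x = np.zeros((1, 4, 4), np.uint8)
        assert not or_maxpool(x).any()
        x[0, 1, 0] = 1  # single bit lights its window
        assert or_maxpool(x)[0, 0, 0] == 1 and or_maxpool(x).sum() == 1

    def test_matches_float_maxpool(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            c, h, w = rng.integers(1, 5), rng.integers(2, 9), rng.integers(2, 9)
            bits = rng.integers(0, 2, size=(c, h, w), dtype=np.uint8)
            got = or_maxpool(bits)
            pm = np.where(bits > 0, 1.0, -1.0)
            oh, ow = h // 2, w // 2
            ref = pm[:, : oh * 2, : ow * 2].reshape(c, oh, 2, ow, 2).max(axis=(2, 4))
            np.testing.assert_array_equal(got, (ref > 0).astype(np.uint8))


class TestInfer:
    def test_forced_tie_is_non_fall(self):
        spec = NetworkSpec((4,), (2,))
        model = _random_model(spec, np.random.default_rng(0))
        model.weights[-1] = np.tile(model.weights[-1][0], (2, 1))  # equal rows
        label, scores = infer(model, np.random.default_rng(1).integers(0, 2, (24, 24)))
        assert scores[0] == scores[1] and label == NON_FALL

    def test_final_layer_bit_flip_swaps_scores(self):
        spec = NetworkSpec((4,), (2,))
        rng = np.random.default_rng(5)
        model = _random_model(spec, rng)
        bits = rng.integers(0, 2, (24, 24), dtype=np.uint8)
        _, scores = infer(model, bits)
        model.weights[-1] = 1 - model.weights[-1]
        _, flipped = infer(model, bits)
        np.testing.assert_array_equal(flipped, -scores)

    @pytest.mark.parametrize("conv,fc", [((4,), (2,)), ((8, 8), (2,)), ((8, 8, 8), (4, 2))])
    def test_matches_float_network_oracle(self, conv, fc):
        """Integer XNOR/popcount inference equals the dense float network
        on +/-1 decodings, for random models and inputs."""
        spec = NetworkSpec(conv, fc)
        for trial in range(40):
            rng = np.random.default_rng(1000 * len(conv) + trial)
            model = _random_model(spec, rng)
            bits = rng.integers(0, 2, (24, 24), dtype=np.uint8)
            label, scores = infer(model, bits)
            ref_scores, _ = _float_forward(model, bits[None])
            np.testing.assert_array_equal(scores, ref_scores.astype(np.int64))
            assert label == (FALL if ref_scores[FALL] > ref_scores[NON_FALL] else NON_FALL)

    def test_shape_mismatch_rejected(self):
        model = _random_model(NetworkSpec((4,), (2,)), np.random.default_rng(0))
        with pytest.raises(ValueError):
            infer(model, np.zeros((20, 20), np.uint8))

    def test_model_invariants_enforced(self):
        spec = NetworkSpec((4,), (2,))
        model = _random_model(spec, np.random.default_rng(0))
        bad_bn = [(model.bn[0][0], model.bn[0][1] + 10_000)]
        with pytest.raises(ValueError, match="threshold"):
            BCNNModel(spec=spec, weights=model.weights, bn=bad_bn)

    def test_weight_count_validation(self):
        spec = NetworkSpec((4,), (2,))
        model = _random_model(spec, np.random.default_rng(0))
        model.validate_counts()
        assert sum(w.size for w in model.weights) == weight_bit_count(spec)
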