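"""Network primitives against brute-force oracles; reference architecture; gradients."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from actimage.cnn import (
    ArchitectureSpec,
    LayerKind,
    LayerSpec,
    build_reference_architecture,
    conv_output_size,
    max_pool,
    relu,
    softmax,
    trace_shapes,
)
from actimage.network import NumpyCNN


def brute_force_placements(K, L):
    """Count positions where a length-L window fits inside a length-K input."""
    return sum(1 for start in range(K) if start + L <= K)


def brute_force_max_pool(x, k, s, p):
    xp = np.pad(np.asarray(x, float), p)  # zero padding, as the primitive defines
    H, W = xp.shape
    ho = (H - k) // s + 1
    wo = (W - k) // s + 1
    out = np.empty((ho, wo))
    for i in range(ho):
        for j in range(wo):
            out[i, j] = xp[i * s : i * s + k, j * s : j * s + k].max()
    return out


class TestConvOutputSize:
    def test_table_row(self):
        # 13x22 feature map through a 3x3 valid convolution -> 11x20
        assert conv_output_size(13, 3) == 11
        assert conv_output_size(22, 3) == 20

    def test_kernel_covering_input(self):
        assert conv_output_size(5, 5) == 1

    def test_exhaustive_small_cases_match_placement_count(self):
        for K in range(1, 11):
            for L in range(1, K + 1):
                assert conv_output_size(K, L) == brute_force_placements(K, L)

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError):
            conv_output_size(3, 4)


class TestRelu:
    def test_definition(self):
        np.testing.assert_array_equal(relu([-2, 0, 3]), [0, 0, 3])

    def test_all_negative_and_idempotence(self, rng):
        x = -np.abs(rng.normal(size=20)) - 0.1
        assert (relu(x) == 0).all()
        y = rng.normal(size=50)
        np.testing.assert_array_equal(relu(relu(y)), relu(y))


class TestMaxPool:
    def test_window_covering_grid(self):
        np.testing.assert_array_equal(max_pool([[1, 2], [3, 4]], k=2, s=1), [[4]])

    def test_constant_grid(self):
        out = max_pool(np.full((5, 5), 7.0), k=2, s=2)
        assert (out == 7.0).all()

    @given(
        st.integers(1, 3), st.integers(1, 3), st.integers(0, 3),
        st.integers(0, 10_000),
    )
    def test_matches_sliding_window_oracle(self, k, s, p, seed):
        x = np.random.default_rng(seed).normal(size=(9, 9))
        np.testing.assert_array_equal(max_pool(x, k, s, p), brute_force_max_pool(x, k, s, p))

    def test_window_exceeding_input_rejected(self):
        with pytest.raises(ValueError):
            max_pool(np.zeros((2, 2)), k=5, s=1)


class TestSoftmax:
    def test_symmetry(self):
        np.testing.assert_allclose(softmax([0, 0, 0]), [1 / 3] * 3)

    def test_sums_to_one_and_shift_invariance(self, rng):
        z = rng.normal(scale=3, size=(10, 3))
        p = softmax(z, axis=1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert ((p > 0) & (p < 1)).all()
        np.testing.assert_allclose(softmax(z + 17.3, axis=1), p, atol=1e-9)

    def test_extreme_scores_stay_finite(self):
        assert np.isfinite(softmax([1000.0, -1000.0, 0.0])).all()


class TestReferenceArchitecture:
    def test_dense_widths_and_head(self):
        arch = build_reference_architecture()
        widths = [l.width for l in arch.layers if l.kind is LayerKind.DENSE]
        assert widths == [900, 300, 100, 3]
        assert arch.layers[-1].kind is LayerKind.SOFTMAX
        assert arch.num_classes == 3

    def test_shape_trace(self):
        arch = build_reference_architecture()
        trace = trace_shapes(arch)
        shapes = [s for _, s in trace.entries]
        assert shapes[0] == (30, 48, 1)
        assert (28, 46, 48) in shapes and (13, 22, 48) in shapes
        assert (11, 20, 48) in shapes and (1, 3, 48) in shapes
        assert trace.flattened == 144

    def test_printed_chain_1x4x48_flattens_to_192(self):
        arch = ArchitectureSpec(
            layers=[
                LayerSpec(LayerKind.FLATTEN),
                LayerSpec(LayerKind.DENSE, width=3),
                LayerSpec(LayerKind.SOFTMAX),
            ],
            input_shape=(1, 4, 48),
        )
        assert trace_shapes(arch).flattened == 192

    def test_five_dropout_variant(self):
        arch = build_reference_architecture(conv_dropout=True)
        assert sum(l.kind is LayerKind.DROPOUT for l in arch.layers) == 5

    def test_identity_architecture_preserves_input(self):
        arch = ArchitectureSpec(layers=[], input_shape=(7, 9, 1))
        trace = trace_shapes(arch)
        assert trace.entries == [("input", (7, 9, 1))]

    def test_impossible_geometry_names_layer(self):
        arch = ArchitectureSpec(
            layers=[LayerSpec(LayerKind.CONV, filters=4, kernel=9)],
            input_shape=(5, 5, 1),
        )
        with pytest.raises(ValueError, match="conv_0"):
            trace_shapes(arch)

    def test_yaml_round_trip(self, tmp_path):
        arch = build_reference_architecture()
        path = tmp_path / "arch.yaml"
        arch.to_yaml(path)
        back = ArchitectureSpec.from_yaml(path)
        assert back.input_shape == arch.input_shape
        assert [l.kind for l in back.layers] == [l.kind for l in arch.layers]
        assert [l.width for l in back.layers] == [l.width for l in arch.layers]


def _small_arch(seed):
    """Randomized small conv/pool stacks for the trace-vs-execution oracle."""
    rng = np.random.default_rng(seed)
    h, w = int(rng.integers(8, 15)), int(rng.integers(8, 15))
    layers = []
    for _ in range(int(rng.integers(1, 3))):
        layers += [
            LayerSpec(LayerKind.CONV, filters=int(rng.integers(1, 5)),
                      kernel=int(rng.integers(1, 4))),
            LayerSpec(LayerKind.RELU),
            LayerSpec(LayerKind.MAXPOOL, kernel=2, stride=int(rng.integers(1, 3))),
        ]
    layers += [
        LayerSpec(LayerKind.FLATTEN),
        LayerSpec(LayerKind.DENSE, width=3),
        LayerSpec(LayerKind.SOFTMAX),
    ]
    return ArchitectureSpec(layers=layers, input_shape=(h, w, 1))


class TestNetworkExecution:
    @pytest.mark.parametrize("seed", range(5))
    def test_trace_matches_actual_forward_shapes(self, seed):
        try:
            arch = _small_arch(seed)
            trace = trace_shapes(arch)
        except ValueError:
            pytest.skip("randomized geometry was inconsistent")
        model = NumpyCNN(arch, seed=seed)
        x = np.random.default_rng(seed).normal(size=(2, *arch.input_shape)).astype(np.float32)
        out = x
        positions = [
            i for i, s in enumerate(arch.layers) if s.kind is not LayerKind.SOFTMAX
        ]
        for layer, pos in zip(model.layers, positions):
            out = layer.forward(out, train=False)
            assert out.shape[1:] == trace.entries[pos + 1][1]

    def test_forward_yields_probability_vector(self, rng):
        model = NumpyCNN(build_reference_architecture(), seed=0)
        x = rng.normal(size=(4, 30, 48, 1)).astype(np.float32)
        p = model.predict_proba(x)
        assert p.shape == (4, 3)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_is_deterministic_despite_dropout(self, rng):
        model = NumpyCNN(build_reference_architecture(dropout_rate=0.5), seed=0)
        x = rng.normal(size=(3, 30, 48, 1)).astype(np.float32)
        np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_same_seed_same_initialization(self):
        arch = build_reference_architecture()
        a, b = NumpyCNN(arch, seed=11), NumpyCNN(arch, seed=11)
        for pa, pb in zip(a.parameters, b.parameters):
            np.testing.assert_array_equal(pa, pb)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        arch = build_reference_architecture()
        a = NumpyCNN(arch, seed=1)
        a.save(tmp_path / "model.npz", manifest={"seed": 1})
        b = NumpyCNN(arch, seed=2)
        b.load_weights(tmp_path / "model.npz")
        x = rng.normal(size=(2, 30, 48, 1)).astype(np.float32)
        np.testing.assert_allclose(a.predict_proba(x), b.predict_proba(x), atol=1e-7)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Analytic gradients agree with central differences on a tiny net."""
        arch = ArchitectureSpec(
            layers=[
                LayerSpec(LayerKind.CONV, filters=2, kernel=2),
                LayerSpec(LayerKind.RELU),
                LayerSpec(LayerKind.MAXPOOL, kernel=2, stride=2),
                LayerSpec(LayerKind.FLATTEN),
                LayerSpec(LayerKind.DENSE, width=3),
                LayerSpec(LayerKind.SOFTMAX),
            ],
            input_shape=(6, 8, 1),
        )
        model = NumpyCNN(arch, seed=0, dtype=np.float64)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(4, 6, 8, 1))
        y = rng.integers(0, 3, size=4)
        model.loss_and_backward(x, y, train=True)  # no dropout in this arch
        grads = [g.copy() for g in model.gradients]
        eps = 1e-6
        checked = 0
        for p, g in zip(model.parameters, grads):
            flat_idx = rng.choice(p.size, size=min(6, p.size), replace=False)
            for idx in flat_idx:
                orig = p.flat[idx]
                p.flat[idx] = orig + eps
                lp, _ = model.loss_and_backward(x, y, train=True)
                p.flat[idx] = orig - eps
                lm, _ = model.loss_and_backward(x, y, train=True)
                p.flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert g.flat[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)
                checked += 1
        assert checked >= 15  # a handful of entries from every parameter tensor
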