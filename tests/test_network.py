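"""Network construction: shape conformance, parameter counts, gradients."""

import numpy as np
import pytest

from vmatqa.errors import ConstructionError, ParameterError
from vmatqa.network import (
    MODEL_BRANCHES,
    NetworkConfig,
    branch_layer_shapes,
    build_network,
    count_parameters,
)

# intermediate output shapes of every branch at clinical scale (H, W, C)
BRANCH_SHAPE_TABLE = {
    "sagittal": [(68, 146, 16), (22, 48, 16), (20, 46, 16), (6, 15, 16), (4, 13, 16), (1, 4, 16)],
    "coronal": [(64, 200, 16), (21, 66, 16), (19, 64, 16), (6, 21, 16), (4, 19, 16), (1, 6, 16)],
    "axial": [(143, 242, 16), (47, 80, 16), (45, 78, 16), (15, 26, 16), (13, 24, 16), (4, 8, 16)],
    "mlpm": [(110, 178, 16), (36, 59, 16), (34, 57, 16), (11, 19, 16), (9, 17, 16), (3, 5, 16)],
    "surface": [(220, 680, 16), (73, 226, 16), (71, 224, 16), (23, 74, 16), (21, 72, 16), (7, 24, 16)],
}
LAYER_ORDER = ["Convolution_1", "Max Pooling_1", "Convolution_2", "Max Pooling_2",
               "Convolution_3", "Max Pooling_3"]

AFFINE1_PARAMS = {"sagittal": 1300, "coronal": 1940, "axial": 10260,
                  "mlpm": 4820, "surface": 53780}


class TestShapes:
    @pytest.mark.parametrize("branch", sorted(BRANCH_SHAPE_TABLE))
    def test_branch_intermediate_shapes(self, branch):
        from vmatqa.network import DEFAULT_BRANCH_SHAPES

        shapes = branch_layer_shapes(DEFAULT_BRANCH_SHAPES[branch])
        for layer, expected in zip(LAYER_ORDER, BRANCH_SHAPE_TABLE[branch]):
            assert shapes[layer] == expected, f"{branch}/{layer}"
        assert shapes["Affine_1"] == (20,)

    def test_branch_counts_per_variant(self):
        for variant, expected in [("model1", 4), ("model2", 3), ("model3", 1)]:
            net = build_network(NetworkConfig(variant))
            assert len(net.branches) == expected
        assert MODEL_BRANCHES["model1"] == ("sagittal", "coronal", "axial", "mlpm")

    def test_infeasible_input_shape_rejected(self):
        with pytest.raises(ConstructionError):
            build_network(NetworkConfig("model3", input_shapes={"surface": (10, 10)}))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ParameterError):
            NetworkConfig("model4")

    def test_config_dict_round_trip(self):
        cfg = NetworkConfig("model2", input_shapes={"sagittal": (51, 51)}, seed=7)
        back = NetworkConfig.from_dict(cfg.to_dict())
        assert back.variant == cfg.variant
        assert back.seed == cfg.seed
        assert back.branch_specs() == cfg.branch_specs()


class TestParameterCounts:
    def test_conv_and_affine_counts(self):
        net = build_network(NetworkConfig("model1"))
        net3 = build_network(NetworkConfig("model3"))
        for branch in ("sagittal", "coronal", "axial", "mlpm"):
            assert count_parameters(net, f"{branch}/Convolution_1") == 160
            assert count_parameters(net, f"{branch}/Convolution_2") == 2320
            assert count_parameters(net, f"{branch}/Convolution_3") == 2320
            assert count_parameters(net, f"{branch}/Affine_1") == AFFINE1_PARAMS[branch]
        assert count_parameters(net3, "surface/Affine_1") == 53780
        assert count_parameters(net, "Affine_2") == 420
        assert count_parameters(net, "Affine_3") == 21
        # batch norm over 20 features: 2 learnable parameters per feature
        assert count_parameters(net, "Batch Normalization") == 40

    def test_unknown_layer_is_lookup_error(self):
        net = build_network(NetworkConfig("model3"))
        with pytest.raises(KeyError):
            count_parameters(net, "Convolution_9")


class TestForward:
    def test_zero_input_gives_finite_nine_vector(self):
        net = build_network(NetworkConfig("model3", input_shapes={"surface": (51, 51)}))
        out = net.predict({"surface": np.zeros((2, 51, 51), dtype=np.float32)})
        assert out.shape == (2, 9)
        assert np.all(np.isfinite(out))

    def test_inference_is_deterministic(self):
        rng = np.random.default_rng(0)
        shapes = {n: (51, 51) for n in ("sagittal", "coronal", "axial")}
        net = build_network(NetworkConfig("model2", input_shapes=shapes))
        x = {n: rng.random((3, 51, 51), dtype=np.float32) for n in shapes}
        np.testing.assert_array_equal(net.predict(x), net.predict(x))

    def test_shape_mismatch_rejected(self):
        net = build_network(NetworkConfig("model3", input_shapes={"surface": (51, 51)}))
        with pytest.raises(ParameterError):
            net.forward({"surface": np.zeros((1, 60, 60))})
        with pytest.raises(ParameterError):
            net.forward({})


class TestCheckpoint:
    def test_save_load_round_trip_and_manifest_guard(self, tmp_path):
        from vmatqa.errors import ParameterError
        from vmatqa.network import load_checkpoint, save_checkpoint

        rng = np.random.default_rng(0)
        net = build_network(NetworkConfig("model3", input_shapes={"surface": (51, 51)}, seed=1))
        x = {"surface": rng.random((2, 51, 51), dtype=np.float32)}
        before = net.predict(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path)

        other = build_network(NetworkConfig("model3", input_shapes={"surface": (51, 51)}, seed=9))
        assert not np.array_equal(other.predict(x), before)
        manifest = load_checkpoint(other, path)
        np.testing.assert_array_equal(other.predict(x), before)
        assert manifest["surface/Affine_1"] == 340  # 16 flat features -> 20

        wrong = build_network(NetworkConfig("model2", input_shapes={
            n: (51, 51) for n in ("sagittal", "coronal", "axial")}))
        with pytest.raises(ParameterError):
            load_checkpoint(wrong, path)


class TestGradients:
    @staticmethod
    def _param_check(layer, x, rng, rel, n_probes=6):
        out = layer.forward(x, True)
        cotangent = rng.standard_normal(out.shape)
        for p in layer.params():
            p.grad[...] = 0
        layer.backward(cotangent)

        def loss():
            return float(np.sum(layer.forward(x, True) * cotangent))

        eps = 1e-6
        for p in layer.params():
            flat = p.value.reshape(-1)
            grad = p.grad.reshape(-1)
            for idx in rng.choice(flat.size, min(n_probes, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert numeric == pytest.approx(grad[idx], rel=rel, abs=1e-7), p.name

    def test_layer_gradients_match_finite_differences(self):
        """Central-difference check of every parameterized layer type."""
        from vmatqa.nn import Affine, BatchNorm1D, Conv2D

        rng = np.random.default_rng(2)
        x_img = rng.standard_normal((3, 2, 9, 9))
        x_vec = rng.standard_normal((5, 7))
        self._param_check(Conv2D(2, 4, pad=1, rng=rng, dtype=np.float64), x_img, rng, rel=1e-6)
        self._param_check(Conv2D(2, 4, pad=0, rng=rng, dtype=np.float64), x_img, rng, rel=1e-6)
        self._param_check(Affine(7, 3, rng=rng, dtype=np.float64), x_vec, rng, rel=1e-6)
        self._param_check(BatchNorm1D(7, dtype=np.float64), x_vec, rng, rel=1e-4)

    def test_full_network_gradient_wiring(self):
        """End-to-end backward agrees with central differences.

        The step is kept small (1e-7) so that probes do not flip max-pool
        argmax selections inside the difference window.
        """
        config = NetworkConfig("model3", input_shapes={"surface": (51, 51)},
                               dropout_rate=0.0, seed=1)
        net = build_network(config, dtype=np.float64)
        rng = np.random.default_rng(2)
        x = {"surface": rng.random((3, 51, 51))}

        def loss():
            out = net.forward(x, train=True)
            return 0.5 * float(np.sum(out**2))

        out = net.forward(x, train=True)
        for p in net.params():
            p.grad[...] = 0
        net.backward(out.copy())

        eps = 1e-7
        rng_pick = np.random.default_rng(3)
        for p in net.params():
            flat = p.value.reshape(-1)
            gflat = p.grad.reshape(-1)
            for idx in rng_pick.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert numeric == pytest.approx(gflat[idx], rel=1e-4, abs=1e-6), p.name
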