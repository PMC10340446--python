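import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pneumoscope.classifier import _batch_step
from pneumoscope.models import (ConvAutoencoder, ModelSpec, SpecError,
                                VariationalConvAutoencoder, build_model,
                                corrupt_zero_mask, loss_beta_kl,
                                loss_reconstruction, loss_sparsity,
                                reconstruct, squash_mean_activation,
                                total_loss)


def _rand_image(seed, shape=(64, 64)):
    return np.random.default_rng(seed).random(shape, dtype=np.float32)


class TestModelSpec:
    def test_hidden_filter_invariants(self):
        assert ModelSpec("pcae", 2).hidden_filters == (16, 16)
        assert ModelSpec("pcae", 4).hidden_filters == (32, 16, 16, 32)

    @pytest.mark.parametrize("kwargs", [
        {"variant": "vae"},
        {"n_hidden_layers": 3},
        {"sigma": 1.5},
        {"z": 0.0},
        {"gamma": -1.0},
        {"beta": -0.5},
        {"variant": "bvcae", "latent_dim": 0},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(SpecError):
            ModelSpec(**kwargs)


class TestBuildModel:
    def test_parameter_counts(self):
        # 2 hidden convs (16 filters each) + single-filter output, 3x3+bias:
        # (1*9+1)*16 + (16*9+1)*16 + (16*9+1)*1
        assert build_model(ModelSpec("pcae", 2), 0).n_params() == 2625
        # 32,16,16,32 hidden + output
        assert build_model(ModelSpec("pcae", 4), 0).n_params() == \
            (1 * 9 + 1) * 32 + (32 * 9 + 1) * 16 + (16 * 9 + 1) * 16 \
            + (16 * 9 + 1) * 32 + (32 * 9 + 1) * 1

    def test_seed_determinism_of_init(self):
        a = build_model(ModelSpec("scae", 4), 7)
        b = build_model(ModelSpec("scae", 4), 7)
        for (pa, _), (pb, _) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)

    def test_variant_dispatch(self):
        assert isinstance(build_model(ModelSpec("bvcae", 2), 0),
                          VariationalConvAutoencoder)
        assert isinstance(build_model(ModelSpec("dcae", 2), 0),
                          ConvAutoencoder)


class TestReconstruct:
    def test_eval_mode_is_deterministic(self):
        x = _rand_image(0)
        for variant in ("pcae", "bvcae"):
            model = build_model(ModelSpec(variant, 2), 1)
            r1 = reconstruct(model, x, mode="eval", seed=1)
            r2 = reconstruct(model, x, mode="eval", seed=99)
            assert np.array_equal(r1.output, r2.output)

    def test_output_matches_input_shape_and_open_interval(self):
        x = np.full((64, 64), 0.5, dtype=np.float32)
        model = build_model(ModelSpec("pcae", 2), 3)
        rec = reconstruct(model, x)
        assert rec.output.shape == (64, 64)
        assert (rec.output > 0).all() and (rec.output < 1).all()

    def test_dcae_sigma_zero_train_equals_pcae_forward(self):
        x = _rand_image(5)
        pcae = build_model(ModelSpec("pcae", 2), 11)
        dcae = build_model(ModelSpec("dcae", 2, sigma=0.0), 11)
        yp = reconstruct(pcae, x, mode="train", seed=2).output
        yd = reconstruct(dcae, x, mode="train", seed=2).output
        assert np.array_equal(yp, yd)

    def test_bvcae_train_mode_varies_with_seed(self):
        x = _rand_image(6)
        model = build_model(ModelSpec("bvcae", 2), 4)
        y1 = reconstruct(model, x, mode="train", seed=1).output
        y2 = reconstruct(model, x, mode="train", seed=2).output
        e1 = reconstruct(model, x, mode="eval", seed=1).output
        e2 = reconstruct(model, x, mode="eval", seed=2).output
        assert not np.array_equal(y1, y2)
        assert np.array_equal(e1, e2)


class TestCorruption:
    def test_sigma_zero_identity_and_sigma_one_blackout(self):
        x = _rand_image(1)
        assert np.array_equal(corrupt_zero_mask(x, 0.0, 0), x)
        assert not corrupt_zero_mask(x, 1.0, 0).any()

    def test_masked_fraction_matches_binomial(self):
        x = np.ones((100, 1000), dtype=np.float32)
        out = corrupt_zero_mask(x, 0.1, np.random.default_rng(8))
        frac = 1.0 - out.mean()
        se = math.sqrt(0.1 * 0.9 / x.size)
        assert abs(frac - 0.1) < 3 * se

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            corrupt_zero_mask(_rand_image(0), 1.2, 0)


class TestLossOracles:
    """Vectorised losses must agree with naive elementwise summation."""

    def test_mse_against_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(250):
            x = rng.random(40)
            y = rng.random(40)
            naive = sum((xi - yi) ** 2 for xi, yi in zip(x, y))
            assert loss_reconstruction(x, y, "mse") == \
                pytest.approx(naive, rel=1e-6)

    def test_bernoulli_ce_against_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(250):
            x = rng.random(30)
            y = rng.uniform(0.01, 0.99, 30)
            naive = -sum(xi * math.log(yi) + (1 - xi) * math.log(1 - yi)
                         for xi, yi in zip(x, y))
            assert loss_reconstruction(x, y, "bernoulli_ce") == \
                pytest.approx(naive, rel=1e-6)

    def test_sparsity_kl_against_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(250):
            z = rng.uniform(0.05, 0.95)
            gamma = rng.uniform(0, 2)
            zbar = rng.uniform(0.01, 0.99, 16)
            naive = gamma * sum(
                z * math.log(z / zb) + (1 - z) * math.log((1 - z) / (1 - zb))
                for zb in zbar)
            assert loss_sparsity(zbar, z, gamma) == \
                pytest.approx(naive, rel=1e-6, abs=1e-12)

    def test_gaussian_kl_against_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(250):
            mu = rng.normal(size=8)
            lv = rng.normal(scale=0.5, size=8)
            beta = rng.uniform(0, 5)
            naive = beta * 0.5 * sum(
                m ** 2 + math.exp(v) - 1 - v for m, v in zip(mu, lv))
            assert loss_beta_kl(mu, lv, beta) == \
                pytest.approx(naive, rel=1e-6, abs=1e-12)

    def test_known_values(self):
        x = np.ones(4096)
        assert loss_reconstruction(x, x) == 0.0
        assert loss_reconstruction(x, np.zeros(4096)) == 4096.0
        # single unit, z=0.5, zbar=0.25
        expect = 0.5 * math.log(0.5 / 0.25) + 0.5 * math.log(0.5 / 0.75)
        assert loss_sparsity(np.array([0.25]), 0.5, 1.0) == \
            pytest.approx(expect)
        assert expect == pytest.approx(0.14384, abs=1e-5)
        assert loss_beta_kl(np.zeros(3), np.zeros(3), 5.0) == 0.0
        assert loss_beta_kl(np.array([1.0]), np.array([0.0]), 1.0) == \
            pytest.approx(0.5)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_losses_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(20), rng.uniform(0.01, 0.99, 20)
        assert loss_reconstruction(x, y, "mse") >= 0
        assert loss_reconstruction(x, y, "bernoulli_ce") >= 0
        assert loss_sparsity(rng.uniform(0.01, 0.99, 5),
                             rng.uniform(0.05, 0.95), rng.uniform(0, 3)) >= 0
        assert loss_beta_kl(rng.normal(size=4), rng.normal(size=4),
                            rng.uniform(0, 5)) >= 0

    def test_gaussian_kl_zero_iff_standard_normal(self):
        assert loss_beta_kl(np.zeros(6), np.zeros(6), 1.0) == 0.0
        assert loss_beta_kl(np.full(6, 0.1), np.zeros(6), 1.0) > 0
        assert loss_beta_kl(np.zeros(6), np.full(6, -0.1), 1.0) > 0


class TestTotalLoss:
    def test_pcae_total_is_reconstruction(self):
        model = build_model(ModelSpec("pcae", 2), 0)
        x = _rand_image(2)
        rec = reconstruct(model, x)
        terms = total_loss(model.spec, x, rec)
        assert terms["total"] == terms["reconstruction"]

    def test_scae_gamma_zero_matches_pcae(self):
        x = _rand_image(3)
        pcae = build_model(ModelSpec("pcae", 2), 5)
        scae = build_model(ModelSpec("scae", 2, gamma=0.0), 5)
        tp = total_loss(pcae.spec, x, reconstruct(pcae, x))
        ts = total_loss(scae.spec, x, reconstruct(scae, x))
        assert ts["total"] == tp["total"]
        assert ts["sparsity"] == 0.0

    def test_component_mismatch_rejected(self):
        model = build_model(ModelSpec("pcae", 2), 0)
        x = _rand_image(4)
        rec = reconstruct(model, x)
        rec.per_sample_loss_terms["kl"] = 1.0
        with pytest.raises(RuntimeError):
            total_loss(model.spec, x, rec)


class TestDegenerateEquivalence:
    """DCAE(sigma=0) and SCAE(gamma=0) are bit-equal to PCAE in loss and
    gradient at shared parameters."""

    def test_losses_and_gradients_bit_equal(self, small_synth):
        _, normals, _ = small_synth
        xb = normals[:8][..., None]
        specs = {
            "pcae": ModelSpec("pcae", 2),
            "dcae0": ModelSpec("dcae", 2, sigma=0.0),
            "scae0": ModelSpec("scae", 2, gamma=0.0),
        }
        results = {}
        for name, spec in specs.items():
            model = build_model(spec, 77)
            terms = _batch_step(model, xb, np.random.default_rng(1),
                                np.random.default_rng(2))
            results[name] = (terms["loss"],
                             [g.copy() for _, g in model.parameters()])
        loss_ref, grads_ref = results["pcae"]
        for name in ("dcae0", "scae0"):
            loss, grads = results[name]
            assert loss == loss_ref
            for g, gr in zip(grads, grads_ref):
                assert np.array_equal(g, gr)


class TestSquash:
    def test_mean_activation_lands_in_open_unit_interval(self):
        latent = np.abs(np.random.default_rng(0).normal(size=(4, 8, 8, 6)))
        zbar = squash_mean_activation(latent)
        assert zbar.shape == (6,)
        assert ((zbar > 0) & (zbar < 1)).all()


class TestGradients:
    """Analytic gradients match central finite differences (float64)."""

    @pytest.mark.parametrize("variant,kwargs", [
        ("pcae", {}),
        ("dcae", {"sigma": 0.3}),
        ("scae", {"z": 0.3, "gamma": 0.5}),
        ("bvcae", {"beta": 2.0, "latent_dim": 5}),
    ])
    def test_backprop_matches_finite_differences(self, float64_layers,
                                                 variant, kwargs):
        spec = ModelSpec(variant, 2, **kwargs)
        rng = np.random.default_rng(1)
        model = (VariationalConvAutoencoder(spec, rng, image_side=8)
                 if variant == "bvcae" else ConvAutoencoder(spec, rng))
        x = np.random.default_rng(0).random((3, 8, 8, 1))

        def step():
            return _batch_step(model, x, np.random.default_rng(7),
                               np.random.default_rng(9))

        step()
        analytic = [g.copy() for _, g in model.parameters()]
        for k, (p, _) in enumerate(model.parameters()):
            flat = p.reshape(-1)
            idxs = np.random.default_rng(k).choice(
                flat.size, size=min(4, flat.size), replace=False)
            for i in idxs:
                orig = flat[i]
                eps = 1e-6
                flat[i] = orig + eps
                f1 = step()["loss"]
                flat[i] = orig - eps
                f2 = step()["loss"]
                flat[i] = orig
                num = (f1 - f2) / (2 * eps)
                ana = analytic[k].reshape(-1)[i]
                assert abs(num - ana) <= 1e-4 * max(abs(num), abs(ana), 1e-6)
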