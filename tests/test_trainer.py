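"""Training mechanics: sampling, batching, loss assembly, optimization."""

import numpy as np
import pytest

import vesselflow as vf
from vesselflow._tape import Var, as_var
from vesselflow.network import NetConfig
from vesselflow.trainer import (
    Adam,
    TrainConfig,
    _batched_backward,
    _batched_forward,
    infer_latent,
    init_model_and_codes,
    kfold_splits,
    make_batches,
    point_sample,
    regularizer_value,
    total_loss_value,
    train,
)

from conftest import random_cloud


class TestInitialization:
    def test_fixed_seed_reproducible_bitwise(self):
        rng = np.random.default_rng(0)
        shapes = [random_cloud(rng, 20) for _ in range(3)]
        cfg = NetConfig(n_z=32, fa_width=8, df_width=8)
        m1, b1 = init_model_and_codes(cfg, shapes, seed=5)
        m2, b2 = init_model_and_codes(cfg, shapes, seed=5)
        assert np.array_equal(m1.parameter_vector(), m2.parameter_vector())
        assert np.array_equal(b1.matrix, b2.matrix)

    def test_code_variance_matches_two_over_nz(self):
        rng = np.random.default_rng(1)
        shapes = [random_cloud(rng, 5) for _ in range(40)]
        cfg = NetConfig(n_z=256)
        _, bank = init_model_and_codes(cfg, shapes, seed=2)
        var = bank.matrix.var()  # 40 * 256 = 10240 draws
        assert abs(var - 2 / 256) / (2 / 256) < 0.05

    def test_zero_velocity_start_maps_identically(self):
        rng = np.random.default_rng(3)
        shapes = [random_cloud(rng, 10)]
        cfg = NetConfig(n_z=32, fa_width=8, df_width=8)
        model, bank = init_model_and_codes(cfg, shapes, seed=0)
        traj = vf.forward_map(shapes[0].points, model, bank.matrix[:, 0], K=10)
        assert np.allclose(traj.endpoint, shapes[0].points, atol=0)


class TestPointSample:
    def test_printed_constants_split(self):
        rng = np.random.default_rng(4)
        loss = rng.uniform(size=4000)
        idx = point_sample(4000, loss, 2000, 0.15, rng)
        assert len(idx) == 2000 and len(np.unique(idx)) == 2000
        top300 = np.argsort(-loss, kind="stable")[:300]
        assert np.intersect1d(idx, top300).size == 300  # 300 retained + 1700 uniform

    def test_zero_fraction_is_uniform(self):
        rng = np.random.default_rng(5)
        idx = point_sample(100, np.arange(100.0), 50, 0.0, rng)
        assert len(np.unique(idx)) == 50

    def test_all_zero_losses_fall_back_to_uniform(self):
        rng = np.random.default_rng(6)
        idx = point_sample(100, np.zeros(100), 60, 0.15, rng)
        assert len(np.unique(idx)) == 60

    def test_concentrated_loss_indices_retained(self):
        rng = np.random.default_rng(7)
        loss = np.zeros(1000)
        hot = rng.choice(1000, 150, replace=False)
        loss[hot] = 1.0 + rng.uniform(size=150)
        idx = point_sample(1000, loss, 1000 // 2, 0.3, rng)  # floor(0.3*500)=150
        assert np.all(np.isin(hot, idx))

    def test_oversized_request_returns_full_cloud(self):
        rng = np.random.default_rng(8)
        with pytest.warns(UserWarning, match="more points"):
            idx = point_sample(10, None, 50, 0.15, rng)
        assert np.array_equal(np.sort(idx), np.arange(10))


class TestMakeBatches:
    def test_paper_cohort_partition(self):
        batches = make_batches(780, 8, np.random.default_rng(9))
        sizes = sorted(len(b) for b in batches)
        assert len(batches) == 97
        assert sizes.count(9) == 4 and sizes.count(8) == 93
        all_idx = np.concatenate(batches)
        assert np.array_equal(np.sort(all_idx), np.arange(780))

    def test_exact_fit_single_batch(self):
        batches = make_batches(8, 8, np.random.default_rng(10))
        assert len(batches) == 1 and len(batches[0]) == 8

    def test_cohort_smaller_than_batch(self):
        batches = make_batches(5, 8, np.random.default_rng(11))
        assert len(batches) == 1 and len(batches[0]) == 5

    @pytest.mark.parametrize("n,b", [(13, 4), (9, 3), (100, 7), (2, 8)])
    def test_every_shape_exactly_once(self, n, b):
        batches = make_batches(n, b, np.random.default_rng(n * b))
        assert np.array_equal(np.sort(np.concatenate(batches)), np.arange(n))


class TestLossAssembly:
    def test_regularizer_zero_field(self):
        from vesselflow.integrator import forward_map
        cfg = NetConfig(n_z=32, fa_width=8, df_width=8)
        model, bank = init_model_and_codes(cfg, [random_cloud(np.random.default_rng(0), 8)], 0)
        traj = forward_map(np.random.default_rng(1).uniform(size=(5, 3)), model,
                           bank.matrix[:, 0], K=4)
        assert regularizer_value([traj]) == 0.0

    def test_regularizer_matches_independent_reintegration(self):
        """The logged velocities reproduce the kinetic energy when the
        states are re-fed through the field independently."""
        from vesselflow.integrator import forward_map
        cfg = NetConfig(n_z=16, g_z=2, fa_layers=2, fa_width=8, df_layers=2, df_width=8,
                        n_e=1)
        model, bank = init_model_and_codes(
            cfg, [random_cloud(np.random.default_rng(2), 8)], 1
        )
        model.params["head_W"].data = np.random.default_rng(3).normal(
            0, 0.1, model.params["head_W"].data.shape
        )
        code = bank.matrix[:, 0]
        traj = forward_map(np.random.default_rng(4).uniform(size=(6, 3)), model, code, K=5)
        recomputed = sum(
            float((model.velocity_at(traj.states[k], code) ** 2).sum()) for k in range(5)
        )
        assert regularizer_value([traj]) == pytest.approx(recomputed, abs=1e-9)

    def test_total_loss_hand_oracle(self):
        cfg = TrainConfig(w_z=0.5, w_theta=0.25, w_v=0.1)
        errs = np.array([0.2, 0.4])
        val = total_loss_value(errs, code_sqnorm=2.0, theta_sqnorm=4.0, l_reg=3.0, config=cfg)
        assert val == pytest.approx(0.3 + 0.5 * 2 + 0.25 * 4 + 0.1 * 3)

    def test_all_weights_zero_identity_map_self_registration(self):
        cfg = TrainConfig(w_z=0.0, w_theta=0.0, w_v=0.0)
        assert total_loss_value(np.zeros(3), 5.0, 5.0, 5.0, cfg) == 0.0

    def test_unit_code_penalty(self):
        cfg = TrainConfig(w_z=1.0, w_theta=0.0, w_v=0.0)
        assert total_loss_value(np.zeros(1), 1.0, 0.0, 0.0, cfg) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def tiny_setup():
    rng = np.random.default_rng(12)
    spec_net = NetConfig(n_z=16, g_z=2, fa_layers=2, fa_width=8, df_layers=2,
                         df_width=16, n_e=1)
    shapes = [random_cloud(rng, 60, label=f"s{i}") for i in range(3)]
    template = random_cloud(rng, 60, label="t")
    return spec_net, shapes, template


class TestTrainingLoop:

    def test_loss_components_recombine(self, tiny_setup):
        net, shapes, template = tiny_setup
        cfg = TrainConfig(epochs=2, batch_size=2, sample_points=30, seed=1, w_theta=1e-5)
        _, _, hist = train(shapes, template, net, cfg)
        for i in range(len(hist["total"])):
            recombined = (
                hist["data"][i] + hist["code_term"][i]
                + hist["theta_term"][i] + hist["reg_term"][i]
            )
            assert abs(hist["total"][i] - recombined) <= 1e-9

    def test_batch_updates_touch_only_batch_codes(self, tiny_setup):
        """Gradient isolation: backprop through one batch leaves the other
        shapes' codes without gradients."""
        net, shapes, template = tiny_setup
        model, bank = init_model_and_codes(net, shapes, seed=3)
        model.params["head_W"].data = np.random.default_rng(4).normal(
            0, 0.05, model.params["head_W"].data.shape
        )
        x0 = as_var(shapes[0].points)
        states, vels = _batched_forward(model, [bank.codes[0]], x0, [0, len(shapes[0])], 5)
        from vesselflow.attachment import measure_loss
        loss, _ = measure_loss("cd", states[-1], template)
        loss.backward()
        assert bank.codes[0].grad is not None
        assert bank.codes[1].grad is None and bank.codes[2].grad is None

    def test_sampled_subclouds_have_unique_indices(self, tiny_setup):
        rng = np.random.default_rng(13)
        for loss in (None, rng.uniform(size=60)):
            idx = point_sample(60, loss, 30, 0.15, rng)
            assert len(np.unique(idx)) == len(idx)

    def test_reproducible_history_given_seed(self, tiny_setup):
        net, shapes, template = tiny_setup
        cfg = TrainConfig(epochs=2, batch_size=2, sample_points=30, seed=5)
        _, _, h1 = train(shapes, template, net, cfg)
        _, _, h2 = train(shapes, template, net, cfg)
        assert h1["total"] == h2["total"]

    def test_sinkhorn_measure_runs_with_uniform_sampling(self, tiny_setup):
        net, shapes, template = tiny_setup
        cfg = TrainConfig(epochs=1, batch_size=3, sample_points=20, measure="sd", seed=6)
        _, _, hist = train(shapes[:2], template, net, cfg)
        assert len(hist["total"]) >= 1
        assert np.all(np.isfinite(hist["total"]))

    def test_self_registration_stays_near_identity(self):
        """One source equal to the template: the zero-initialized flow is
        already optimal, so the data loss must stay at the noise floor."""
        rng = np.random.default_rng(14)
        template = random_cloud(rng, 80, label="t")
        net = NetConfig(n_z=16, g_z=2, fa_layers=2, fa_width=8, df_layers=2,
                        df_width=16, n_e=1)
        cfg = TrainConfig(epochs=25, batch_size=1, sample_points=80, seed=7, lr=1e-3)
        _, _, hist = train([template], template, net, cfg)
        assert hist["data"][-1] <= max(hist["data"][0], 1e-8)
        assert hist["data"][-1] < 1e-4


class TestAdamAndInference:
    def test_adam_converges_on_quadratic(self):
        p = Var(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam(lr=0.2)
        for _ in range(300):
            p.grad = None
            ((p * p).sum()).backward()
            opt.step({"p": p})
        assert np.max(np.abs(p.data)) < 1e-3

    def test_reinference_of_training_shape_matches_trained_error(
        self, trained_toy, toy_cohort
    ):
        """Code-only optimization from scratch (frozen network) must recover
        a training shape's registration quality to within 2x."""
        from vesselflow.integrator import forward_map, inverse_map_explicit
        import vesselflow as vf

        model = trained_toy["model"]
        template = toy_cohort["template"]
        shape = toy_cohort["sources"][0]
        z_trained = trained_toy["bank"].matrix[:, 0]
        fwd = shape.with_points(forward_map(shape.points, model, z_trained, 10).endpoint)
        inv = template.with_points(
            inverse_map_explicit(template.points, model, z_trained, 10).endpoint
        )
        trained_err = vf.chamfer(fwd, template).total + vf.chamfer(inv, shape).total
        cfg = TrainConfig(sample_points=300, lr=1e-3, infer_adam_epochs=100,
                          infer_lbfgs_epochs=10, K=10, seed=11)
        res = infer_latent(shape, template, model, cfg)
        assert res.error <= 2 * trained_err

    def test_infer_latent_freezes_parameters(self, trained_toy, toy_cohort):
        model = trained_toy["model"]
        before = model.parameter_vector().copy()
        cfg = TrainConfig(epochs=1, sample_points=150, infer_adam_epochs=5,
                          infer_lbfgs_epochs=2, seed=9, lr=trained_toy["config"].lr)
        res = infer_latent(toy_cohort["heldout"], toy_cohort["template"], model, cfg)
        assert np.array_equal(model.parameter_vector(), before)
        assert res.code.shape == (model.config.n_z,)
        assert all(p.requires_grad for p in model.params.values())


class TestKfold:
    def test_splits_partition_cohort(self):
        splits = kfold_splits(20, 4, seed=1)
        assert len(splits) == 4
        for tr, te in splits:
            assert len(np.intersect1d(tr, te)) == 0
            assert np.array_equal(np.sort(np.concatenate([tr, te])), np.arange(20))
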