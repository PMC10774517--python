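"""DDPM forward/reverse processes, loss, training, sampling, reconstruction."""

import numpy as np
import pytest

from gdrn.connectome import ConnectivityMatrix
from gdrn.diffusion import (
    DiffusionSchedule,
    NoisePredictor,
    TrainConfig,
    load_checkpoint,
    make_schedule,
    p_mean_variance,
    q_sample,
    reconstruct,
    sample,
    save_checkpoint,
    simple_loss,
    to_model_space,
    train,
    variational_bound,
)


class StubPredictor:
    """Fixed-function predictor for closed-form reverse-step checks."""

    def __init__(self, fn, dim):
        self.fn = fn
        self.dim = dim

    def predict(self, x, t):
        return self.fn(np.asarray(x, float), t)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------


def test_make_schedule_single_step():
    s = make_schedule(1, 0.1, 0.1)
    np.testing.assert_allclose(s.alpha_bar, [0.9])


def test_make_schedule_constant_beta_cumprod():
    s = make_schedule(4, 0.5, 0.5)
    np.testing.assert_allclose(s.alpha_bar, [0.5, 0.25, 0.125, 0.0625])


@pytest.mark.parametrize("kind", ["linear", "cosine"])
def test_schedule_alpha_bar_strictly_decreasing(kind):
    s = make_schedule(100, 1e-4, 0.05, kind)
    assert np.all(np.diff(s.alpha_bar) < 0)
    np.testing.assert_allclose(s.alpha, 1.0 - s.beta)
    np.testing.assert_allclose(s.alpha_bar, np.cumprod(s.alpha), atol=1e-12)


@pytest.mark.parametrize(
    "args", [(10, 0.0, 0.02), (10, 0.05, 0.01), (10, 0.1, 1.0), (0, 0.1, 0.2)]
)
def test_make_schedule_invalid(args):
    with pytest.raises(ValueError):
        make_schedule(*args)


# ---------------------------------------------------------------------------
# forward process
# ---------------------------------------------------------------------------


def test_q_sample_noiseless_limit():
    s = make_schedule(10, 0.01, 0.1)
    x0 = np.linspace(-1, 1, 5)
    out = q_sample(x0, 4, np.zeros(5), s)
    np.testing.assert_allclose(out, np.sqrt(s.alpha_bar[3]) * x0)


def test_q_sample_zero_signal():
    s = make_schedule(10, 0.01, 0.1)
    eps = np.arange(5.0)
    out = q_sample(np.zeros(5), 7, eps, s)
    np.testing.assert_allclose(out, np.sqrt(1 - s.alpha_bar[6]) * eps)


def test_q_sample_shape_mismatch():
    s = make_schedule(5, 0.01, 0.1)
    with pytest.raises(ValueError, match="shape"):
        q_sample(np.zeros(4), 1, np.zeros(5), s)
    with pytest.raises(ValueError, match="t must lie"):
        q_sample(np.zeros(4), 6, np.zeros(4), s)


def test_q_sample_marginal_monte_carlo():
    """Empirical mean/variance of x_t match the closed-form marginal."""
    s = make_schedule(50, 1e-3, 0.08)
    rng = np.random.default_rng(42)
    x0 = rng.normal(0, 0.5, size=8)
    n = 20_000
    for t in (1, 25, 50):
        eps = rng.standard_normal((n, 8))
        xt = q_sample(np.tile(x0, (n, 1)), t, eps, s)
        ab = s.alpha_bar[t - 1]
        resid = xt - np.sqrt(ab) * x0
        z_mean = resid.mean() / np.sqrt((1 - ab) / (n * 8))
        pooled_var = resid.var(ddof=1)
        z_var = (pooled_var - (1 - ab)) / ((1 - ab) * np.sqrt(2 / (n * 8 - 1)))
        assert abs(z_mean) < 3.0
        assert abs(z_var) < 3.0


def test_forward_composition_property():
    """Chaining single-step kernels q(x_t | x_{t-1}) reproduces the direct
    marginal q(x_t | x_0) distributionally."""
    s = make_schedule(5, 0.05, 0.3)
    rng = np.random.default_rng(1)
    x0 = np.array([0.8, -0.4])
    n = 30_000
    x = np.tile(x0, (n, 1))
    for t in range(1, 6):
        x = np.sqrt(s.alpha[t - 1]) * x + np.sqrt(s.beta[t - 1]) * rng.standard_normal((n, 2))
    ab = s.alpha_bar[-1]
    z_mean = (x - np.sqrt(ab) * x0).mean() / np.sqrt((1 - ab) / (n * 2))
    z_var = ((x - np.sqrt(ab) * x0).var(ddof=1) - (1 - ab)) / (
        (1 - ab) * np.sqrt(2 / (n * 2 - 1))
    )
    assert abs(z_mean) < 3.0 and abs(z_var) < 3.0


# ---------------------------------------------------------------------------
# reverse step
# ---------------------------------------------------------------------------


def test_p_mean_recovers_x0_at_t1():
    """With the true eps plugged in at t=1 (abar_1 = alpha_1), the reverse
    mean is exactly x0."""
    s = make_schedule(5, 0.05, 0.2)
    rng = np.random.default_rng(2)
    x0 = rng.normal(size=6)
    eps = rng.standard_normal(6)
    x1 = q_sample(x0, 1, eps, s)
    model = StubPredictor(lambda x, t: eps, 6)
    mean, _ = p_mean_variance(model, x1, 1, s)
    np.testing.assert_allclose(mean, x0, atol=1e-10)


def test_p_mean_zero_predictor_and_variance():
    s = make_schedule(5, 0.05, 0.2)
    x = np.array([1.0, -2.0])
    model = StubPredictor(lambda x_, t: np.zeros_like(x_), 2)
    for t in (1, 3, 5):
        mean, var = p_mean_variance(model, x, t, s)
        np.testing.assert_allclose(mean, x / np.sqrt(s.alpha[t - 1]))
        assert var == s.beta[t - 1]


def test_p_mean_variance_t0_rejected():
    s = make_schedule(5, 0.05, 0.2)
    model = StubPredictor(lambda x, t: x, 2)
    with pytest.raises(ValueError, match="t must lie"):
        p_mean_variance(model, np.zeros(2), 0, s)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def test_simple_loss_values():
    assert simple_loss(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
    assert simple_loss(np.array([1.0, 0.0]), np.array([0.0, 0.0])) == 0.5
    with pytest.raises(ValueError, match="shape"):
        simple_loss(np.zeros(3), np.zeros(4))


def test_simple_loss_nonnegative():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a, b = rng.normal(size=(2, 16))
        assert simple_loss(a, b) >= 0.0


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def test_train_rejects_bad_datasets(tiny_fc):
    fc_by_group, _ = tiny_fc
    cfg = TrainConfig(T=10, epochs=1)
    with pytest.raises(ValueError, match="empty"):
        train([], cfg)
    mixed = [fc_by_group["saline"][0], fc_by_group["high"][0]]
    with pytest.raises(ValueError, match="mixed groups"):
        train(mixed, cfg)


def test_train_reduces_loss_and_is_deterministic(tiny_fc):
    fc_by_group, _ = tiny_fc
    cfg = TrainConfig(T=50, epochs=60, batch_size=8, seed=4)
    m1 = train(fc_by_group["saline"], cfg)
    assert m1.trained and m1.group == "saline"
    assert m1.loss_history[-1] < m1.loss_history[0]
    m2 = train(fc_by_group["saline"], cfg)
    assert abs(m1.loss_history[-1] - m2.loss_history[-1]) < 1e-6


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def test_sample_empty_and_untrained(tiny_fc):
    fc_by_group, _ = tiny_fc
    cfg = TrainConfig(T=20, epochs=2, seed=0)
    model = train(fc_by_group["saline"], cfg)
    sched = cfg.make_schedule()
    assert sample(model, sched, 0, seed=1) == []
    fresh = NoisePredictor(model.dim, "saline", cfg, model.region_indices)
    with pytest.raises(ValueError, match="trained"):
        sample(fresh, sched, 1, seed=1)


def test_sample_deterministic_and_valid(tiny_fc):
    fc_by_group, _ = tiny_fc
    cfg = TrainConfig(T=30, epochs=20, seed=0)
    model = train(fc_by_group["saline"], cfg)
    sched = cfg.make_schedule()
    a = sample(model, sched, 3, seed=5)
    b = sample(model, sched, 3, seed=5)
    for fa, fb in zip(a, b):
        np.testing.assert_array_equal(fa.values, fb.values)
        assert np.array_equal(fa.values, fa.values.T)
        assert np.all(np.diag(fa.values) == 1.0)
        assert fa.values.min() >= -1.0 and fa.values.max() <= 1.0


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------


def test_reconstruct_identity_at_t0(models, sched, test_fc):
    fc = test_fc["saline"][0]
    out = reconstruct(models["saline"], fc, 0, sched, seed=1)
    np.testing.assert_array_equal(out.values, fc.values)


def test_reconstruct_dimension_mismatch(models, sched, tiny_fc):
    fc_by_group, _ = tiny_fc
    with pytest.raises(ValueError, match="dimension"):
        reconstruct(models["saline"], fc_by_group["saline"][0], 10, sched, seed=0)


def test_reconstruction_error_monotone_in_noise_level(models, sched, test_fc):
    """More forward noising loses more subject identity: mean reconstruction
    error is non-decreasing in t_noise (averaged over 20 seeds)."""
    fc = test_fc["saline"][0]
    x0 = to_model_space(fc, "fisher_z")
    means = []
    for t_noise in (10, 50, 200):
        errs = []
        for s in range(20):
            rec = reconstruct(models["saline"], fc, t_noise, sched, seed=s)
            errs.append(np.sum((to_model_space(rec, "fisher_z") - x0) ** 2))
        means.append(np.mean(errs))
    assert means[0] <= means[1] <= means[2]


# ---------------------------------------------------------------------------
# variational bound
# ---------------------------------------------------------------------------


def test_vlb_finite(tiny_fc):
    fc_by_group, _ = tiny_fc
    cfg = TrainConfig(T=20, epochs=5, seed=0)
    m = train(fc_by_group["saline"], cfg)
    v = variational_bound(m, fc_by_group["saline"][0], cfg.make_schedule(), seed=0, n_mc=3)
    assert np.isfinite(v)


def test_vlb_matches_analytic_one_step():
    """1-D, T=1, zero predictor: the bound has a closed form
    KL(q(x_1|x_0) || N(0,1)) + E[-log N(x_0; x_1/sqrt(a), 1-a)]."""
    a = 0.8
    sched = make_schedule(1, 1 - a, 1 - a)
    x0 = np.array([0.7])
    model = StubPredictor(lambda x, t: np.zeros_like(x), 1)
    model.config = TrainConfig(T=2)  # transform unused for raw vectors

    lt = 0.5 * (a * x0[0] ** 2 + (1 - a) - 1 - np.log(1 - a))
    rec = 0.5 * (np.log(2 * np.pi * (1 - a)) + 1 / a)
    analytic = lt + rec

    est = variational_bound(model, x0, sched, seed=3, n_mc=400)
    assert abs(est - analytic) < 0.25


def test_vlb_decreases_with_training(tiny_fc):
    fc_by_group, _ = tiny_fc
    cfg = TrainConfig(T=30, epochs=60, seed=2)
    untrained = NoisePredictor(15, "saline", cfg, list(range(6)))
    trained = train(fc_by_group["saline"], cfg)
    sched = cfg.make_schedule()
    x0 = fc_by_group["saline"][0]
    v0 = variational_bound(untrained, x0, sched, seed=5, n_mc=5)
    v1 = variational_bound(trained, x0, sched, seed=5, n_mc=5)
    assert v1 < v0


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def test_checkpoint_roundtrip(tmp_path, tiny_fc):
    fc_by_group, _ = tiny_fc
    cfg = TrainConfig(T=25, epochs=10, seed=1)
    model = train(fc_by_group["high"], cfg)
    sched = cfg.make_schedule()
    path = tmp_path / "model.npz"
    save_checkpoint(model, sched, path)
    model2, sched2 = load_checkpoint(path)
    assert model2.group == "high" and model2.trained
    np.testing.assert_array_equal(sched2.beta, sched.beta)
    x = np.random.default_rng(0).normal(size=model.dim)
    np.testing.assert_array_equal(model.predict(x, 5), model2.predict(x, 5))
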