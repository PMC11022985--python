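"""Loss closed forms, adversarial perturbation, training-loop contracts."""

import numpy as np
import pytest
from scipy import stats

from soluens.network import MemberConfig, forward_batch, init_member_params
from soluens.training import (
    Adam,
    TrainingConfig,
    adversarial_embed,
    clean_update,
    heldout_nll,
    new_member_state,
    nll_loss,
    nll_loss_tensor,
    train_ensemble,
    train_member,
    train_step,
)

TINY = MemberConfig(vocab_size=6, embed_dim=4, rnn_kind="gru", rnn_units=3, dense_units=(5, 3), dropout_rate=0.0)


class TestNllLoss:
    def test_standard_normal_at_zero(self):
        assert np.isclose(nll_loss(0.0, 1.0, 0.0), 0.5 * np.log(2 * np.pi), atol=1e-12)

    def test_exact_zero_case(self):
        assert nll_loss(1.7, 1.0 / (2 * np.pi), 1.7) == 0.0

    def test_monotone_in_absolute_error(self):
        losses = [nll_loss(mu, 0.5, 0.0) for mu in (0.1, 0.5, 1.0, 3.0)]
        assert losses == sorted(losses)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            nll_loss(0.0, 0.0, 0.0)

    def test_matches_negative_gaussian_logpdf(self):
        rng = np.random.default_rng(1)
        mu = rng.normal(size=200)
        s2 = rng.uniform(0.01, 5.0, size=200)
        y = rng.normal(size=200)
        expected = -stats.norm.logpdf(y, loc=mu, scale=np.sqrt(s2))
        got = np.array([nll_loss(m, v, t) for m, v, t in zip(mu, s2, y)])
        assert np.allclose(got, expected, atol=1e-10)

    def test_tensor_version_agrees_with_scalar(self):
        from soluens.autodiff import Tensor

        mu = np.array([[0.3], [-1.0]])
        s2 = np.array([[0.5], [1.5]])
        y = np.array([0.0, -1.2])
        t = nll_loss_tensor(Tensor(mu), Tensor(s2), y)
        assert np.isclose(t.data, nll_loss(mu[:, 0], s2[:, 0], y), atol=1e-12)


class TestAdversarialEmbed:
    def test_epsilon_zero_is_identity(self):
        x = np.random.default_rng(0).normal(size=(3, 4))
        g = np.random.default_rng(1).normal(size=(3, 4))
        out = adversarial_embed(x, g, 0.0)
        assert out is x or np.array_equal(out, x)

    def test_perturbation_is_sign_times_epsilon(self):
        x = np.zeros((2, 3))
        g = np.array([[1.0, -2.0, 0.0], [0.5, -0.1, 3.0]])
        out = adversarial_embed(x, g, 0.25)
        assert np.array_equal(out - x, 0.25 * np.sign(g))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            adversarial_embed(np.zeros((2, 3)), np.zeros((3, 2)), 0.1)

    def test_increases_smooth_quadratic_loss(self):
        """First-order check: moving along sign(grad) increases the loss."""
        A = np.diag([1.0, 2.0, 0.5])
        x = np.array([[0.3, -0.7, 1.1]])
        loss = lambda v: float((v @ A @ v.T).item())
        g = 2 * x @ A
        x_adv = adversarial_embed(x, g, 1e-3)
        assert loss(x_adv) > loss(x)


def _toy_batch(rng, n=8, t=5):
    ids = rng.integers(1, TINY.vocab_size, size=(n, t))
    y = rng.normal(size=n)
    return ids.astype(int), y


class TestTrainStep:
    def test_adversarial_off_ignores_epsilon(self):
        rng = np.random.default_rng(0)
        ids, y = _toy_batch(rng)
        cfg_a = TrainingConfig(learning_rate=0.01, adversarial=False, epsilon_adv=0.5, ensemble_size=1)
        cfg_b = TrainingConfig(learning_rate=0.01, adversarial=False, epsilon_adv=0.0, ensemble_size=1)
        sa = new_member_state(TINY, cfg_a, seed=3)
        sb = new_member_state(TINY, cfg_b, seed=3)
        for _ in range(5):
            train_step(sa, (ids, y), cfg_a)
            train_step(sb, (ids, y), cfg_b)
        for (ka, ta), (kb, tb) in zip(sa.params.items(), sb.params.items()):
            assert ka == kb and np.array_equal(ta.data, tb.data)

    def test_epsilon_zero_equals_two_clean_updates(self):
        """The eps=0 adversarial trajectory is bit-identical to doubling the
        clean update (second update on the captured clean embeddings)."""
        from soluens.training import perturbed_update

        rng = np.random.default_rng(0)
        ids, y = _toy_batch(rng)
        cfg = TrainingConfig(learning_rate=0.01, adversarial=True, epsilon_adv=0.0, ensemble_size=1)
        adv = new_member_state(TINY, cfg, seed=9)
        ora = new_member_state(TINY, cfg, seed=9)
        for _ in range(4):
            train_step(adv, (ids, y), cfg)
            # oracle: clean update, then a second clean update re-using the
            # embedded representation from the first pass, unperturbed
            _, embedded = clean_update(ora, ids, y)
            perturbed_update(ora, ids, [e.data for e in embedded], y)
        for (ka, ta), (kb, tb) in zip(adv.params.items(), ora.params.items()):
            assert ka == kb and np.array_equal(ta.data, tb.data), ka

    def test_overfits_single_sample(self):
        rng = np.random.default_rng(5)
        ids = rng.integers(1, TINY.vocab_size, size=(1, 5)).astype(int)
        y = np.array([0.7])
        cfg = TrainingConfig(learning_rate=0.01, adversarial=False, ensemble_size=1)
        state = new_member_state(TINY, cfg, seed=0)
        first = train_step(state, (ids, y), cfg)["clean"]
        last = first
        for _ in range(199):
            last = train_step(state, (ids, y), cfg)["clean"]
        assert last < first

    def test_empty_batch_rejected(self):
        cfg = TrainingConfig(ensemble_size=1)
        state = new_member_state(TINY, cfg, seed=0)
        with pytest.raises(ValueError):
            train_step(state, (np.zeros((0, 3), dtype=int), np.zeros(0)), cfg)


class TestTrainMember:
    def test_same_seed_reproduces_exactly(self):
        rng = np.random.default_rng(2)
        ids, y = _toy_batch(rng, n=20)
        cfg = TrainingConfig(learning_rate=0.01, adversarial=True, epochs=3, batch_size=8, ensemble_size=1)
        p1, t1 = train_member((ids, y), (ids, y), TINY, cfg, seed=7)
        p2, t2 = train_member((ids, y), (ids, y), TINY, cfg, seed=7)
        assert t1.train_loss == t2.train_loss
        assert t1.val_loss == t2.val_loss
        for (k1, a), (k2, b) in zip(p1.items(), p2.items()):
            assert np.array_equal(a.data, b.data)

    def test_trace_lengths_match_epochs(self):
        rng = np.random.default_rng(2)
        ids, y = _toy_batch(rng, n=16)
        cfg = TrainingConfig(learning_rate=0.01, adversarial=False, epochs=4, batch_size=8, ensemble_size=1)
        _, trace = train_member((ids, y), (ids, y), TINY, cfg, seed=1)
        assert len(trace.train_loss) == len(trace.val_loss) == len(trace.epoch_seconds) == 4
        assert all(np.isfinite(trace.train_loss))

    def test_empty_training_data_rejected(self):
        cfg = TrainingConfig(ensemble_size=1)
        with pytest.raises(ValueError):
            train_member((np.zeros((0, 3), dtype=int), np.zeros(0)), None, TINY, cfg, seed=0)


class TestTrainEnsemble:
    def test_duplicate_seeds_warn(self):
        rng = np.random.default_rng(2)
        ids, y = _toy_batch(rng, n=12)
        cfg = TrainingConfig(
            learning_rate=0.01, adversarial=False, epochs=1, batch_size=6,
            ensemble_size=2, member_seeds=(3, 3),
        )
        with pytest.warns(UserWarning, match="duplicate"):
            train_ensemble((ids, y), None, TINY, cfg)

    def test_members_independent_of_training_order(self):
        rng = np.random.default_rng(2)
        ids, y = _toy_batch(rng, n=12)
        mk = lambda seeds: TrainingConfig(
            learning_rate=0.01, adversarial=False, epochs=2, batch_size=6,
            ensemble_size=2, member_seeds=seeds,
        )
        m_ab, _ = train_ensemble((ids, y), None, TINY, mk((1, 2)))
        m_ba, _ = train_ensemble((ids, y), None, TINY, mk((2, 1)))
        for (ka, a), (kb, b) in zip(m_ab[0].items(), m_ba[1].items()):
            assert np.array_equal(a.data, b.data)


def test_heldout_nll_matches_direct_computation():
    rng = np.random.default_rng(3)
    params = init_member_params(TINY, 0)
    ids = rng.integers(1, TINY.vocab_size, size=(9, 4)).astype(int)
    y = rng.normal(size=9)
    mu, s2, _ = forward_batch(params, ids)
    direct = nll_loss(mu.data[:, 0], s2.data[:, 0], y)
    assert np.isclose(heldout_nll(params, ids, y, chunk=4), direct, atol=1e-12)


def test_adam_matches_reference_formula():
    """One Adam step against a hand-computed update."""
    from soluens.autodiff import parameter
    from soluens.network import MemberParams

    p = parameter(np.array([[1.0, -2.0]]))
    p.grad = np.array([[0.5, -1.0]])
    params = MemberParams(TINY, {"w": p})
    opt = Adam(learning_rate=0.1, beta1=0.9, beta2=0.999)
    opt.update(params)
    g = np.array([[0.5, -1.0]])
    mhat = (0.1 * g) / (1 - 0.9)
    vhat = (0.001 * g * g) / (1 - 0.999)
    expected = np.array([[1.0, -2.0]]) - 0.1 * mhat / (np.sqrt(vhat) + 1e-8)
    assert np.allclose(p.data, expected, atol=1e-12)
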