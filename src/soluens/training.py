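"""Gaussian NLL loss, adversarial perturbation, and the training loops.

Each member minimizes the heteroscedastic Gaussian negative log-likelihood

    l(mu, sigma^2; y) = 1/2 log(2 pi sigma^2) + (y - mu)^2 / (2 sigma^2)

with Adam.  With adversarial training enabled, every iteration performs two
optimizer updates sharing one optimizer state: one on the clean batch, and one
on a batch whose embedded representation is perturbed by the fast-gradient-sign
step x' = x + eps * sign(grad_x l).  The inputs are discrete tokens, so the
perturbation acts on the embedding output; the perturbed input is treated as a
constant (the embedding matrix receives no gradient from the second update).
The perturbation gradient comes from the clean pass (that iteration's dropout
mask); the perturbed pass re-samples dropout.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .network import (
    MemberConfig,
    MemberParams,
    NumericalError,
    forward_batch,
    init_member_params,
)

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class TrainingConfig:
    """All training hyperparameters of the ensemble."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon_adv: float = 0.01
    adversarial: bool = True
    epochs: int = 50
    batch_size: int = 32
    ensemble_size: int = 4
    member_seeds: tuple[int, ...] | None = None
    max_len: int = 128

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta1 and beta2 must be in [0, 1)")
        if self.epsilon_adv < 0:
            raise ValueError("epsilon_adv must be >= 0")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.member_seeds is not None and len(self.member_seeds) != self.ensemble_size:
            raise ValueError("need exactly one seed per member")

    def resolved_member_seeds(self, base_seed: int = 0) -> tuple[int, ...]:
        if self.member_seeds is not None:
            return tuple(self.member_seeds)
        ss = np.random.SeedSequence(base_seed)
        return tuple(int(s) for s in ss.generate_state(self.ensemble_size) >> 1)


@dataclass
class TrainingTrace:
    """Per-epoch loss bookkeeping for one member."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)


def nll_loss(mu, sigma2, y) -> float:
    """Mean Gaussian negative log-likelihood (exact, constant included)."""
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be strictly positive")
    return float(np.mean(0.5 * np.log(TWO_PI * sigma2) + (y - mu) ** 2 / (2.0 * sigma2)))


def nll_loss_tensor(mu: Tensor, sigma2: Tensor, y: np.ndarray) -> Tensor:
    """Differentiable batch-mean NLL; ``y`` is a constant (B, 1) array."""
    yt = Tensor(np.asarray(y, dtype=float).reshape(-1, 1))
    return ((sigma2 * TWO_PI).log() * 0.5 + (yt - mu).square() / (sigma2 * 2.0)).mean()


def adversarial_embed(
    embedded: np.ndarray, loss_gradient: np.ndarray, epsilon_adv: float
) -> np.ndarray:
    """Fast-gradient-sign perturbation of an embedded input."""
    embedded = np.asarray(embedded)
    loss_gradient = np.asarray(loss_gradient)
    if embedded.shape != loss_gradient.shape:
        raise ValueError("embedded input and gradient shapes differ")
    if epsilon_adv == 0:
        return embedded
    return embedded + epsilon_adv * np.sign(loss_gradient)


class Adam:
    """Adam with a fixed learning rate (one state shared by all updates)."""

    def __init__(self, learning_rate: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def update(self, params: MemberParams) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p in params.items():
            g = p.grad
            if g is None:
                continue
            m = self.m.setdefault(name, np.zeros_like(p.data))
            v = self.v.setdefault(name, np.zeros_like(p.data))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class MemberState:
    """A member's parameters plus its private RNG and optimizer state."""

    params: MemberParams
    rng: np.random.Generator
    optimizer: Adam


def new_member_state(member_config: MemberConfig, training_config: TrainingConfig, seed: int) -> MemberState:
    init_ss, run_ss = np.random.SeedSequence(seed).spawn(2)
    params = init_member_params(member_config, int(init_ss.generate_state(1)[0] >> 1))
    return MemberState(
        params=params,
        rng=np.random.default_rng(run_ss),
        optimizer=Adam(training_config.learning_rate, training_config.beta1, training_config.beta2),
    )


def clean_update(state: MemberState, ids: np.ndarray, y: np.ndarray):
    """One NLL update on the clean batch; returns (loss, embedded tensors)."""
    state.params.zero_grad()
    mu, sigma2, embedded = forward_batch(state.params, ids, training=True, rng=state.rng)
    loss = nll_loss_tensor(mu, sigma2, y)
    if not np.isfinite(loss.data):
        raise NumericalError("non-finite training loss")
    loss.backward()
    state.optimizer.update(state.params)
    return float(loss.data), embedded


def perturbed_update(
    state: MemberState, ids: np.ndarray, embedded_arrays: list[np.ndarray], y: np.ndarray
) -> float:
    """One NLL update on a fixed embedded input (treated as constant).

    ``ids`` only supplies the padding mask, so the perturbed pass masks the
    same positions as the clean pass that produced the embeddings.
    """
    state.params.zero_grad()
    mu, sigma2, _ = forward_batch(
        state.params, ids, training=True, rng=state.rng, embedded_override=embedded_arrays
    )
    loss = nll_loss_tensor(mu, sigma2, y)
    if not np.isfinite(loss.data):
        raise NumericalError("non-finite adversarial training loss")
    loss.backward()
    state.optimizer.update(state.params)
    return float(loss.data)


def train_step(
    state: MemberState, batch: tuple[np.ndarray, np.ndarray], config: TrainingConfig
) -> dict[str, float]:
    """One training iteration: clean update, then (optionally) adversarial."""
    ids, y = batch
    if len(y) == 0:
        raise ValueError("empty batch")
    losses: dict[str, float] = {}
    try:
        clean_loss, embedded = clean_update(state, ids, y)
    except NumericalError as exc:
        raise NumericalError(f"{exc} (clean step, batch of {len(y)})") from exc
    losses["clean"] = clean_loss
    if config.adversarial:
        perturbed = [
            adversarial_embed(e.data, np.zeros_like(e.data) if e.grad is None else e.grad, config.epsilon_adv)
            for e in embedded
        ]
        try:
            losses["adversarial"] = perturbed_update(state, ids, perturbed, y)
        except NumericalError as exc:
            raise NumericalError(f"{exc} (adversarial step, batch of {len(y)})") from exc
    return losses


def heldout_nll(params: MemberParams, ids: np.ndarray, y: np.ndarray, chunk: int = 512) -> float:
    """Dropout-off NLL of one member on a held-out set."""
    losses = []
    for lo in range(0, len(y), chunk):
        mu, sigma2, _ = forward_batch(params, ids[lo : lo + chunk], training=False)
        losses.append(
            np.sum(0.5 * np.log(TWO_PI * sigma2.data[:, 0]) + (y[lo : lo + chunk] - mu.data[:, 0]) ** 2 / (2 * sigma2.data[:, 0]))
        )
    return float(np.sum(losses) / len(y))


def train_member(
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray] | None,
    member_config: MemberConfig,
    training_config: TrainingConfig,
    seed: int,
) -> tuple[MemberParams, TrainingTrace]:
    """Train one member to completion (final-epoch weights are kept)."""
    ids, y = train_data
    if len(y) == 0:
        raise ValueError("empty training data")
    state = new_member_state(member_config, training_config, seed)
    trace = TrainingTrace()
    n = len(y)
    bs = training_config.batch_size
    for _epoch in range(training_config.epochs):
        t0 = time.perf_counter()
        order = state.rng.permutation(n)
        batch_losses = []
        for lo in range(0, n, bs):
            sel = order[lo : lo + bs]
            losses = train_step(state, (ids[sel], y[sel]), training_config)
            batch_losses.append(losses["clean"])
        trace.train_loss.append(float(np.mean(batch_losses)))
        if val_data is not None:
            trace.val_loss.append(heldout_nll(state.params, *val_data))
        trace.epoch_seconds.append(time.perf_counter() - t0)
    return state.params, trace


def train_ensemble(
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray] | None,
    member_config: MemberConfig,
    training_config: TrainingConfig,
    base_seed: int = 0,
) -> tuple[list[MemberParams], list[TrainingTrace]]:
    """Train all members independently (they differ only by their seeds)."""
    seeds = training_config.resolved_member_seeds(base_seed)
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate member seeds degrade ensemble diversity", stacklevel=2)
    members: list[MemberParams] = []
    traces: list[TrainingTrace] = []
    for seed in seeds:
        params, trace = train_member(train_data, val_data, member_config, training_config, seed)
        members.append(params)
        traces.append(trace)
    return members, traces
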