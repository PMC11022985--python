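"""Per-member recurrent network and deep-ensemble aggregation.

Each ensemble member maps a padded token-id sequence through an embedding
layer, two bidirectional recurrent layers (GRU or LSTM), layer normalization,
a dense stack (32 -> 16 by default) and two parallel 1-unit heads: a linear
head for the predictive mean mu and a softplus head for the aleatoric standard
deviation sigma (floored at ``sigma_floor``).  Padding (id 0) is masked inside
the recurrent layers, so trailing pad positions cannot influence the output.

An ensemble of N members, each predicting a Gaussian (mu_m, sigma_m^2), is
aggregated as the uniform mixture's moments:

    mu*         = mean_m mu_m
    sigma_ale^2 = mean_m sigma_m^2          (aleatoric, data noise)
    sigma_epi^2 = mean_m (mu_m - mu*)^2     (epistemic, member disagreement)

whose sum is the mixture variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, parameter
from .vocab import PAD_ID, TokenSequence


@dataclass(frozen=True)
class MemberConfig:
    """Architecture hyperparameters of one ensemble member."""

    vocab_size: int
    embed_dim: int = 64
    rnn_kind: str = "lstm"
    rnn_units: int = 64
    rnn_layers: int = 2
    dense_units: tuple[int, ...] = (32, 16)
    dropout_rate: float = 0.35
    sigma_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.rnn_kind not in ("gru", "lstm"):
            raise ValueError("rnn_kind must be 'gru' or 'lstm'")
        if min(self.vocab_size, self.embed_dim, self.rnn_units, self.rnn_layers, *self.dense_units) < 1:
            raise ValueError("all sizes must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.sigma_floor <= 0:
            raise ValueError("sigma_floor must be > 0")


@dataclass(frozen=True)
class MemberPrediction:
    """One member's Gaussian prediction for one input."""

    mu_m: float
    sigma2_m: float

    def __post_init__(self) -> None:
        if self.sigma2_m <= 0:
            raise ValueError("sigma2_m must be strictly positive")


@dataclass(frozen=True)
class EnsemblePrediction:
    """Aggregated ensemble prediction with uncertainty decomposition."""

    mu_star: float
    sigma2_ale: float
    sigma2_epi: float
    n_members: int
    member_predictions: tuple[MemberPrediction, ...] = field(default=())

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_ale + self.sigma2_epi


def aggregate(members: list[MemberPrediction]) -> EnsemblePrediction:
    """Aggregate member Gaussians into the uniform-mixture moments."""
    if not members:
        raise ValueError("cannot aggregate an empty ensemble")
    mus = np.array([m.mu_m for m in members])
    sig2 = np.array([m.sigma2_m for m in members])
    mu_star = float(mus.mean())
    return EnsemblePrediction(
        mu_star=mu_star,
        sigma2_ale=float(sig2.mean()),
        sigma2_epi=float(((mus - mu_star) ** 2).mean()),
        n_members=len(members),
        member_predictions=tuple(members),
    )


class NumericalError(FloatingPointError):
    """Non-finite activations encountered during a forward pass."""


class MemberParams:
    """Named trainable tensors of one member, in a fixed order."""

    def __init__(self, config: MemberConfig, tensors: dict[str, Tensor]):
        self.config = config
        self.tensors = tensors

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def items(self):
        return self.tensors.items()

    def values(self):
        return self.tensors.values()

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.zero_grad()

    def copy(self) -> "MemberParams":
        return MemberParams(
            self.config, {k: parameter(v.data.copy()) for k, v in self.tensors.items()}
        )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_member_params(config: MemberConfig, seed: int) -> MemberParams:
    """Initialize one member's weights from its own seed.

    Independent per-member seeds are the ensemble's source of diversity.
    """
    rng = np.random.default_rng(seed)
    n_gates = 4 if config.rnn_kind == "lstm" else 3
    h = config.rnn_units
    t: dict[str, Tensor] = {}
    t["embedding"] = parameter(rng.uniform(-0.05, 0.05, size=(config.vocab_size, config.embed_dim)))
    in_dim = config.embed_dim
    for layer in range(config.rnn_layers):
        for direction in ("fwd", "bwd"):
            p = f"rnn{layer}_{direction}"
            t[f"{p}_W"] = parameter(_glorot(rng, in_dim, n_gates * h))
            if config.rnn_kind == "gru":
                t[f"{p}_U"] = parameter(_glorot(rng, h, 2 * h))
                t[f"{p}_Un"] = parameter(_glorot(rng, h, h))
            else:
                t[f"{p}_U"] = parameter(_glorot(rng, h, n_gates * h))
            bias = np.zeros((1, n_gates * h))
            if config.rnn_kind == "lstm":
                bias[0, h : 2 * h] = 1.0  # forget-gate bias
            t[f"{p}_b"] = parameter(bias)
        in_dim = 2 * h  # bidirectional concatenation
    t["ln_gain"] = parameter(np.ones((1, in_dim)))
    t["ln_bias"] = parameter(np.zeros((1, in_dim)))
    for i, units in enumerate(config.dense_units):
        t[f"dense{i}_W"] = parameter(_glorot(rng, in_dim, units))
        t[f"dense{i}_b"] = parameter(np.zeros((1, units)))
        in_dim = units
    t["mu_W"] = parameter(_glorot(rng, in_dim, 1))
    t["mu_b"] = parameter(np.zeros((1, 1)))
    t["sigma_W"] = parameter(_glorot(rng, in_dim, 1))
    t["sigma_b"] = parameter(np.zeros((1, 1)))
    return MemberParams(config, t)


def _gru_direction(params, prefix, xs, mask, h0, reverse):
    W, U, Un, b = params[f"{prefix}_W"], params[f"{prefix}_U"], params[f"{prefix}_Un"], params[f"{prefix}_b"]
    h = h0
    hs = [None] * len(xs)
    steps = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
    n = params.config.rnn_units
    for ti in steps:
        x = xs[ti]
        xW = x @ W + b
        hU = h @ U
        z = (xW.slice_cols(0, n) + hU.slice_cols(0, n)).sigmoid()
        r = (xW.slice_cols(n, 2 * n) + hU.slice_cols(n, 2 * n)).sigmoid()
        cand = (xW.slice_cols(2 * n, 3 * n) + (r * h) @ Un).tanh()
        h_new = cand + z * (h - cand)
        m = mask[:, ti : ti + 1]
        h = h + Tensor(m) * (h_new - h)
        hs[ti] = h
    return hs, h


def _lstm_direction(params, prefix, xs, mask, h0, c0, reverse):
    W, U, b = params[f"{prefix}_W"], params[f"{prefix}_U"], params[f"{prefix}_b"]
    h, c = h0, c0
    hs = [None] * len(xs)
    steps = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
    n = params.config.rnn_units
    for ti in steps:
        x = xs[ti]
        gates = x @ W + h @ U + b
        i = gates.slice_cols(0, n).sigmoid()
        f = gates.slice_cols(n, 2 * n).sigmoid()
        g = gates.slice_cols(2 * n, 3 * n).tanh()
        o = gates.slice_cols(3 * n, 4 * n).sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        m = Tensor(mask[:, ti : ti + 1])
        c = c + m * (c_new - c)
        h = h + m * (h_new - h)
        hs[ti] = h
    return hs, h


def forward_batch(
    params: MemberParams,
    ids: np.ndarray,
    *,
    training: bool = False,
    rng: np.random.Generator | None = None,
    embedded_override: list[np.ndarray] | None = None,
):
    """Run one member on a batch of padded id sequences.

    Returns ``(mu, sigma2, embedded)`` where ``mu`` and ``sigma2`` are
    ``(B, 1)`` tensors and ``embedded`` is the per-timestep list of embedding
    output tensors (before dropout), whose ``.grad`` after a backward pass is
    the loss gradient with respect to the embedded input.

    ``embedded_override`` replaces the embedding lookup with fixed arrays
    (used for adversarially perturbed inputs, which are treated as constants).
    With ``training`` the three dropout masks (after embedding and after each
    dense layer) are drawn from ``rng`` in a fixed order.
    """
    cfg = params.config
    ids = np.asarray(ids)
    if ids.ndim != 2:
        raise ValueError("ids must be a (batch, time) array")
    if embedded_override is None and ids.max(initial=0) >= cfg.vocab_size:
        raise ValueError("token id out of range for vocab_size")
    if training and cfg.dropout_rate > 0 and rng is None:
        raise ValueError("training with dropout requires an rng")
    B, T = ids.shape
    mask = (ids != PAD_ID).astype(np.float64)
    # All-pad rows (empty sequences) would freeze at the zero state anyway.

    keep = 1.0 - cfg.dropout_rate

    def dropout(t: Tensor, shape) -> Tensor:
        if not training or cfg.dropout_rate == 0:
            return t
        m = (rng.random(shape) < keep) / keep
        return t * Tensor(m)

    if embedded_override is not None:
        embedded = [Tensor(e) for e in embedded_override]
    else:
        emb = params["embedding"]
        embedded = [emb.take_rows(ids[:, ti]) for ti in range(T)]
    drop_mask_shape = (B, T, cfg.embed_dim)
    if training and cfg.dropout_rate > 0:
        dm = (rng.random(drop_mask_shape) < keep) / keep
        xs = [embedded[ti] * Tensor(dm[:, ti, :]) for ti in range(T)]
    else:
        xs = list(embedded)

    h0 = Tensor(np.zeros((B, cfg.rnn_units)))
    final_states = None
    for layer in range(cfg.rnn_layers):
        if cfg.rnn_kind == "gru":
            hs_f, hf = _gru_direction(params, f"rnn{layer}_fwd", xs, mask, h0, reverse=False)
            hs_b, hb = _gru_direction(params, f"rnn{layer}_bwd", xs, mask, h0, reverse=True)
        else:
            c0 = Tensor(np.zeros((B, cfg.rnn_units)))
            hs_f, hf = _lstm_direction(params, f"rnn{layer}_fwd", xs, mask, h0, c0, reverse=False)
            hs_b, hb = _lstm_direction(params, f"rnn{layer}_bwd", xs, mask, h0, c0, reverse=True)
        xs = [Tensor.concat([hs_f[ti], hs_b[ti]], axis=1) for ti in range(T)]
        final_states = Tensor.concat([hf, hb], axis=1)

    x = final_states
    m = x.mean(axis=1, keepdims=True)
    xc = x - m
    var = xc.square().mean(axis=1, keepdims=True)
    x = xc * (var + 1e-5).pow(-0.5) * params["ln_gain"] + params["ln_bias"]

    for i in range(len(cfg.dense_units)):
        x = (x @ params[f"dense{i}_W"] + params[f"dense{i}_b"]).relu()
        x = dropout(x, x.shape)

    mu = x @ params["mu_W"] + params["mu_b"]
    sigma = (x @ params["sigma_W"] + params["sigma_b"]).softplus() + cfg.sigma_floor
    sigma2 = sigma.square()
    if not (np.all(np.isfinite(mu.data)) and np.all(np.isfinite(sigma2.data))):
        raise NumericalError("non-finite activations in member forward pass")
    return mu, sigma2, embedded


def member_forward(
    tokens: TokenSequence,
    params: MemberParams,
    *,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> MemberPrediction:
    """Single-sequence forward pass returning a :class:`MemberPrediction`."""
    ids = np.array([tokens.ids])
    mu, sigma2, _ = forward_batch(params, ids, training=training, rng=rng)
    return MemberPrediction(mu_m=float(mu.data[0, 0]), sigma2_m=float(sigma2.data[0, 0]))


def predict_members(members: list[MemberParams], ids: np.ndarray) -> list[EnsemblePrediction]:
    """Deterministic (dropout-off) ensemble prediction for a batch."""
    mus = []
    sig2s = []
    for params in members:
        mu, sigma2, _ = forward_batch(params, ids, training=False)
        mus.append(mu.data[:, 0])
        sig2s.append(sigma2.data[:, 0])
    mus_arr = np.array(mus)  # (M, B)
    sig2_arr = np.array(sig2s)
    out = []
    for j in range(ids.shape[0]):
        preds = [MemberPrediction(float(mus_arr[m, j]), float(sig2_arr[m, j])) for m in range(len(members))]
        out.append(aggregate(preds))
    return out
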