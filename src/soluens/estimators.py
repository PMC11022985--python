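"""Scikit-learn style estimators wrapping the deep ensemble.

``DeepEnsembleRegressor`` is the user-facing model: ``fit`` takes SMILES
strings and log S labels, ``predict`` returns the ensemble mean, and
``predict_dist`` exposes the aleatoric/epistemic decomposition.  It composes
with sklearn tooling (``get_params``/``set_params``/``clone``).
``SelfiesTokenizer`` is the corresponding transformer from molecular strings
to padded integer id matrices.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .chem import to_selfies
from .data import MoleculeRecord, augment
from .network import MemberConfig, predict_members
from .selfies_codec import split_tokens
from .training import TrainingConfig, train_ensemble
from .vocab import TokenVocabulary, build_vocabulary, count_unknown, encode_ids


def _as_smiles_list(X) -> list[str]:
    if isinstance(X, str):
        raise ValueError("X must be a sequence of SMILES strings, not a single string")
    X = list(X)
    if not all(isinstance(s, str) for s in X):
        raise ValueError("X must contain SMILES strings")
    return X


class SelfiesTokenizer(TransformerMixin, BaseEstimator):
    """Transform SMILES strings into padded SELFIES token-id matrices.

    ``fit`` builds the token vocabulary from the training corpus; ``transform``
    encodes, mapping out-of-vocabulary tokens to ``<unk>``.  ``max_len=None``
    fits the maximum training sequence length.
    """

    def __init__(self, max_len: int | None = 128, strict: bool = False):
        self.max_len = max_len
        self.strict = strict

    def fit(self, X, y=None):
        selfies = [to_selfies(s) for s in _as_smiles_list(X)]
        if not selfies:
            raise ValueError("empty corpus")
        self.vocabulary_ = build_vocabulary(selfies)
        longest = max(len(split_tokens(s)) for s in selfies)
        self.max_len_ = longest if self.max_len is None else self.max_len
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "vocabulary_")
        selfies = [to_selfies(s) for s in _as_smiles_list(X)]
        return np.array(
            [
                encode_ids(s, self.vocabulary_, self.max_len_, strict=self.strict).ids
                for s in selfies
            ]
        )


class DeepEnsembleRegressor(RegressorMixin, BaseEstimator):
    """Deep ensemble of recurrent heteroscedastic regressors for log S.

    Parameters mirror the reference architecture: embedding (64), two
    bidirectional GRU/LSTM layers (64 units), layer normalization, dense
    32/16 with dropout 0.35, and linear/softplus heads, trained with Adam
    (lr 1e-4, betas 0.9/0.999) on the Gaussian NLL, optionally with
    fast-gradient-sign adversarial updates of strength ``epsilon_adv`` in
    embedding space.  ``augment_max_new`` > 0 enables randomized-SMILES
    augmentation of the training set (labels are inherited from parents).

    Attributes set by ``fit`` (trailing underscore) include ``vocab_``,
    ``members_`` (per-member weights), ``traces_`` (per-epoch losses) and
    ``max_len_``.
    """

    def __init__(
        self,
        ensemble_size: int = 4,
        rnn_kind: str = "lstm",
        embed_dim: int = 64,
        rnn_units: int = 64,
        dense_units: tuple[int, ...] = (32, 16),
        dropout_rate: float = 0.35,
        sigma_floor: float = 1e-3,
        learning_rate: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        adversarial: bool = True,
        epsilon_adv: float = 0.01,
        epochs: int = 50,
        batch_size: int = 32,
        max_len: int | None = 128,
        augment_max_new: int = 0,
        validation_fraction: float = 0.0,
        random_state: int = 0,
    ):
        self.ensemble_size = ensemble_size
        self.rnn_kind = rnn_kind
        self.embed_dim = embed_dim
        self.rnn_units = rnn_units
        self.dense_units = dense_units
        self.dropout_rate = dropout_rate
        self.sigma_floor = sigma_floor
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.adversarial = adversarial
        self.epsilon_adv = epsilon_adv
        self.epochs = epochs
        self.batch_size = batch_size
        self.max_len = max_len
        self.augment_max_new = augment_max_new
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _configs(self, vocab: TokenVocabulary, max_len: int):
        member_config = MemberConfig(
            vocab_size=vocab.size,
            embed_dim=self.embed_dim,
            rnn_kind=self.rnn_kind,
            rnn_units=self.rnn_units,
            dense_units=tuple(self.dense_units),
            dropout_rate=self.dropout_rate,
            sigma_floor=self.sigma_floor,
        )
        training_config = TrainingConfig(
            learning_rate=self.learning_rate,
            beta1=self.beta1,
            beta2=self.beta2,
            epsilon_adv=self.epsilon_adv,
            adversarial=self.adversarial,
            epochs=self.epochs,
            batch_size=self.batch_size,
            ensemble_size=self.ensemble_size,
            max_len=max_len,
        )
        return member_config, training_config

    def fit(self, X, y):
        smiles = _as_smiles_list(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(smiles) != len(y):
            raise ValueError("X and y lengths differ")
        if len(smiles) == 0:
            raise ValueError("empty training data")
        if not np.all(np.isfinite(y)):
            raise ValueError("labels must be finite")

        records = [
            MoleculeRecord(smiles=s, log_s=float(v), source_id=str(i))
            for i, (s, v) in enumerate(zip(smiles, y))
        ]
        if self.augment_max_new > 0:
            records = augment(records, self.augment_max_new, seed=self.random_state)
        selfies = [to_selfies(r.smiles) for r in records]
        labels = np.array([r.log_s for r in records])

        vocab = build_vocabulary(selfies)
        longest = max(len(split_tokens(s)) for s in selfies)
        max_len = longest if self.max_len is None else self.max_len
        kept = [(s, lab) for s, lab in zip(selfies, labels) if len(split_tokens(s)) <= max_len]
        if len(kept) < len(selfies):
            import logging

            logging.getLogger(__name__).warning(
                "rejected %d training sequence(s) longer than max_len=%d",
                len(selfies) - len(kept),
                max_len,
            )
        ids = np.array([encode_ids(s, vocab, max_len, on_overflow="error").ids for s, _ in kept])
        labels = np.array([lab for _, lab in kept])

        val_data = None
        if self.validation_fraction > 0:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(labels))
            n_val = max(1, int(round(self.validation_fraction * len(labels))))
            val_idx, train_idx = order[:n_val], order[n_val:]
            val_data = (ids[val_idx], labels[val_idx])
            ids, labels = ids[train_idx], labels[train_idx]

        member_config, training_config = self._configs(vocab, max_len)
        members, traces = train_ensemble(
            (ids, labels), val_data, member_config, training_config, base_seed=self.random_state
        )

        self.vocab_ = vocab
        self.max_len_ = max_len
        self.member_config_ = member_config
        self.training_config_ = training_config
        self.members_ = members
        self.traces_ = traces
        self.member_seeds_ = training_config.resolved_member_seeds(self.random_state)
        self.n_features_in_ = 1
        return self

    def _encode(self, X) -> tuple[np.ndarray, list[int]]:
        selfies = [to_selfies(s) for s in _as_smiles_list(X)]
        n_unknown = [count_unknown(s, self.vocab_) for s in selfies]
        ids = np.array([encode_ids(s, self.vocab_, self.max_len_).ids for s in selfies])
        return ids, n_unknown

    def predict(self, X, return_std: bool = False):
        """Ensemble mean log S; with ``return_std`` also the total std."""
        check_is_fitted(self, "members_")
        preds = self.predict_dist(X)
        mu = np.array([p.mu_star for p in preds])
        if return_std:
            return mu, np.sqrt(np.array([p.sigma2_total for p in preds]))
        return mu

    def predict_dist(self, X):
        """Full ensemble predictions (mu*, sigma2_ale, sigma2_epi, members)."""
        check_is_fitted(self, "members_")
        ids, _ = self._encode(X)
        return predict_members(self.members_, ids)

    def to_model(self):
        """Export as a saveable :class:`soluens.bundle.EnsembleModel`."""
        from .bundle import EnsembleModel

        check_is_fitted(self, "members_")
        training_config = TrainingConfig(
            **{
                **self.training_config_.__dict__,
                "member_seeds": tuple(self.member_seeds_),
                "max_len": self.max_len_,
            }
        )
        return EnsembleModel(
            members=self.members_,
            vocab=self.vocab_,
            member_config=self.member_config_,
            training_config=training_config,
        )

    @classmethod
    def from_model(cls, model) -> "DeepEnsembleRegressor":
        """Rebuild a fitted estimator from a loaded bundle."""
        mc, tc = model.member_config, model.training_config
        est = cls(
            ensemble_size=len(model.members),
            rnn_kind=mc.rnn_kind,
            embed_dim=mc.embed_dim,
            rnn_units=mc.rnn_units,
            dense_units=mc.dense_units,
            dropout_rate=mc.dropout_rate,
            sigma_floor=mc.sigma_floor,
            learning_rate=tc.learning_rate,
            beta1=tc.beta1,
            beta2=tc.beta2,
            adversarial=tc.adversarial,
            epsilon_adv=tc.epsilon_adv,
            epochs=tc.epochs,
            batch_size=tc.batch_size,
            max_len=tc.max_len,
        )
        est.vocab_ = model.vocab
        est.max_len_ = tc.max_len
        est.member_config_ = mc
        est.training_config_ = tc
        est.members_ = model.members
        est.traces_ = []
        est.member_seeds_ = tc.member_seeds or ()
        est.n_features_in_ = 1
        return est
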