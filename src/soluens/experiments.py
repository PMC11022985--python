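"""Scaled-down uncertainty experiments on the synthetic corpus.

These runners reproduce, at desk scale, the qualitative behaviour of the
full-scale ensembles: recovery of the heteroscedastic noise level by the
aleatoric head, and the dependence of the epistemic variance on ensemble and
training-set size.  Tiny members (embedding 16, 16 recurrent units, GRU,
no dropout) are trained for 50 epochs with Adam at a fixed learning rate of
0.01 on batches of 64 — settings sized for a 5-token-alphabet corpus of a
few thousand molecules rather than the full training database.
Everything is deterministic given the two seeds (corpus and training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from .chem import to_selfies
from .data import MoleculeRecord, shuffle_split
from .evaluation import MetricsReport, compute_metrics
from .network import MemberConfig, MemberParams, predict_members
from .selfies_codec import split_tokens
from .synthetic import SyntheticSpec, generate_synthetic_corpus
from .training import TrainingConfig, train_ensemble
from .vocab import TokenVocabulary, build_vocabulary, encode_ids

TINY_MEMBER = dict(embed_dim=16, rnn_kind="gru", rnn_units=16, dropout_rate=0.0)
TINY_TRAINING = dict(learning_rate=0.01, adversarial=False, epochs=50, batch_size=64)


def tokenize_records(
    records: list[MoleculeRecord],
    vocab: TokenVocabulary | None = None,
    max_len: int | None = None,
) -> tuple[np.ndarray, np.ndarray, TokenVocabulary, int]:
    """SELFIES-encode records into a padded id matrix and a label vector."""
    selfies = [to_selfies(r.smiles) for r in records]
    if vocab is None:
        vocab = build_vocabulary(selfies)
    if max_len is None:
        max_len = max(len(split_tokens(s)) for s in selfies)
    ids = np.array([encode_ids(s, vocab, max_len).ids for s in selfies])
    y = np.array([r.log_s for r in records])
    return ids, y, vocab, max_len


@dataclass
class UncertaintyStudy:
    """Everything the scaled-down uncertainty experiments measure."""

    ale_pearson: float  # corr(sqrt aleatoric variance, true noise std), N=4
    mean_epi: dict[int, float]  # mean held-out epistemic variance per N
    p95_epi: dict[int, float]
    p95_ale: dict[int, float]
    mean_epi_small_train: float  # 10-member pool trained on the small subset
    mean_epi_large_train: float
    metrics: dict[int, MetricsReport]  # held-out metrics per ensemble size
    true_std: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    pools: dict = field(repr=False, default_factory=dict)


def run_uncertainty_study(
    *,
    n_corpus: int = 2000,
    n_small_train: int = 200,
    ensemble_sizes: tuple[int, ...] = (1, 4, 10),
    corpus_seed: int = 11,
    train_seed: int = 2024,
    epochs: int | None = None,
) -> UncertaintyStudy:
    """Train member pools on the synthetic corpus and measure uncertainties.

    One pool of ``max(ensemble_sizes)`` members is trained on the 80% train
    split; sub-ensembles of size N are its first N members, so smaller
    ensembles share seeds with larger ones.  A second pool of the same size
    is trained on the first ``n_small_train`` training records to probe the
    effect of training-set size on member disagreement.
    """
    records, truth = generate_synthetic_corpus(SyntheticSpec(n_molecules=n_corpus, seed=corpus_seed))
    split = shuffle_split(records, 0.8, seed=corpus_seed)
    ids_all, _, vocab, max_len = tokenize_records(records)
    index = {r.source_id: i for i, r in enumerate(records)}
    tr_idx = np.array([index[r.source_id] for r in split.train])
    te_idx = np.array([index[r.source_id] for r in split.test])
    ids, y = ids_all[tr_idx], np.array([r.log_s for r in split.train])
    te_ids, te_y = ids_all[te_idx], np.array([r.log_s for r in split.test])
    true_std = truth["true_std"].to_numpy()[te_idx]

    n_members = max(ensemble_sizes)
    member_config = MemberConfig(vocab_size=vocab.size, **TINY_MEMBER)
    training_kwargs = dict(TINY_TRAINING)
    if epochs is not None:
        training_kwargs["epochs"] = epochs
    training_config = TrainingConfig(
        ensemble_size=n_members, max_len=max_len, **training_kwargs
    )
    pool_large, _ = train_ensemble((ids, y), None, member_config, training_config, base_seed=train_seed)
    pool_small, _ = train_ensemble(
        (ids[:n_small_train], y[:n_small_train]), None, member_config, training_config, base_seed=train_seed
    )

    mean_epi: dict[int, float] = {}
    p95_epi: dict[int, float] = {}
    p95_ale: dict[int, float] = {}
    metrics: dict[int, MetricsReport] = {}
    ale_pearson = float("nan")
    for n in ensemble_sizes:
        preds = predict_members(pool_large[:n], te_ids)
        epi = np.array([p.sigma2_epi for p in preds])
        ale = np.array([p.sigma2_ale for p in preds])
        mean_epi[n] = float(epi.mean())
        p95_epi[n] = float(np.percentile(epi, 95))
        p95_ale[n] = float(np.percentile(ale, 95))
        metrics[n] = compute_metrics([p.mu_star for p in preds], te_y)
        if n == 4 or (4 not in ensemble_sizes and n == max(ensemble_sizes)):
            ale_pearson = float(pearsonr(np.sqrt(ale), true_std).statistic)

    preds_small = predict_members(pool_small, te_ids)
    preds_large = predict_members(pool_large, te_ids)
    return UncertaintyStudy(
        ale_pearson=ale_pearson,
        mean_epi=mean_epi,
        p95_epi=p95_epi,
        p95_ale=p95_ale,
        mean_epi_small_train=float(np.mean([p.sigma2_epi for p in preds_small])),
        mean_epi_large_train=float(np.mean([p.sigma2_epi for p in preds_large])),
        metrics=metrics,
        true_std=true_std,
        pools={"large": pool_large, "small": pool_small, "vocab": vocab, "max_len": max_len},
    )
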