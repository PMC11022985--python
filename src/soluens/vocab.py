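"""Token vocabulary and integer encoding of SELFIES strings.

The vocabulary maps each distinct SELFIES token seen in a training corpus to a
contiguous integer id.  Two special tokens are fixed: the padding token
``<pad>`` at id 0 (masked inside the recurrent layers) and the unknown token
``<unk>`` at id 1, used for out-of-vocabulary tokens at prediction time.
Chemical tokens receive ids 2.. in lexicographic order, which makes the build
deterministic and order/duplicate-invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .selfies_codec import split_tokens

logger = logging.getLogger(__name__)

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
PAD_ID = 0
UNK_ID = 1


class UnknownTokenError(KeyError):
    """Raised in strict mode when a token is missing from the vocabulary."""


@dataclass(frozen=True)
class TokenVocabulary:
    """Bijection between SELFIES tokens and contiguous integer ids."""

    token_to_id: dict[str, int]

    def __post_init__(self) -> None:
        t2i = self.token_to_id
        if t2i.get(PAD_TOKEN) != PAD_ID or t2i.get(UNK_TOKEN) != UNK_ID:
            raise ValueError("vocabulary must map <pad> to 0 and <unk> to 1")
        ids = sorted(t2i.values())
        if ids != list(range(len(t2i))):
            raise ValueError("vocabulary ids must be contiguous from 0")
        if len(set(t2i)) != len(t2i):  # dict keys are unique; kept for clarity
            raise ValueError("duplicate tokens")

    @property
    def size(self) -> int:
        """Total number of ids, special tokens included."""
        return len(self.token_to_id)

    @property
    def n_chemical_tokens(self) -> int:
        """Distinct chemical tokens, excluding ``<pad>`` and ``<unk>``."""
        return len(self.token_to_id) - 2

    @property
    def id_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_id.items()}

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def save(self, path: str | Path) -> None:
        """Write a plain-text manifest, one ``token<TAB>id`` line per entry."""
        lines = [f"{t}\t{i}" for t, i in sorted(self.token_to_id.items(), key=lambda kv: kv[1])]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TokenVocabulary":
        t2i: dict[str, int] = {}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            try:
                token, id_str = line.split("\t")
                t2i[token] = int(id_str)
            except ValueError as exc:
                raise ValueError(f"malformed manifest line {lineno}: {line!r}") from exc
        return cls(t2i)


@dataclass(frozen=True)
class TokenSequence:
    """Integer-encoded, padded SELFIES token sequence."""

    ids: tuple[int, ...]
    length: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.length < 0:
            object.__setattr__(self, "length", len(self.ids))
        if self.length > len(self.ids):
            raise ValueError("length exceeds padded id count")


def build_vocabulary(corpus: list[str]) -> TokenVocabulary:
    """Build a vocabulary from a corpus of SELFIES strings.

    Deterministic: chemical tokens are id-assigned in lexicographic order
    after the specials, so the result is invariant to corpus order and to
    duplicated entries.
    """
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    tokens: set[str] = set()
    for s in corpus:
        tokens.update(split_tokens(s))
    t2i = {PAD_TOKEN: PAD_ID, UNK_TOKEN: UNK_ID}
    for i, token in enumerate(sorted(tokens), start=2):
        t2i[token] = i
    return TokenVocabulary(t2i)


def encode_ids(
    selfies: str,
    vocab: TokenVocabulary,
    max_len: int,
    *,
    strict: bool = False,
    on_overflow: str = "truncate",
) -> TokenSequence:
    """Encode a SELFIES string as a padded id sequence.

    Unknown tokens map to ``<unk>`` with a logged warning (or raise when
    ``strict``).  Sequences longer than ``max_len`` are truncated with a
    warning, or rejected when ``on_overflow='error'`` (used during training
    data preparation).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    tokens = split_tokens(selfies)
    if len(tokens) > max_len:
        if on_overflow == "error":
            raise ValueError(f"sequence of {len(tokens)} tokens exceeds max_len={max_len}")
        logger.warning(
            "truncating sequence of %d tokens to max_len=%d", len(tokens), max_len
        )
        tokens = tokens[:max_len]
    ids = []
    n_unknown = 0
    for token in tokens:
        tid = vocab.token_to_id.get(token)
        if tid is None:
            if strict:
                raise UnknownTokenError(token)
            n_unknown += 1
            tid = UNK_ID
        ids.append(tid)
    if n_unknown:
        logger.warning("%d token(s) not in vocabulary mapped to <unk>", n_unknown)
    length = len(ids)
    ids.extend([PAD_ID] * (max_len - length))
    return TokenSequence(ids=tuple(ids), length=length)


def decode_ids(seq: TokenSequence, vocab: TokenVocabulary) -> list[str]:
    """Invert :func:`encode_ids` over non-pad positions."""
    i2t = vocab.id_to_token
    return [i2t[i] for i in seq.ids[: seq.length]]


def count_unknown(selfies: str, vocab: TokenVocabulary) -> int:
    """Number of tokens in ``selfies`` that are not in the vocabulary."""
    return sum(1 for t in split_tokens(selfies) if t not in vocab)
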