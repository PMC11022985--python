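"""Dataset loading, randomized-SMILES augmentation, and train/test splitting.

The training corpus is an AqSolDB-style CSV of (SMILES, log S) pairs, where
log S is the base-10 logarithm of aqueous solubility in mol/L.  Augmentation
adds up to ``max_new`` randomized SMILES per record, each carrying the parent
record's label, and removes exact string duplicates globally.  The split is
performed *after* augmentation by default, so alternative representations of
one molecule can land on both sides; the leakage report makes this visible,
and a by-parent split mode avoids it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import InvalidMoleculeError, canonicalize, enumerate_randomized

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MoleculeRecord:
    """One SMILES string with its log S label and provenance."""

    smiles: str
    log_s: float
    source_id: str = ""
    parent_canonical: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_s):
            raise ValueError(f"non-finite log S for {self.smiles!r}")
        if not self.parent_canonical:
            object.__setattr__(self, "parent_canonical", canonicalize(self.smiles))


@dataclass(frozen=True)
class DatasetSplit:
    train: list[MoleculeRecord]
    test: list[MoleculeRecord]
    seed: int
    fractions: tuple[float, float] = (0.8, 0.2)

    def leakage_report(self) -> list[str]:
        """Parent molecules (canonical SMILES) present in both halves."""
        train_parents = {r.parent_canonical for r in self.train}
        test_parents = {r.parent_canonical for r in self.test}
        return sorted(train_parents & test_parents)


def load_solubility_csv(
    path: str,
    smiles_column: str = "SMILES",
    label_column: str = "Solubility",
) -> list[MoleculeRecord]:
    """Load an AqSolDB-style CSV into molecule records.

    Rows whose SMILES does not parse are dropped with a logged count; the
    remaining rows become one record each, with ``source_id`` set to the row
    index (or an ``ID`` column when present).
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty table: {path}")
    missing = {smiles_column, label_column} - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s) {sorted(missing)} in {path}")
    id_col = "ID" if "ID" in df.columns else None
    records: list[MoleculeRecord] = []
    n_dropped = 0
    for idx, row in df.iterrows():
        smiles = str(row[smiles_column])
        try:
            parent = canonicalize(smiles)
        except InvalidMoleculeError:
            n_dropped += 1
            continue
        label = float(row[label_column])
        if not np.isfinite(label):
            n_dropped += 1
            continue
        source = str(row[id_col]) if id_col else str(idx)
        records.append(
            MoleculeRecord(smiles=smiles, log_s=label, source_id=source, parent_canonical=parent)
        )
    if n_dropped:
        logger.warning("dropped %d unparsable/invalid row(s) from %s", n_dropped, path)
    if not records:
        raise ValueError(f"no valid molecules in {path}")
    return records


def n_unique_molecules(records: list[MoleculeRecord]) -> int:
    """Number of distinct molecules by canonical SMILES."""
    return len({r.parent_canonical for r in records})


def augment(
    records: list[MoleculeRecord],
    max_new: int,
    seed: int,
    *,
    dedup: str = "string",
) -> list[MoleculeRecord]:
    """Augment records with up to ``max_new`` randomized SMILES each.

    Every new record carries its parent's label and ``parent_canonical``.
    Duplicates are removed globally — by exact string (default, replicating
    the upstream pipeline) or at the canonical-molecule level
    (``dedup='canonical'``, which also collapses distinct representations).
    """
    if max_new < 0:
        raise ValueError("max_new must be >= 0")
    if dedup not in ("string", "canonical"):
        raise ValueError("dedup must be 'string' or 'canonical'")
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    root = np.random.SeedSequence(seed)
    child_seeds = root.generate_state(len(records)) >> 1  # keep below 2**31

    def key(rec: MoleculeRecord) -> str:
        return rec.parent_canonical if dedup == "canonical" else rec.smiles

    for rec, sub_seed in zip(records, child_seeds):
        if key(rec) not in seen:
            seen.add(key(rec))
            out.append(rec)
        for new_smiles in sorted(enumerate_randomized(rec.smiles, max_new, int(sub_seed))):
            new_rec = MoleculeRecord(
                smiles=new_smiles,
                log_s=rec.log_s,
                source_id=rec.source_id,
                parent_canonical=rec.parent_canonical,
            )
            if key(new_rec) not in seen:
                seen.add(key(new_rec))
                out.append(new_rec)
    return out


def shuffle_split(
    records: list[MoleculeRecord],
    train_fraction: float = 0.8,
    seed: int = 0,
    *,
    by_parent: bool = False,
) -> DatasetSplit:
    """Shuffle and split records into train/test partitions.

    With ``by_parent=True`` the split is performed over distinct parent
    molecules so no molecule contributes records to both halves.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    if by_parent:
        parents = sorted({r.parent_canonical for r in records})
        order = rng.permutation(len(parents))
        n_train = int(round(train_fraction * len(parents)))
        train_parents = {parents[i] for i in order[:n_train]}
        train = [r for r in records if r.parent_canonical in train_parents]
        test = [r for r in records if r.parent_canonical not in train_parents]
    else:
        order = rng.permutation(len(records))
        n_train = int(round(train_fraction * len(records)))
        train = [records[i] for i in order[:n_train]]
        test = [records[i] for i in order[n_train:]]
    split = DatasetSplit(train=train, test=test, seed=seed, fractions=(train_fraction, 1 - train_fraction))
    leaked = split.leakage_report()
    if leaked:
        logger.info("%d parent molecule(s) appear in both train and test", len(leaked))
    return split


def records_to_frame(records: list[MoleculeRecord]) -> pd.DataFrame:
    """Tabular view of records (round-trips through :func:`frame_to_records`)."""
    return pd.DataFrame(
        {
            "smiles": [r.smiles for r in records],
            "log_s": [r.log_s for r in records],
            "source_id": [r.source_id for r in records],
            "parent_canonical": [r.parent_canonical for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[MoleculeRecord]:
    return [
        MoleculeRecord(
            smiles=row.smiles,
            log_s=float(row.log_s),
            source_id=str(row.source_id),
            parent_canonical=row.parent_canonical,
        )
        for row in df.itertuples()
    ]
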