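"""Molecular string handling: canonicalization, SMILES randomization, SELFIES.

A molecule here is identified by its canonical SMILES, as produced by RDKit.
One molecule admits many valid SMILES; the recurrent models downstream are
*not* invariant to the chosen string, which is why randomized-SMILES
enumeration (:func:`enumerate_randomized`) is used as data augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from rdkit import Chem

from . import selfies_codec
from .selfies_codec import split_tokens  # re-exported  # noqa: F401


class InvalidMoleculeError(ValueError):
    """Raised when a string does not parse as a molecule in its declared form."""


class StringForm(str, Enum):
    SMILES = "smiles"
    SELFIES = "selfies"


@dataclass(frozen=True)
class MoleculeString:
    """A validated molecular string (SMILES or SELFIES)."""

    raw: str
    form: StringForm = StringForm.SMILES

    def __post_init__(self) -> None:
        if self.form == StringForm.SMILES:
            if Chem.MolFromSmiles(self.raw) is None:
                raise InvalidMoleculeError(f"invalid SMILES: {self.raw!r}")
        else:
            try:
                selfies_codec.decode(self.raw)
            except selfies_codec.SelfiesError as exc:
                raise InvalidMoleculeError(f"invalid SELFIES: {self.raw!r} ({exc})") from exc

    def as_smiles(self) -> str:
        if self.form == StringForm.SMILES:
            return self.raw
        return selfies_codec.decode(self.raw)


def canonicalize(mol: str | MoleculeString) -> str:
    """Return the canonical SMILES defining molecule identity.

    Idempotent; two strings denoting the same molecule map to the same output.
    """
    if isinstance(mol, MoleculeString):
        smiles = mol.as_smiles()
    else:
        smiles = mol
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise InvalidMoleculeError(f"invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(m)


def enumerate_randomized(smiles: str, max_new: int, seed: int) -> set[str]:
    """Enumerate up to ``max_new`` randomized SMILES for one molecule.

    Randomization renumbers the atoms with a seeded permutation and writes a
    non-canonical SMILES rooted at the permuted first atom.  The result
    excludes the input string itself, contains no duplicates, and every member
    canonicalizes back to ``canonicalize(smiles)``.  Attempts are capped at
    ``10 * max_new`` so that molecules with few distinct representations
    (e.g. methane) terminate with fewer, possibly zero, strings.
    """
    if max_new < 0:
        raise ValueError("max_new must be >= 0")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"invalid SMILES: {smiles!r}")
    if max_new == 0:
        return set()
    rng = np.random.default_rng(seed)
    n = mol.GetNumAtoms()
    out: set[str] = set()
    for _ in range(10 * max_new):
        perm = [int(i) for i in rng.permutation(n)]
        randomized = Chem.MolToSmiles(
            Chem.RenumberAtoms(mol, perm), canonical=False, doRandom=False
        )
        if randomized != smiles and Chem.MolFromSmiles(randomized) is not None:
            out.add(randomized)
        if len(out) >= max_new:
            break
    return out


def to_selfies(smiles: str) -> str:
    """Encode a SMILES string as SELFIES (see :mod:`soluens.selfies_codec`)."""
    try:
        return selfies_codec.encode(smiles)
    except selfies_codec.SelfiesEncodeError:
        raise
    except selfies_codec.SelfiesError as exc:  # pragma: no cover
        raise selfies_codec.SelfiesEncodeError(str(exc)) from exc


def from_selfies(selfies: str) -> str:
    """Decode a SELFIES string to canonical SMILES."""
    return selfies_codec.decode(selfies)
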