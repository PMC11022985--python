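"""Synthetic solubility-like corpus with a known heteroscedastic noise model.

The generator emits valid SMILES built from linear carbon/oxygen chains with
occasional single-atom branches — the kind of small aliphatic
alcohols/ethers/polyols a solubility model sees, minus rings, charges and
heteroatoms beyond oxygen.  Labels follow a known linear ground truth

    y = a * n_heavy + b * n_oxygen + Normal(0, std(x)),
    std(x) = c0 + c1 * (n_oxygen / n_heavy),

so both the mean structure and the aleatoric noise level are recoverable by
construction: the noise standard deviation depends only on the oxygen
fraction, a quantity readable from the token sequence.  The defaults
(a=-0.3, b=0.8, c0=0.1, c1=0.4) make heavier molecules less soluble and
oxygen-rich molecules more soluble and noisier, spanning roughly the log S
range and noise scales of curated aqueous-solubility data at toy size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .data import MoleculeRecord


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic corpus generator."""

    n_molecules: int
    coefficients: tuple[float, float] = (-0.3, 0.8)
    noise: tuple[float, float] = (0.1, 0.4)
    seed: int = 11
    min_heavy: int = 5
    max_heavy: int = 14

    def __post_init__(self) -> None:
        c0, c1 = self.noise
        if c0 <= 0:
            raise ValueError("baseline noise c0 must be > 0")
        if c0 + c1 * 0.5 <= 0:  # oxygen fraction never exceeds ~0.5 here
            raise ValueError("noise std must stay positive")
        if self.n_molecules < 10:
            raise ValueError("n_molecules must be >= 10 (too small for any training test)")
        if not 2 <= self.min_heavy <= self.max_heavy:
            raise ValueError("invalid heavy-atom bounds")


def _random_molecule(rng: np.random.Generator, min_heavy: int, max_heavy: int) -> tuple[str, int, int]:
    """Build one chain/branch SMILES; returns (smiles, n_heavy, n_oxygen)."""
    n_heavy = int(rng.integers(min_heavy, max_heavy + 1))
    oxy_frac = float(rng.uniform(0.0, 0.45))
    n_branches = int(rng.integers(0, min(3, max(1, n_heavy - 4)) + 1))
    chain_len = n_heavy - n_branches
    # Backbone atoms: O with probability oxy_frac, never adjacent (no peroxides).
    backbone = []
    for i in range(chain_len):
        if backbone and backbone[-1] == "O":
            backbone.append("C")
        else:
            backbone.append("O" if rng.random() < oxy_frac else "C")
    # Branches attach to interior backbone carbons, at most one per site.
    interior_c = [i for i in range(1, chain_len - 1) if backbone[i] == "C"]
    sites = list(rng.choice(interior_c, size=min(n_branches, len(interior_c)), replace=False)) if interior_c else []
    branch_atoms = {int(i): ("O" if rng.random() < oxy_frac else "C") for i in sites}
    parts = []
    for i, atom in enumerate(backbone):
        parts.append(atom)
        if i in branch_atoms:
            parts.append(f"({branch_atoms[i]})")
    smiles = "".join(parts)
    n_total = chain_len + len(branch_atoms)
    n_oxygen = backbone.count("O") + sum(1 for a in branch_atoms.values() if a == "O")
    return smiles, n_total, n_oxygen


def generate_synthetic_corpus(spec: SyntheticSpec) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Generate the corpus and its ground-truth table.

    Returns ``(records, truth)`` where ``truth`` has one row per record with
    columns ``smiles, n_heavy, n_oxygen, noiseless, true_std, log_s``.
    Deterministic for a fixed spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    a, b = spec.coefficients
    c0, c1 = spec.noise
    records: list[MoleculeRecord] = []
    rows = []
    for i in range(spec.n_molecules):
        smiles, n_heavy, n_oxygen = _random_molecule(rng, spec.min_heavy, spec.max_heavy)
        assert Chem.MolFromSmiles(smiles) is not None, smiles
        noiseless = a * n_heavy + b * n_oxygen
        true_std = c0 + c1 * (n_oxygen / n_heavy)
        label = noiseless + true_std * rng.standard_normal()
        records.append(MoleculeRecord(smiles=smiles, log_s=float(label), source_id=f"syn{i:05d}"))
        rows.append(
            {
                "smiles": smiles,
                "n_heavy": n_heavy,
                "n_oxygen": n_oxygen,
                "noiseless": noiseless,
                "true_std": true_std,
                "log_s": float(label),
            }
        )
    return records, pd.DataFrame(rows)
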