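"""Model bundle: a trained ensemble plus everything needed to reuse it.

A bundle directory contains the vocabulary manifest (``vocab.tsv``), a JSON
config manifest (``config.json`` with all architecture/training fields, seeds
and an optional data fingerprint), and one weights file per member
(``member_000.npz`` ...).  Loading validates that the weights and manifests
are mutually consistent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .chem import MoleculeString, StringForm, to_selfies
from .network import (
    EnsemblePrediction,
    MemberConfig,
    MemberParams,
    init_member_params,
    predict_members,
)
from .training import TrainingConfig
from .vocab import TokenVocabulary, count_unknown, encode_ids


class BundleError(ValueError):
    """Inconsistent or unreadable model bundle."""


@dataclass
class EnsembleModel:
    """A trained deep ensemble bound to its vocabulary."""

    members: list[MemberParams]
    vocab: TokenVocabulary
    member_config: MemberConfig
    training_config: TrainingConfig
    data_fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.member_config.vocab_size != self.vocab.size:
            raise BundleError(
                f"model expects vocab_size={self.member_config.vocab_size} "
                f"but vocabulary manifest has {self.vocab.size} entries"
            )

    def predict_smiles(self, smiles_list: list[str]) -> tuple[list[EnsemblePrediction], list[int]]:
        """Predict log S for SMILES inputs; also reports unknown-token counts."""
        selfies = [to_selfies(s) for s in smiles_list]
        return self.predict_selfies(selfies)

    def predict_selfies(self, selfies_list: list[str]) -> tuple[list[EnsemblePrediction], list[int]]:
        max_len = self.training_config.max_len
        n_unknown = [count_unknown(s, self.vocab) for s in selfies_list]
        ids = np.array([encode_ids(s, self.vocab, max_len).ids for s in selfies_list])
        return predict_members(self.members, ids), n_unknown

    def predict(self, mol: MoleculeString) -> EnsemblePrediction:
        """Predict for a single validated molecule string."""
        if mol.form == StringForm.SELFIES:
            preds, _ = self.predict_selfies([mol.raw])
        else:
            preds, _ = self.predict_smiles([mol.raw])
        return preds[0]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.vocab.save(directory / "vocab.tsv")
        manifest = {
            "package_version": __version__,
            "member_config": dataclasses.asdict(self.member_config),
            "training_config": dataclasses.asdict(self.training_config),
            "n_members": len(self.members),
            "data_fingerprint": self.data_fingerprint,
        }
        (directory / "config.json").write_text(json.dumps(manifest, indent=2) + "\n")
        for i, params in enumerate(self.members):
            np.savez(
                directory / f"member_{i:03d}.npz",
                **{name: t.data for name, t in params.items()},
            )

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        directory = Path(directory)
        try:
            manifest = json.loads((directory / "config.json").read_text())
        except FileNotFoundError as exc:
            raise BundleError(f"no config.json in {directory}") from exc
        mc_dict = dict(manifest["member_config"])
        mc_dict["dense_units"] = tuple(mc_dict["dense_units"])
        member_config = MemberConfig(**mc_dict)
        tc_dict = dict(manifest["training_config"])
        if tc_dict.get("member_seeds") is not None:
            tc_dict["member_seeds"] = tuple(tc_dict["member_seeds"])
        training_config = TrainingConfig(**tc_dict)
        vocab = TokenVocabulary.load(directory / "vocab.tsv")
        members = []
        template = init_member_params(member_config, 0)
        expected = {name: t.data.shape for name, t in template.items()}
        for i in range(int(manifest["n_members"])):
            path = directory / f"member_{i:03d}.npz"
            if not path.exists():
                raise BundleError(f"missing weights file {path.name}")
            with np.load(path) as npz:
                arrays = {k: npz[k] for k in npz.files}
            if {k: v.shape for k, v in arrays.items()} != expected:
                raise BundleError(f"weight shapes in {path.name} do not match config")
            params = init_member_params(member_config, 0)
            for name, arr in arrays.items():
                params[name].data = arr
            members.append(params)
        return cls(
            members=members,
            vocab=vocab,
            member_config=member_config,
            training_config=training_config,
            data_fingerprint=manifest.get("data_fingerprint", ""),
        )
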