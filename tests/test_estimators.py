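"""sklearn-API conformance and end-to-end estimator behaviour."""

import numpy as np
import pytest
from sklearn.base import clone

from soluens.bundle import BundleError, EnsembleModel
from soluens.chem import MoleculeString, StringForm, enumerate_randomized
from soluens.estimators import DeepEnsembleRegressor, SelfiesTokenizer
from soluens.synthetic import SyntheticSpec, generate_synthetic_corpus

TINY = dict(
    embed_dim=4, rnn_units=3, dense_units=(4, 3), dropout_rate=0.0,
    learning_rate=0.02, epochs=3, batch_size=8, max_len=None, ensemble_size=2,
)


@pytest.fixture(scope="module")
def corpus():
    records, _ = generate_synthetic_corpus(SyntheticSpec(n_molecules=40, seed=9))
    return [r.smiles for r in records], np.array([r.log_s for r in records])


@pytest.fixture(scope="module")
def fitted(corpus):
    X, y = corpus
    est = DeepEnsembleRegressor(**TINY, random_state=1)
    return est.fit(X, y)


class TestSelfiesTokenizer:
    def test_fit_transform_shapes_and_padding(self, corpus):
        X, _ = corpus
        tok = SelfiesTokenizer(max_len=None).fit(X)
        ids = tok.transform(X)
        assert ids.shape == (len(X), tok.max_len_)
        assert ids.min() >= 0
        # at least one sequence fills the max length
        assert (ids[:, -1] != 0).any() or (ids != 0).all(axis=1).any()

    def test_unseen_tokens_map_to_unk(self, corpus):
        X, _ = corpus
        tok = SelfiesTokenizer(max_len=32).fit(X)
        ids = tok.transform(["CCN"])  # nitrogen never occurs in the corpus
        assert (ids == 1).sum() == 1

    def test_get_params_round_trip(self):
        tok = SelfiesTokenizer(max_len=64, strict=True)
        assert SelfiesTokenizer(**tok.get_params()).get_params() == tok.get_params()


class TestDeepEnsembleRegressor:
    def test_clone_and_params(self):
        est = DeepEnsembleRegressor(**TINY, random_state=3)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_sets_underscored_attributes(self, fitted):
        assert len(fitted.members_) == 2
        assert fitted.vocab_.size >= 4
        assert len(fitted.traces_) == 2
        assert all(len(t.train_loss) == TINY["epochs"] for t in fitted.traces_)

    def test_predict_shapes_and_determinism(self, fitted, corpus):
        X, _ = corpus
        mu1 = fitted.predict(X[:5])
        mu2 = fitted.predict(X[:5])
        assert mu1.shape == (5,)
        assert np.array_equal(mu1, mu2)
        mu, std = fitted.predict(X[:5], return_std=True)
        assert np.all(std > 0)

    def test_predict_dist_decomposition(self, fitted, corpus):
        X, _ = corpus
        preds = fitted.predict_dist(X[:3])
        for p in preds:
            assert p.n_members == 2
            assert p.sigma2_ale > 0 and p.sigma2_epi >= 0
            assert np.isclose(p.sigma2_total, p.sigma2_ale + p.sigma2_epi)

    def test_same_random_state_reproduces_fit(self, corpus):
        X, y = corpus
        m1 = DeepEnsembleRegressor(**TINY, random_state=7).fit(X[:20], y[:20])
        m2 = DeepEnsembleRegressor(**TINY, random_state=7).fit(X[:20], y[:20])
        assert np.array_equal(m1.predict(X[20:25]), m2.predict(X[20:25]))

    def test_representation_sensitivity_documented(self, fitted):
        """Predictions for different SMILES of one molecule generally differ:
        the network is not representation-invariant by construction."""
        base = "CCOCC"
        alt = sorted(enumerate_randomized(base, 5, seed=0))[0]
        p_base = fitted.predict([base])[0]
        p_alt = fitted.predict([alt])[0]
        assert p_base != p_alt

    def test_input_validation(self, corpus):
        X, y = corpus
        est = DeepEnsembleRegressor(**TINY)
        with pytest.raises(ValueError):
            est.fit("CCO", [0.0])
        with pytest.raises(ValueError):
            est.fit(X[:3], y[:2])
        with pytest.raises(ValueError):
            est.fit([], [])

    def test_augmentation_during_fit(self, corpus):
        X, y = corpus
        est = DeepEnsembleRegressor(**{**TINY, "epochs": 1, "ensemble_size": 1},
                                    augment_max_new=3, random_state=2)
        est.fit(X[:10], y[:10])
        assert len(est.members_) == 1  # smoke: augmented fit completes


class TestBundle:
    def test_save_load_predicts_identically(self, fitted, corpus, tmp_path):
        X, _ = corpus
        model = fitted.to_model()
        model.save(tmp_path / "bundle")
        loaded = EnsembleModel.load(tmp_path / "bundle")
        est2 = DeepEnsembleRegressor.from_model(loaded)
        assert np.allclose(fitted.predict(X[:6]), est2.predict(X[:6]), atol=0)
        assert loaded.vocab.token_to_id == fitted.vocab_.token_to_id

    def test_predict_molecule_string_forms(self, fitted):
        model = fitted.to_model()
        from soluens.chem import to_selfies

        p_smiles = model.predict(MoleculeString("CCO", StringForm.SMILES))
        p_selfies = model.predict(MoleculeString(to_selfies("CCO"), StringForm.SELFIES))
        assert np.isclose(p_smiles.mu_star, p_selfies.mu_star)

    def test_vocab_model_mismatch_rejected(self, fitted, tmp_path):
        model = fitted.to_model()
        model.save(tmp_path / "bundle")
        # corrupt the vocabulary manifest: drop one chemical token
        vocab_path = tmp_path / "bundle" / "vocab.tsv"
        lines = vocab_path.read_text().splitlines()
        vocab_path.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(BundleError):
            EnsembleModel.load(tmp_path / "bundle")

    def test_missing_member_file_rejected(self, fitted, tmp_path):
        model = fitted.to_model()
        model.save(tmp_path / "bundle")
        (tmp_path / "bundle" / "member_001.npz").unlink()
        with pytest.raises(BundleError, match="member_001"):
            EnsembleModel.load(tmp_path / "bundle")
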