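"""Metrics, uncertainty summaries, parity export, ablation bookkeeping."""

import math

import numpy as np
import pytest

from soluens.evaluation import (
    compute_metrics,
    parity_export,
    read_parity,
    run_ablation_grid,
    summarize_uncertainty,
)
from soluens.network import EnsemblePrediction, MemberPrediction, aggregate


class TestComputeMetrics:
    def test_perfect_prediction(self):
        r = compute_metrics([1, 2, 3], [1, 2, 3])
        assert (r.rmse, r.mae, r.acc_half_log) == (0.0, 0.0, 100.0)
        assert np.isclose(r.pearson_r, 1.0, atol=1e-12)

    def test_hand_computed_values(self):
        r = compute_metrics([0, 0, 0], [1, -1, 0.3])
        assert np.isclose(r.rmse, np.sqrt(2.09 / 3), atol=1e-12)
        assert np.isclose(r.mae, 2.3 / 3, atol=1e-12)
        assert np.isclose(r.acc_half_log, 100 / 3, atol=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        p, o = rng.normal(size=50), rng.normal(size=50)
        r1, r2 = compute_metrics(p, o), compute_metrics(p + 2.5, o + 2.5)
        for attr in ("rmse", "mae", "pearson_r", "acc_half_log"):
            assert np.isclose(getattr(r1, attr), getattr(r2, attr))

    def test_order_invariance_and_rmse_ge_mae(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p, o = rng.normal(size=30), rng.normal(size=30)
            r = compute_metrics(p, o)
            assert r.rmse >= r.mae >= 0
            assert 0 <= r.acc_half_log <= 100
            perm = rng.permutation(30)
            r2 = compute_metrics(p[perm], o[perm])
            assert np.isclose(r.rmse, r2.rmse) and np.isclose(r.pearson_r, r2.pearson_r)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        p, o = rng.normal(size=200), rng.normal(size=200)
        r = compute_metrics(p, o)
        assert np.isclose(r.rmse, np.sqrt(np.sum((p - o) ** 2) / 200), atol=1e-12)
        assert np.isclose(r.mae, np.sum(np.abs(p - o)) / 200, atol=1e-12)
        pc = (p - p.mean()) / p.std()
        oc = (o - o.mean()) / o.std()
        assert np.isclose(r.pearson_r, np.mean(pc * oc), atol=1e-12)

    def test_constant_vector_gives_nan_r(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            r = compute_metrics([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        assert math.isnan(r.pearson_r)
        assert "undefined" in caplog.text

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 2], [1, 2, 3])


class TestUncertaintySummary:
    def test_degenerate_ensemble_zero_epistemic(self):
        preds = [aggregate([MemberPrediction(1.0, 0.3)] * 3) for _ in range(5)]
        s = summarize_uncertainty(preds)
        assert np.all(s.sigma2_epi == 0)
        assert s.summaries.loc["sigma2_epi", "max"] == 0.0

    def test_summaries_match_direct_computation(self):
        rng = np.random.default_rng(0)
        preds = []
        for _ in range(40):
            members = [MemberPrediction(float(rng.normal()), float(rng.uniform(0.1, 2))) for _ in range(6)]
            preds.append(aggregate(members))
        s = summarize_uncertainty(preds)
        ale = np.array([p.sigma2_ale for p in preds])
        assert np.isclose(s.summaries.loc["sigma2_ale", "mean"], ale.mean())
        assert np.isclose(s.summaries.loc["sigma2_ale", "p95"], np.percentile(ale, 95))
        assert np.isclose(s.summaries.loc["sigma2_epi", "median"], np.median(s.sigma2_epi))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_uncertainty([])


class TestParityExport:
    def test_round_trip_and_header_metrics(self, tmp_path):
        path = tmp_path / "parity.csv"
        p, o = [0.1, 1.2, -0.5], [0.0, 1.0, 0.2]
        report = parity_export(p, o, path)
        df = read_parity(path)
        assert len(df) == 3
        assert np.allclose(df["predicted"], p)
        assert np.allclose(df["observed"], o)
        header = path.read_text().splitlines()
        assert any(f"rmse = {report.rmse}" in line for line in header)
        assert np.isclose(report.rmse, compute_metrics(p, o).rmse)


@pytest.fixture(scope="module")
def toy_records():
    from soluens.synthetic import SyntheticSpec, generate_synthetic_corpus

    records, _ = generate_synthetic_corpus(SyntheticSpec(n_molecules=40, seed=3))
    return records


class TestAblationGrid:
    BASE = dict(
        embed_dim=4, rnn_units=3, dense_units=(4, 3), dropout_rate=0.0,
        learning_rate=0.02, epochs=2, batch_size=8, max_len=None,
    )

    def test_single_cell_equals_direct_run(self, toy_records):
        from soluens.estimators import DeepEnsembleRegressor
        from soluens.evaluation import compute_metrics as cm

        grid = {"rnn_kind": ["gru"], "ensemble_size": [1], "adversarial": [False]}
        table = run_ablation_grid(grid, toy_records[:30], {"test": toy_records[30:]}, self.BASE, seed=5)
        assert len(table) == 1
        est = DeepEnsembleRegressor(
            **self.BASE, rnn_kind="gru", ensemble_size=1, adversarial=False, random_state=5
        )
        est.fit([r.smiles for r in toy_records[:30]], [r.log_s for r in toy_records[:30]])
        direct = cm(est.predict([r.smiles for r in toy_records[30:]]),
                    [r.log_s for r in toy_records[30:]])
        assert np.isclose(table.iloc[0]["rmse"], direct.rmse)

    def test_row_count_is_grid_times_eval_sets(self, toy_records):
        grid = {"rnn_kind": ["gru"], "adversarial": [False, True], "ensemble_size": [1]}
        table = run_ablation_grid(
            grid, toy_records[:30],
            {"a": toy_records[30:35], "b": toy_records[35:]},
            self.BASE, seed=5,
        )
        assert len(table) == 2 * 2
        assert set(table["eval_set"]) == {"a", "b"}

    def test_failed_cell_recorded_and_grid_continues(self, toy_records):
        grid = {"rnn_kind": ["gru", "not_a_kind"], "ensemble_size": [1], "adversarial": [False]}
        table = run_ablation_grid(grid, toy_records[:30], {"t": toy_records[30:]}, self.BASE, seed=5)
        assert len(table) == 2
        bad = table[table["rnn_kind"] == "not_a_kind"]
        assert bad["error"].iloc[0] != ""
        assert np.isnan(bad["rmse"].iloc[0])


def test_ensemble_averaging_does_not_hurt_rmse(uncertainty_study):
    """Averaging members cannot systematically hurt: held-out RMSE of the
    4-member ensemble stays within 0.05 of the single member's."""
    m = uncertainty_study.metrics
    assert m[4].rmse <= m[1].rmse + 0.05
    assert m[10].rmse <= m[1].rmse + 0.05
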