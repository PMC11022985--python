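"""Regression metrics, uncertainty summaries, parity export, ablation grid.

The headline metrics follow solubility-challenge practice: RMSE and MAE in
log S units, the Pearson correlation coefficient r, and the ±0.5 log%
accuracy — the percentage of predictions whose absolute error is at most
0.5 log S units (closed boundary).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    mae: float
    pearson_r: float  # NaN when undefined (constant vector)
    acc_half_log: float  # percent in [0, 100]
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "rmse": self.rmse,
            "mae": self.mae,
            "pearson_r": self.pearson_r,
            "acc_half_log": self.acc_half_log,
            "n": self.n,
        }


def compute_metrics(predicted, observed) -> MetricsReport:
    """Compute RMSE, MAE, Pearson r and ±0.5 log% accuracy."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed lengths differ")
    if predicted.size < 2:
        raise ValueError("need at least 2 samples")
    err = predicted - observed
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        logger.warning("constant vector: Pearson r undefined, reported as NaN")
        r = math.nan
    else:
        r = float(stats.pearsonr(predicted, observed).statistic)
    acc = float(100.0 * np.mean(np.abs(err) <= 0.5))
    return MetricsReport(rmse=rmse, mae=mae, pearson_r=r, acc_half_log=acc, n=predicted.size)


@dataclass(frozen=True)
class UncertaintySummary:
    """Distribution summaries of the per-sample uncertainty components."""

    sigma2_ale: np.ndarray
    sigma2_epi: np.ndarray
    summaries: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.summaries is None:
            rows = {}
            for name, arr in (("sigma2_ale", self.sigma2_ale), ("sigma2_epi", self.sigma2_epi)):
                rows[name] = {
                    "mean": float(np.mean(arr)),
                    "median": float(np.median(arr)),
                    "p95": float(np.percentile(arr, 95)),
                    "max": float(np.max(arr)),
                }
            object.__setattr__(self, "summaries", pd.DataFrame(rows).T)


def summarize_uncertainty(predictions) -> UncertaintySummary:
    """Summarize aleatoric/epistemic variances of ensemble predictions."""
    if not predictions:
        raise ValueError("no predictions to summarize")
    ale = np.array([p.sigma2_ale for p in predictions])
    epi = np.array([p.sigma2_epi for p in predictions])
    return UncertaintySummary(sigma2_ale=ale, sigma2_epi=epi)


def parity_export(predicted, observed, path: str | Path) -> MetricsReport:
    """Write parity-plot data (predicted, observed) with a metrics header."""
    report = compute_metrics(predicted, observed)
    path = Path(path)
    header = "".join(
        f"# {key} = {value}\n" for key, value in report.as_dict().items()
    )
    df = pd.DataFrame({"predicted": np.asarray(predicted), "observed": np.asarray(observed)})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return report


def read_parity(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_ablation_grid(
    grid: dict[str, list],
    train_records,
    eval_sets: dict[str, list],
    base_params: dict,
    *,
    seed: int = 0,
) -> pd.DataFrame:
    """Train one model per grid cell and evaluate it on every evaluation set.

    ``grid`` maps estimator parameter names (e.g. ``rnn_kind``,
    ``adversarial``, ``ensemble_size``, ``augment_max_new``) to lists of
    values; the full cross product is run.  All cells share the same training
    records, member seeds and evaluation sets, so rows are comparable.  A
    failed cell is recorded with its error and the grid continues.
    """
    from itertools import product

    from .estimators import DeepEnsembleRegressor

    names = sorted(grid)
    rows = []
    train_smiles = [r.smiles for r in train_records]
    train_y = np.array([r.log_s for r in train_records])
    for values in product(*(grid[n] for n in names)):
        cell = dict(zip(names, values))
        est = DeepEnsembleRegressor(**{**base_params, **cell}, random_state=seed)
        try:
            est.fit(train_smiles, train_y)
            for set_name, records in eval_sets.items():
                mu = est.predict([r.smiles for r in records])
                report = compute_metrics(mu, [r.log_s for r in records])
                rows.append({**cell, "eval_set": set_name, **report.as_dict(), "error": ""})
        except Exception as exc:  # noqa: BLE001 - grid must continue
            logger.error("ablation cell %s failed: %s", cell, exc)
            for set_name in eval_sets:
                rows.append(
                    {
                        **cell,
                        "eval_set": set_name,
                        "rmse": math.nan,
                        "mae": math.nan,
                        "pearson_r": math.nan,
                        "acc_half_log": math.nan,
                        "n": 0,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)
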