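"""Counting metrics, calibration and diagnostic analyses.

Implements MAE and sMAPE over per-image count records, the fraction of
images whose true count falls within k predicted standard deviations,
uncertainty averaged in bins of mean colony size or dish coverage, and
per-size-group ordinary-least-squares fits of the self-normalization
parameter beta against dish coverage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import SceneSet
from .model import DensityMapNet
from .training import predict_counts
from .uncertainty import (DropoutInferenceConfig, ensemble_predict,
                          mc_dropout_predict, _LightOutput)

__all__ = ["CountRecord", "MetricsReport", "mae", "smape",
           "within_sigma_fraction", "bin_by_feature", "beta_coverage_fit",
           "evaluate", "records_to_frame"]

log = logging.getLogger(__name__)


@dataclass
class CountRecord:
    """One test image: true count n, predicted count n_hat, 1-sigma, covariates."""

    image_id: str
    n: int
    n_hat: float
    sigma: float = 0.0
    beta: float = 1.0
    coverage: float = math.nan
    mean_colony_size: float = math.nan

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("true count must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class MetricsReport:
    N: int
    mae: float
    smape: float                       # percent, in [0, 100]
    within_1sigma: float
    stratified: pd.DataFrame           # rows: <=50 / >50 / overall
    binned: dict[str, pd.DataFrame] = field(default_factory=dict)
    mean_sigma: float = math.nan
    mean_beta: float = math.nan


# ------------------------------------------------------------------ metrics

def mae(records: list[CountRecord]) -> float:
    """(1/N) sum |n_i - n_hat_i|."""
    if not records:
        raise ValueError("mae of an empty record list is undefined")
    return float(np.mean([abs(r.n - r.n_hat) for r in records]))


def smape(records: list[CountRecord]) -> float:
    """(100/N) sum |n - n_hat| / |n + n_hat|; an exactly-predicted empty dish
    (n = n_hat = 0) contributes 0 by convention."""
    if not records:
        raise ValueError("smape of an empty record list is undefined")
    terms = []
    for r in records:
        num, den = abs(r.n - r.n_hat), abs(r.n + r.n_hat)
        terms.append(0.0 if num == 0.0 else num / den)
    return float(100.0 * np.mean(terms))


def within_sigma_fraction(records: list[CountRecord], k: float = 1.0) -> float:
    """Fraction of records with |n - n_hat| <= k*sigma (sigma=0 needs n == n_hat)."""
    if not records:
        raise ValueError("empty record list")
    covered = [abs(r.n - r.n_hat) <= k * r.sigma for r in records]
    return float(np.mean(covered))


def bin_by_feature(records: list[CountRecord], feature: str,
                   bin_edges) -> pd.DataFrame:
    """Average sigma (and sigma per colony) in bins of a per-image feature."""
    if feature not in ("mean_colony_size", "coverage", "n"):
        raise ValueError("feature must be mean_colony_size, coverage or n")
    edges = np.asarray(bin_edges, dtype=np.float64)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    vals = np.array([getattr(r, feature) for r in records], dtype=np.float64)
    sig = np.array([r.sigma for r in records], dtype=np.float64)
    ns = np.array([r.n for r in records], dtype=np.float64)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        inb = (vals >= lo) & (vals < hi)
        n_in = int(inb.sum())
        pos = inb & (ns > 0)
        rows.append({
            "bin_left": lo, "bin_right": hi, "count": n_in,
            "mean_sigma": float(sig[inb].mean()) if n_in else math.nan,
            "mean_sigma_per_colony": (float((sig[pos] / ns[pos]).mean())
                                      if pos.any() else math.nan),
            "empty": n_in == 0,
        })
    return pd.DataFrame(rows)


def beta_coverage_fit(records: list[CountRecord],
                      size_group_edges) -> pd.DataFrame:
    """OLS line beta ~ coverage within each mean-colony-size group."""
    edges = np.asarray(size_group_edges, dtype=np.float64)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("size_group_edges must be strictly increasing")
    sizes = np.array([r.mean_colony_size for r in records], dtype=np.float64)
    cov = np.array([r.coverage for r in records], dtype=np.float64)
    beta = np.array([r.beta for r in records], dtype=np.float64)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        ing = (sizes >= lo) & (sizes < hi)
        n_in = int(ing.sum())
        row = {"size_low": lo, "size_high": hi, "n": n_in,
               "slope": math.nan, "intercept": math.nan, "fit": False}
        if n_in >= 2 and np.ptp(cov[ing]) > 0:
            res = stats.linregress(cov[ing], beta[ing])
            row.update(slope=float(res.slope), intercept=float(res.intercept),
                       fit=True)
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- evaluate

def _stratum_metrics(records: list[CountRecord], threshold: int) -> pd.DataFrame:
    strata = {
        f"<={threshold}": [r for r in records if r.n <= threshold],
        f">{threshold}": [r for r in records if r.n > threshold],
        "overall": records,
    }
    rows = []
    for name, recs in strata.items():
        if recs:
            rows.append({"stratum": name, "N": len(recs), "mae": mae(recs),
                         "smape": smape(recs),
                         "mean_sigma": float(np.mean([r.sigma for r in recs])),
                         "empty": False})
        else:
            rows.append({"stratum": name, "N": 0, "mae": math.nan,
                         "smape": math.nan, "mean_sigma": math.nan,
                         "empty": True})
    return pd.DataFrame(rows)


def records_to_frame(records: list[CountRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in records])
    frame["n_hat_rounded"] = frame["n_hat"].round().astype(int)
    return frame


def _predict_records(predictor, test_set: SceneSet) -> list[CountRecord]:
    records = []
    for i in range(len(test_set)):
        n_hat, sigma, beta = predictor(i)
        records.append(CountRecord(
            image_id=test_set.ids[i] if test_set.ids else str(i),
            n=int(test_set.counts[i]), n_hat=n_hat, sigma=sigma, beta=beta,
            coverage=float(test_set.coverages[i]),
            mean_colony_size=float(test_set.mean_sizes[i])))
    return records


def evaluate(model_or_ensemble, test_set: SceneSet, method: str = "single",
             dropout_config: DropoutInferenceConfig | None = None,
             stratum_threshold: int = 50,
             size_bins=None, coverage_bins=None,
             ) -> tuple[MetricsReport, pd.DataFrame]:
    """Predict the test split and assemble metrics, strata and binned tables.

    `method` is one of "single" (one deterministic model), "bootstrap"
    (model_or_ensemble is a list of trained members) or "mc_dropout".
    """
    if method == "single":
        model: DensityMapNet = model_or_ensemble
        counts, betas = predict_counts(model, test_set, return_beta=True)
        predictor = lambda i: (float(counts[i]), 0.0, float(betas[i]))
    elif method == "bootstrap":
        members: list[DensityMapNet] = list(model_or_ensemble)
        per_member = [predict_counts(m, test_set, return_beta=True)
                      for m in members]

        def predictor(i):
            outs = [_LightOutput(np.array([[c[i]]])) for c, _ in per_member]
            ens = ensemble_predict(outs, method="bootstrap")
            mean_beta = float(np.mean([b[i] for _, b in per_member]))
            return ens.mean_count, ens.sigma_count, mean_beta
    elif method == "mc_dropout":
        model = model_or_ensemble
        cfg = dropout_config or DropoutInferenceConfig()
        _, det_betas = predict_counts(model, test_set, return_beta=True)

        def predictor(i):
            ens = mc_dropout_predict(model, test_set.images[i], cfg)
            return ens.mean_count, ens.sigma_count, float(det_betas[i])
    else:
        raise ValueError("method must be single, bootstrap or mc_dropout")

    records = _predict_records(predictor, test_set)
    frame = records_to_frame(records)
    sizes = frame["mean_colony_size"].to_numpy()
    finite = sizes[np.isfinite(sizes)]
    if size_bins is None:
        size_bins = (np.linspace(finite.min(), finite.max() + 1e-9, 5)
                     if finite.size else [0, 1])
    if coverage_bins is None:
        coverage_bins = np.linspace(0.0, max(frame["coverage"].max(), 1e-6) + 1e-9, 5)
    report = MetricsReport(
        N=len(records), mae=mae(records), smape=smape(records),
        within_1sigma=within_sigma_fraction(records, 1.0),
        stratified=_stratum_metrics(records, stratum_threshold),
        binned={
            "mean_colony_size": bin_by_feature(records, "mean_colony_size", size_bins),
            "coverage": bin_by_feature(records, "coverage", coverage_bins),
        },
        mean_sigma=float(frame["sigma"].mean()),
        mean_beta=float(frame["beta"].mean()),
    )
    return report, frame
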