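"""Region-level methylation metrics and the baseline-referenced sample score.

For each region (MCB or DMR feature) and sample, two methylation levels are
available: the mean beta-value and the methylated fragment ratio (MFR), the
fraction of qualifying fragments (covering >=3 CpGs in the region, with
conversion rate >=95%) that are fully methylated.  Differential features are
selected between groups by a moderated t-test on the chosen metric.  A test
sample is then scored against the baseline (control) samples: per feature i
a Z-score Z_i = (x_i - mu_i)/sigma_i against the baseline MFR distribution,
transformed to a p-value and combined across the feature set by a weighted
Fisher statistic

    score = sum_i -2 c_i ln(p_i) / sum_i c_i

where the weight c_i is the number of qualifying fragments the sample has on
feature i.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import moderated_t_test

log = logging.getLogger(__name__)

MIN_CPG = 3                # fragment must cover >= 3 CpGs in the region
MIN_CONVERSION = 0.95      # fragment conversion rate >= 95%
P_FLOOR = 1e-300           # keeps -ln(p) finite
SIGMA_MIN = 1e-9           # baseline sd below this is treated as zero


@dataclass(frozen=True)
class BaselineStats:
    """Per-feature baseline mean and standard deviation of MFR."""

    region_id: str
    mu: float
    sigma: float


@dataclass
class MethylationScore:
    sample_id: str
    score: float
    features: pd.DataFrame  # per-feature region_id, z, p, weight


def filter_fragments(records: pd.DataFrame, min_cpg: int = MIN_CPG,
                     min_conversion: float = MIN_CONVERSION) -> pd.DataFrame:
    """Keep fragment methylation records passing both quality filters
    (thresholds inclusive); input order is preserved."""
    keep = (records["n_cpg"] >= min_cpg) \
        & (records["conversion_rate"] >= min_conversion)
    return records[keep]


def region_mfr(records: pd.DataFrame) -> tuple[float, int]:
    """Methylated fragment ratio and weight for one region+sample.

    ``records`` must already be filtered.  Returns (mfr, c) where c is the
    number of qualifying fragments and mfr the fraction of them that are
    fully methylated (n_meth == n_cpg); mfr is NaN when c == 0.
    """
    c = len(records)
    if c == 0:
        return math.nan, 0
    full = int((records["n_meth"] == records["n_cpg"]).sum())
    return full / c, c


def region_mean_beta(betas) -> float:
    """Arithmetic mean of per-CpG beta values on a region (NaN if empty)."""
    arr = np.asarray(list(betas), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        log.warning("no covered CpG; mean beta undefined")
        return math.nan
    return float(arr.mean())


def region_metrics(methcalls: pd.DataFrame, min_cpg: int = MIN_CPG,
                   min_conversion: float = MIN_CONVERSION) -> pd.DataFrame:
    """Per region x sample metrics table from fragment methylation calls.

    Columns: region_id, sample_id, mean_beta, mfr, c.  mean_beta here is the
    fragment-pooled methylation level (total methylated CpG calls over total
    CpG calls among qualifying fragments), the estimate of the region mean
    beta available from fragment summaries.
    """
    filtered = filter_fragments(methcalls, min_cpg, min_conversion)
    grouped = filtered.assign(
        full=(filtered["n_meth"] == filtered["n_cpg"]).astype(int)
    ).groupby(["region_id", "sample_id"], observed=True)
    out = grouped.agg(
        n_meth_total=("n_meth", "sum"),
        n_cpg_total=("n_cpg", "sum"),
        full=("full", "sum"),
        c=("fragment_id", "count"),
    ).reset_index()
    out["mean_beta"] = out["n_meth_total"] / out["n_cpg_total"]
    out["mfr"] = out["full"] / out["c"]
    return out[["region_id", "sample_id", "mean_beta", "mfr", "c"]]


def _metric_matrix(metrics: pd.DataFrame, metric: str) -> pd.DataFrame:
    return metrics.pivot(index="region_id", columns="sample_id",
                         values=metric)


def select_features(metrics: pd.DataFrame, labels: pd.DataFrame,
                    metric: str = "mfr", alpha: float = 0.05) -> list[str]:
    """Regions whose metric differs between groups at unadjusted p < alpha.

    Per region, a moderated t-test compares the chosen metric (``mfr`` or
    ``mean_beta``) between case and control samples; regions with the metric
    undefined (no qualifying fragment) in any sample are excluded.
    """
    mat = _metric_matrix(metrics, metric)
    complete = mat.dropna()
    n_dropped = len(mat) - len(complete)
    if n_dropped:
        log.info("excluding %d region(s) with undefined %s", n_dropped, metric)
    if complete.empty:
        return []
    case = labels.loc[labels["group"] == "case", "sample_id"].tolist()
    control = labels.loc[labels["group"] == "control", "sample_id"].tolist()
    stats = moderated_t_test(complete, case, control)
    keep = stats["p"].to_numpy() < alpha
    return [str(r) for r in complete.index[keep]]


def zscore_vs_baseline(x: float, baseline: BaselineStats) -> float:
    """Standardise a test-sample MFR against the baseline distribution."""
    if baseline.sigma < SIGMA_MIN:
        raise ValueError(f"feature {baseline.region_id}: zero baseline sigma")
    return (x - baseline.mu) / baseline.sigma


def z_to_p(z, side: str = "upper"):
    """Standard-normal tail probability of a Z-score.

    ``upper``: P(Z > z); ``two``: two-sided.
    """
    z = np.asarray(z, dtype=float)
    if side == "upper":
        p = sps.norm.sf(z)
    elif side == "two":
        p = 2.0 * sps.norm.sf(np.abs(z))
    else:
        raise ValueError(f"unknown side {side!r}")
    return float(p) if p.ndim == 0 else p


def methylation_score(p_values, weights, p_floor: float = P_FLOOR) -> float:
    """Weighted Fisher combination:  sum -2 c_i ln(p_i) / sum c_i."""
    p = np.asarray(p_values, dtype=float)
    c = np.asarray(weights, dtype=float)
    if p.size == 0:
        raise ValueError("no features to combine")
    if (c <= 0).any():
        raise ValueError("weights must be positive")
    if (p <= 0).any():
        log.warning("clamping %d nonpositive p-value(s) to %g",
                    int((p <= 0).sum()), p_floor)
    p = np.clip(p, p_floor, 1.0)
    return float((-2.0 * c * np.log(p)).sum() / c.sum())


def baseline_stats(metrics: pd.DataFrame, labels: pd.DataFrame,
                   features: list[str],
                   exclude: str | None = None) -> dict[str, BaselineStats]:
    """Baseline per-feature MFR mean/sd over control samples (optionally
    leaving one control sample out)."""
    controls = labels.loc[labels["group"] == "control", "sample_id"].tolist()
    if exclude is not None:
        controls = [s for s in controls if s != exclude]
    if len(controls) < 2:
        raise ValueError("baseline needs at least two control samples")
    mat = _metric_matrix(metrics, "mfr")
    out = {}
    for f in features:
        vals = mat.loc[f, controls].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size < 2:
            continue
        out[f] = BaselineStats(f, float(vals.mean()),
                               float(vals.std(ddof=1)))
    return out


def score_cohort(metrics: pd.DataFrame, labels: pd.DataFrame,
                 features: list[str], side: str = "upper",
                 leave_one_out: bool = False,
                 p_floor: float = P_FLOOR) -> list[MethylationScore]:
    """Score every sample against the control-group baseline.

    Baseline mu_i/sigma_i come from the control samples; by default a
    control sample's own value is part of the baseline (set
    ``leave_one_out`` to exclude it when scoring that sample).  Features
    with zero baseline sigma are dropped for all samples; features with no
    qualifying fragment in a sample are dropped for that sample only.
    """
    mfr = _metric_matrix(metrics, "mfr")
    cmat = _metric_matrix(metrics, "c")
    group = dict(zip(labels["sample_id"], labels["group"]))

    shared = baseline_stats(metrics, labels, features)
    degenerate = {f for f, b in shared.items() if b.sigma < SIGMA_MIN}
    if degenerate:
        log.warning("dropping %d feature(s) with zero baseline sigma",
                    len(degenerate))
    usable = [f for f in features if f in shared and f not in degenerate]

    results = []
    for sample in labels["sample_id"]:
        if leave_one_out and group[sample] == "control":
            base = baseline_stats(metrics, labels, usable, exclude=sample)
        else:
            base = shared
        rows = []
        for f in usable:
            if f not in base:
                continue
            b = base[f]
            if b.sigma < SIGMA_MIN:
                continue
            x = mfr.at[f, sample] if f in mfr.index else math.nan
            c = cmat.at[f, sample] if f in cmat.index else 0
            if math.isnan(x) or not c > 0:
                continue
            z = zscore_vs_baseline(float(x), b)
            rows.append((f, z, z_to_p(z, side), float(c)))
        feat = pd.DataFrame(rows, columns=["region_id", "z", "p", "weight"])
        if len(feat):
            score = methylation_score(feat["p"], feat["weight"], p_floor)
        else:
            log.warning("sample %s has no scorable feature", sample)
            score = math.nan
        results.append(MethylationScore(sample, score, feat))
    return results
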