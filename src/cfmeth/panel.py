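"""Methylation panel design: DMP selection, DMR merging, MCB construction.

Differentially methylated positions (DMPs) are called on CpG-by-sample
beta-value matrices with a moderated t-test — an ordinary two-group linear
model whose per-CpG variance is shrunk towards a pooled prior by empirical
Bayes, the device that makes small-sample array comparisons stable.  DMPs
within 250 bp of each other chain into differentially methylated regions
(DMRs); runs of >=3 CpGs, each within 100 bp of and Pearson-correlated
>=0.95 with its neighbour, form methylation-correlated blocks (MCBs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DMR_MAX_GAP = 250       # bp, strict: gaps < 250 merge
MCB_MAX_GAP = 100       # bp, inclusive
MCB_MIN_R = 0.95        # Pearson r, inclusive
MCB_MIN_CPGS = 3
DMP_TOP_N = 5000
DMP_DELTA_MIN = 0.3     # strict: |mean beta difference| > 0.3
DMP_FDR_MAX = 0.05      # strict: FDR < 0.05


@dataclass(frozen=True)
class Region:
    """Genomic interval (0-based half-open) holding member CpGs."""

    chrom: str
    start: int
    end: int
    members: tuple[str, ...]
    kind: str  # "DMR" or "MCB"

    def to_bed_row(self) -> dict:
        return {"chrom": self.chrom, "start": self.start, "end": self.end,
                "name": ",".join(self.members)}


def regions_to_bed(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame([r.to_bed_row() for r in regions],
                        columns=["chrom", "start", "end", "name"])


# --- moderated t ----------------------------------------------------------

def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(-dif / x < 1e-8):
            break
    return x


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to observed sample variances.

    Matches the mean and variance of log(s2) against the theoretical moments
    of a scaled F(df, d0) variable, yielding the prior variance s0^2 and
    prior degrees of freedom d0 (possibly inf when the observed spread is no
    wider than sampling alone explains).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array([e_var]))[0])
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0)
                            - np.log(d0 / 2.0)))
    else:
        # spread no wider than sampling alone: infinite prior df, and the
        # pooled variance is simply the average sample variance
        d0 = np.inf
        s0_2 = float(s2[ok].mean())
    return s0_2, d0


def moderated_t_test(beta: pd.DataFrame, group_a: list[str],
                     group_b: list[str],
                     prior_df: float | None = None) -> pd.DataFrame:
    """Per-CpG moderated two-group comparison (group_a minus group_b).

    Parameters
    ----------
    beta
        Matrix in beta.tsv layout (cpg_id, chrom, pos, one column per
        sample) or a plain feature-by-sample frame whose index names the
        features.
    group_a, group_b
        Sample column names; each group needs >=2 samples.
    prior_df
        Override the estimated prior degrees of freedom; 0 recovers the
        ordinary two-sample t-test.

    Returns a frame with columns cpg_id, delta (mean difference), t, p, fdr.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two samples")
    if "cpg_id" in beta.columns:
        ids = beta["cpg_id"].to_numpy()
        a = beta[group_a].to_numpy(dtype=float)
        b = beta[group_b].to_numpy(dtype=float)
    else:
        ids = beta.index.to_numpy()
        a = beta[group_a].to_numpy(dtype=float)
        b = beta[group_b].to_numpy(dtype=float)

    na, nb = a.shape[1], b.shape[1]
    df_resid = na + nb - 2
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    delta = mean_a - mean_b
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) \
        + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    se_scale = np.sqrt(1.0 / na + 1.0 / nb)

    if prior_df is None:
        s0_2, d0 = fit_f_dist(s2, df_resid)
    else:
        d0 = float(prior_df)
        s0_2 = fit_f_dist(s2, df_resid)[0] if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_2)
    else:
        s2_mod = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
    # total df capped at the pooled residual df across all features
    df_total = min(d0 + df_resid, len(s2) * df_resid)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / (np.sqrt(s2_mod) * se_scale)
    t = np.where(np.isnan(t), 0.0, t)  # 0/0: no difference, no evidence
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.minimum(p, 1.0)

    out = pd.DataFrame({"cpg_id": ids, "delta": delta, "t": t, "p": p})
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def select_dmps(stats: pd.DataFrame, mode: str = "threshold",
                top_n: int = DMP_TOP_N, delta_min: float = DMP_DELTA_MIN,
                fdr_max: float = DMP_FDR_MAX) -> pd.DataFrame:
    """Select DMPs from moderated-t statistics.

    ``topN`` mode keeps, among CpGs with fdr < fdr_max, the top_n largest
    absolute mean beta differences (ties broken by larger |delta|, then
    smaller p, then cpg_id).  ``threshold`` mode keeps CpGs with
    |delta| > delta_min and fdr < fdr_max.
    """
    passing = stats[stats["fdr"] < fdr_max].copy()
    if mode == "threshold":
        return passing[passing["delta"].abs() > delta_min].reset_index(drop=True)
    if mode == "topN":
        passing["_absd"] = passing["delta"].abs()
        passing = passing.sort_values(["_absd", "p", "cpg_id"],
                                      ascending=[False, True, True])
        return passing.head(top_n).drop(columns="_absd").reset_index(drop=True)
    raise ValueError(f"unknown mode {mode!r}")


def merge_dmps_to_dmrs(dmps: pd.DataFrame,
                       max_gap: int = DMR_MAX_GAP) -> list[Region]:
    """Chain DMPs into DMRs by single linkage.

    Consecutive DMPs on the same chromosome whose 1-based positions differ
    by strictly less than ``max_gap`` join one DMR; a singleton becomes a
    width-1 region.  ``dmps`` needs columns cpg_id, chrom, pos.
    """
    regions: list[Region] = []
    for chrom, sub in dmps.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        run_ids, run_pos = [], []
        for cpg, pos in zip(sub["cpg_id"], sub["pos"]):
            if run_pos and pos - run_pos[-1] >= max_gap:
                regions.append(Region(chrom, run_pos[0] - 1, run_pos[-1],
                                      tuple(run_ids), "DMR"))
                run_ids, run_pos = [], []
            run_ids.append(cpg)
            run_pos.append(int(pos))
        if run_pos:
            regions.append(Region(chrom, run_pos[0] - 1, run_pos[-1],
                                  tuple(run_ids), "DMR"))
    return regions


def build_mcbs(beta: pd.DataFrame, max_gap: int = MCB_MAX_GAP,
               min_r: float = MCB_MIN_R,
               min_cpgs: int = MCB_MIN_CPGS) -> list[Region]:
    """Chain CpGs into methylation-correlated blocks.

    Scanning CpGs in genomic order, the current block extends while the next
    CpG is at most ``max_gap`` bp from the previous one AND the Pearson
    correlation of their beta values across samples is at least ``min_r``.
    Blocks with at least ``min_cpgs`` sites are emitted.  A zero-variance
    CpG has no defined correlation and breaks the chain.
    """
    sample_cols = [c for c in beta.columns
                   if c not in ("cpg_id", "chrom", "pos")]
    if len(sample_cols) < 3:
        raise ValueError("need at least three samples to correlate CpGs")

    blocks: list[Region] = []

    def flush(chrom, ids, pos):
        if len(ids) >= min_cpgs:
            blocks.append(Region(chrom, pos[0] - 1, pos[-1],
                                 tuple(ids), "MCB"))

    for chrom, sub in beta.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        values = sub[sample_cols].to_numpy(dtype=float)
        ids = sub["cpg_id"].tolist()
        pos = sub["pos"].astype(int).tolist()
        run_i, run_p = [ids[0]], [pos[0]]
        for k in range(1, len(ids)):
            prev, cur = values[k - 1], values[k]
            gap_ok = pos[k] - pos[k - 1] <= max_gap
            if gap_ok and prev.std() > 0 and cur.std() > 0:
                r = float(np.corrcoef(prev, cur)[0, 1])
                link = r >= min_r
            else:
                if gap_ok:
                    log.info("zero-variance CpG breaks chain at %s:%d",
                             chrom, pos[k])
                link = False
            if link:
                run_i.append(ids[k])
                run_p.append(pos[k])
            else:
                flush(chrom, run_i, run_p)
                run_i, run_p = [ids[k]], [pos[k]]
        flush(chrom, run_i, run_p)
    return blocks
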