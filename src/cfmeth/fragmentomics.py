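"""Fragmentation-profile statistics for plasma cfDNA.

Three complementary summaries of cfDNA fragmentation:

* **fragmentation index** — the number of distinct-length electropherogram
  peaks after merging peaks that fall within the instrument's sizing
  resolution (10% relative for peaks under 600 bp, 20% for 600-7000 bp);
* **end-motif frequency** — the frequency of a given 4-mer at fragments'
  5' ends among quality-passing fragments (CCCA is the conventional motif
  score);
* **DELFI score** — the GC-corrected ratio of short (100-150 bp) to long
  (151-220 bp) fragment coverage, averaged over targeted regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

log = logging.getLogger(__name__)

SHORT_RANGE = (100, 150)   # bp, inclusive
LONG_RANGE = (151, 220)    # bp, inclusive
MIN_MAPQ_FIELD = 20        # post-alignment field filter
MIN_MAPQ_MOTIF = 30        # quality filter of the motif-score protocol
MIN_REGIONS_FOR_LOESS = 5


@dataclass
class DelfiResult:
    """Per-region short/long ratios and the per-sample summary score.

    ``regions`` has one row per usable region (long-fragment count > 0) with
    columns name, gc, short, long, raw_ratio, corrected_ratio.
    """

    regions: pd.DataFrame
    score: float
    corrected: bool


def fragmentation_index(peaks: pd.DataFrame | list, res_low: float = 0.10,
                        res_high: float = 0.20) -> int:
    """Count electropherogram peaks that represent distinct fragment lengths.

    Peaks are sorted by size and swept left to right; a peak joins the
    current cluster when its relative difference to the previous peak,
    (larger - smaller)/smaller, is below the sizing resolution of the band
    the smaller peak lies in: ``res_low`` (10%) below 600 bp, ``res_high``
    (20%) for 600 bp and above.  Intensities are ignored.
    """
    if isinstance(peaks, pd.DataFrame):
        sizes = peaks["size_bp"].to_numpy(dtype=float)
    else:
        sizes = np.asarray(list(peaks), dtype=float)
    if sizes.size == 0:
        return 0
    if (sizes <= 0).any():
        raise ValueError("peak sizes must be positive")
    sizes = np.sort(sizes)
    clusters = 1
    prev = sizes[0]
    for s in sizes[1:]:
        tol = res_high if prev >= 600 else res_low
        if (s - prev) / prev >= tol:
            clusters += 1
        prev = s
    return clusters


def _motif_counts(fragments: pd.DataFrame, min_quality: int) -> pd.Series:
    ok = fragments["mapq"] >= min_quality
    motifs = fragments.loc[ok, "motif5p"].astype(str)
    motifs = motifs[~motifs.str.contains("N")]
    return motifs.value_counts()


def end_motif_frequency(fragments: pd.DataFrame, motif: str = "CCCA",
                        min_quality: int = MIN_MAPQ_MOTIF) -> float:
    """Frequency of ``motif`` at 5' fragment ends among quality-passing
    fragments (N-containing motifs excluded from both counts).

    Returns NaN when no fragment passes the quality filter.
    """
    if len(motif) != 4:
        raise ValueError("motif must be a 4-mer")
    counts = _motif_counts(fragments, min_quality)
    total = int(counts.sum())
    if total == 0:
        log.warning("no quality-passing fragments; motif frequency undefined")
        return math.nan
    return counts.get(motif, 0) / total


def all_motif_frequencies(fragments: pd.DataFrame,
                          min_quality: int = MIN_MAPQ_MOTIF) -> dict[str, float]:
    """Frequencies of all 256 5'-end 4-mers; values sum to 1."""
    from .sim import ALL_4MERS
    counts = _motif_counts(fragments, min_quality)
    total = int(counts.sum())
    if total == 0:
        log.warning("no quality-passing fragments; motif frequencies undefined")
        return {m: math.nan for m in ALL_4MERS}
    return {m: counts.get(m, 0) / total for m in ALL_4MERS}


def _assign_regions(fragments: pd.DataFrame,
                    regions: pd.DataFrame) -> pd.Series:
    """Region name per fragment by midpoint containment (NaN if none)."""
    mid = ((fragments["start"] + fragments["end"]) // 2).to_numpy()
    order = np.argsort(regions["start"].to_numpy(), kind="stable")
    starts = regions["start"].to_numpy()[order]
    ends = regions["end"].to_numpy()[order]
    names = regions["name"].to_numpy()[order]
    idx = np.searchsorted(starts, mid, side="right") - 1
    valid = (idx >= 0) & (mid < ends[np.clip(idx, 0, None)])
    chrom_ok = fragments["chrom"].to_numpy() == regions["chrom"].iloc[0]
    assigned = np.where(valid & chrom_ok, names[np.clip(idx, 0, None)], None)
    return pd.Series(assigned, index=fragments.index)


def delfi_score(fragments: pd.DataFrame, regions: pd.DataFrame,
                loess_span: float = 0.75, min_mapq: int = MIN_MAPQ_FIELD,
                pooled: bool = False) -> DelfiResult:
    """Short/long fragment-coverage ratio per region, GC-corrected by LOESS.

    Per region: short = fragments of length 100-150 bp, long = 151-220 bp,
    raw ratio = short/long.  The ratio is regressed on region mean fragment
    GC by locally weighted regression with span ``loess_span`` and corrected
    as residual + grand mean.  Regions with no long fragments are excluded;
    with fewer than five usable regions the correction is skipped and raw
    ratios are used.  The sample score is the mean corrected ratio, or the
    pooled short/long count ratio when ``pooled`` is set.
    """
    frags = fragments[fragments["mapq"] >= min_mapq].copy()
    length = frags["end"] - frags["start"]
    frags["is_short"] = length.between(*SHORT_RANGE)
    frags["is_long"] = length.between(*LONG_RANGE)
    frags["region"] = _assign_regions(frags, regions)
    frags = frags[frags["region"].notna()]

    per = frags.groupby("region").agg(
        gc=("gc", "mean"),
        short=("is_short", "sum"),
        long=("is_long", "sum"),
    ).reset_index().rename(columns={"region": "name"})

    dropped = per[per["long"] == 0]
    if len(dropped):
        log.info("excluding %d region(s) with zero long fragments",
                 len(dropped))
    per = per[per["long"] > 0].copy()
    per["raw_ratio"] = per["short"] / per["long"]

    gc_informative = per["gc"].nunique() > 1
    if len(per) >= MIN_REGIONS_FOR_LOESS and gc_informative:
        fit = lowess(per["raw_ratio"].to_numpy(), per["gc"].to_numpy(),
                     frac=loess_span, return_sorted=False)
        per["corrected_ratio"] = (per["raw_ratio"] - fit
                                  + per["raw_ratio"].mean())
        corrected = True
    elif not gc_informative and len(per) >= MIN_REGIONS_FOR_LOESS:
        # constant covariate: the local fit is the grand mean, a no-op
        per["corrected_ratio"] = per["raw_ratio"]
        corrected = True
    else:
        log.warning("fewer than %d usable regions; GC correction skipped",
                    MIN_REGIONS_FOR_LOESS)
        per["corrected_ratio"] = per["raw_ratio"]
        corrected = False

    if len(per) == 0:
        return DelfiResult(per, math.nan, corrected)
    if pooled:
        score = float(per["short"].sum() / per["long"].sum())
    else:
        score = float(per["corrected_ratio"].mean())
    return DelfiResult(per, score, corrected)


def size_histogram(fragments: pd.DataFrame, bin_width: int = 1) -> pd.DataFrame:
    """Fragment-length histogram: count and proportion per length bin."""
    length = (fragments["end"] - fragments["start"]).to_numpy()
    if length.size == 0:
        return pd.DataFrame(columns=["length", "count", "proportion"])
    bins = (length // bin_width) * bin_width
    counts = pd.Series(bins).value_counts().sort_index()
    return pd.DataFrame({
        "length": counts.index,
        "count": counts.to_numpy(),
        "proportion": counts.to_numpy() / length.size,
    }).reset_index(drop=True)
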