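"""Synthetic cfDNA cohort generator.

Emulates the inputs of a small plasma-cfDNA methylation-sequencing study:
two groups of samples (3 case-like, 6 control-like by default) whose cfDNA
differs in the proportion of short fragments (100-150 bp vs 151-220 bp) and
in per-region methylation level, plus tissue/blood beta-value matrices with
planted differentially methylated positions, and Bioanalyzer-style
electropherogram peak tables.

Everything is generated on one synthetic chromosome ``chrS`` and is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io

log = logging.getLogger(__name__)

CHROM = "chrS"
REGION_LENGTH = 1000
REGION_SPACING = 2000

# Bioanalyzer HS DNA chip sizing-marker range (bp).
MARKER_MIN = 35
MARKER_MAX = 10380

# Fragment-length mixture: short component within the 100-150 bp window,
# long component within 151-220 bp.
SHORT_WINDOW = (100, 150)
LONG_WINDOW = (151, 220)
SHORT_MEAN, SHORT_SD = 135.0, 10.0
LONG_MEAN, LONG_SD = 166.0, 15.0

BASES = "ACGT"
ALL_4MERS = [a + b + c + d for a in BASES for b in BASES for c in BASES for d in BASES]
# Fixed 5'-end 4-mer distribution: uniform background with CCCA enriched to
# a frequency of 5/260 ~ 0.019, the order of magnitude seen in plasma cfDNA.
_MOTIF_WEIGHTS = np.ones(len(ALL_4MERS))
_MOTIF_WEIGHTS[ALL_4MERS.index("CCCA")] = 5.0
MOTIF_PROBS = _MOTIF_WEIGHTS / _MOTIF_WEIGHTS.sum()


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    short_frac defaults are back-derived from typical case/control mean
    short:long coverage ratios of ~0.90 and ~0.76 (p = r/(1+r)); meth_shift
    is the additive increase of case per-region methylation probability.
    """

    seed: int = 0
    n_case: int = 3
    n_control: int = 6
    n_regions: int = 100
    n_fragments_per_sample: int = 10_000
    short_frac_case: float = 0.47
    short_frac_control: float = 0.43
    meth_shift: float = 0.2
    conversion_rate_mean: float = 0.99
    gc_trend_strength: float = 0.2

    def __post_init__(self):
        for name in ("short_frac_case", "short_frac_control",
                     "conversion_rate_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -1.0 <= self.meth_shift <= 1.0:
            raise ValueError(f"meth_shift={self.meth_shift} outside [-1, 1]")
        for name in ("n_case", "n_control", "n_regions",
                     "n_fragments_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")


@dataclass
class SyntheticCohort:
    """All generated inputs plus the true parameters used."""

    fragments: pd.DataFrame
    methcalls: pd.DataFrame
    regions: pd.DataFrame
    labels: pd.DataFrame
    peaks: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels["sample_id"])


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                             random_state=rng)


def _sample_fragments(rng, sample_id, short_frac, n, regions, gc_trend):
    is_short = rng.random(n) < short_frac
    lengths = np.empty(n)
    n_short = int(is_short.sum())
    lengths[is_short] = _trunc_normal(rng, SHORT_MEAN, SHORT_SD,
                                      SHORT_WINDOW[0], SHORT_WINDOW[1], n_short)
    lengths[~is_short] = _trunc_normal(rng, LONG_MEAN, LONG_SD,
                                       LONG_WINDOW[0], LONG_WINDOW[1],
                                       n - n_short)
    lengths = np.round(lengths).astype(int)

    region_idx = rng.integers(0, len(regions), size=n)
    counts = np.bincount(region_idx, minlength=len(regions))
    if (counts == 0).any():
        raise ValueError(
            "a region received zero fragments; increase "
            "n_fragments_per_sample or reduce n_regions")
    mid = regions["start"].to_numpy()[region_idx] + rng.integers(
        0, REGION_LENGTH, size=n)
    start = mid - lengths // 2
    end = start + lengths

    # GC trends against length so that short-rich regions drift in GC and the
    # LOESS correction has a real confounder to remove.
    gc = rng.normal(0.5 + gc_trend * (160.0 - lengths) / 60.0, 0.03)
    gc = np.clip(gc, 0.01, 0.99)

    mapq = rng.choice([60, 40, 25, 10], size=n, p=[0.85, 0.07, 0.04, 0.04])
    motifs = rng.choice(ALL_4MERS, size=n, p=MOTIF_PROBS)

    return pd.DataFrame({
        "sample_id": sample_id,
        "fragment_id": [f"{sample_id}_f{i:06d}" for i in range(n)],
        "chrom": CHROM,
        "start": start,
        "end": end,
        "mapq": mapq,
        "motif5p": motifs,
        "gc": gc,
    }), region_idx


def _sample_methcalls(rng, frags, region_idx, region_ids, meth_prob,
                      conversion_mean):
    n = len(frags)
    n_cpg = rng.poisson(4.0, size=n)
    while (n_cpg == 0).any():          # truncate Poisson at >= 1
        zero = n_cpg == 0
        n_cpg[zero] = rng.poisson(4.0, size=int(zero.sum()))
    p = meth_prob[region_idx]
    n_meth = rng.binomial(n_cpg, p)
    k = 100.0                          # Beta concentration around the mean
    conv = rng.beta(conversion_mean * k, (1.0 - conversion_mean) * k, size=n)
    return pd.DataFrame({
        "sample_id": frags["sample_id"].to_numpy(),
        "fragment_id": frags["fragment_id"].to_numpy(),
        "region_id": region_ids[region_idx],
        "n_cpg": n_cpg,
        "n_meth": n_meth,
        "conversion_rate": conv,
    })


def generate_electropherogram(true_peak_sizes, jitter: float = 0.0,
                              seed: int = 0) -> pd.DataFrame:
    """Emit a peak table whose sizes are the true sizes perturbed by at most
    ``jitter`` relative error; sizes must lie within the sizing-marker range."""
    sizes = np.asarray(list(true_peak_sizes), dtype=float)
    if sizes.size and ((sizes < MARKER_MIN) | (sizes > MARKER_MAX)).any():
        raise ValueError(
            f"peak sizes must lie within [{MARKER_MIN}, {MARKER_MAX}] bp")
    rng = np.random.default_rng(seed)
    emitted = sizes * (1.0 + rng.uniform(-jitter, jitter, size=sizes.size))
    intensity = rng.lognormal(4.0, 0.3, size=sizes.size)
    return pd.DataFrame({"size_bp": emitted, "intensity": intensity})


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate fragment tables, methylation calls, regions, labels and
    electropherograms for a two-group cohort."""
    rng = np.random.default_rng(config.seed)

    starts = np.arange(config.n_regions) * REGION_SPACING
    region_ids = np.array([f"R{i:04d}" for i in range(config.n_regions)])
    regions = pd.DataFrame({
        "chrom": CHROM,
        "start": starts,
        "end": starts + REGION_LENGTH,
        "name": region_ids,
    })

    meth_control = rng.uniform(0.1, 0.5, size=config.n_regions)
    meth_case = np.clip(meth_control + config.meth_shift, 0.0, 1.0)

    samples = ([(f"case{i+1:02d}", "case") for i in range(config.n_case)]
               + [(f"ctrl{i+1:02d}", "control")
                  for i in range(config.n_control)])

    frag_tables, meth_tables, peak_tables = [], [], []
    for sample_id, group in samples:
        short_frac = (config.short_frac_case if group == "case"
                      else config.short_frac_control)
        frags, region_idx = _sample_fragments(
            rng, sample_id, short_frac, config.n_fragments_per_sample,
            regions, config.gc_trend_strength)
        meth_prob = meth_case if group == "case" else meth_control
        calls = _sample_methcalls(rng, frags, region_idx, region_ids,
                                  meth_prob, config.conversion_rate_mean)
        frag_tables.append(frags)
        meth_tables.append(calls)

        # mononucleosome / dinucleosome peaks plus a few sample-specific ones
        n_extra = rng.poisson(3.0)
        extra = np.exp(rng.uniform(np.log(MARKER_MIN + 1),
                                   np.log(MARKER_MAX - 1), size=n_extra))
        peaks = generate_electropherogram(
            np.concatenate([[166.0, 332.0], extra]), jitter=0.02,
            seed=int(rng.integers(0, 2**31 - 1)))
        peaks.insert(0, "sample_id", sample_id)
        peak_tables.append(peaks)

    labels = pd.DataFrame(samples, columns=["sample_id", "group"])
    return SyntheticCohort(
        fragments=pd.concat(frag_tables, ignore_index=True),
        methcalls=pd.concat(meth_tables, ignore_index=True),
        regions=regions,
        labels=labels,
        peaks=pd.concat(peak_tables, ignore_index=True),
        params={
            "config": asdict(config),
            "meth_prob_control": meth_control.tolist(),
            "meth_prob_case": meth_case.tolist(),
        },
    )


def generate_beta_matrix(n_tumor: int, n_normal: int, n_blood: int,
                         n_cpg: int, n_planted_dmp: int, delta: float,
                         seed: int = 0):
    """CpG-by-sample beta matrix with planted tumor-vs-blood DMPs.

    CpGs sit on ``chrS`` in correlated clusters of five consecutive sites,
    with inter-site gaps mixing values below and above the 100 bp and 250 bp
    chaining thresholds so block construction and DMR merging are both
    exercised.  Planted DMPs occupy whole clusters and carry a mean
    tumor-minus-blood beta difference of ``delta``.

    Returns ``(beta, groups, truth)``: the matrix in beta.tsv layout, a
    sample->group mapping, and the planted CpG-id truth set.
    """
    if delta > 1.0:
        raise ValueError("delta cannot exceed 1")
    if n_planted_dmp > n_cpg:
        raise ValueError("n_planted_dmp cannot exceed n_cpg")
    rng = np.random.default_rng(seed)

    gaps = rng.choice([30, 60, 90, 150, 300, 600], size=n_cpg)
    pos = 1000 + np.cumsum(gaps)                       # 1-based positions
    cluster = np.arange(n_cpg) // 5
    n_clusters = int(cluster.max()) + 1

    planted = np.zeros(n_cpg, dtype=bool)
    order = rng.permutation(n_clusters)
    for k in order:
        if planted.sum() >= n_planted_dmp:
            break
        members = np.flatnonzero(cluster == k)
        take = members[: n_planted_dmp - int(planted.sum())]
        planted[take] = True

    groups = {}
    for prefix, n, g in (("T", n_tumor, "tumor"), ("N", n_normal, "normal"),
                         ("B", n_blood, "blood")):
        for i in range(n):
            groups[f"{prefix}{i+1:02d}"] = g
    sample_ids = list(groups)

    hi = max(0.1, 1.0 - abs(delta) - 0.05)
    base = rng.uniform(0.05, hi, size=n_cpg)

    data = {}
    # shared within-cluster factor drives adjacent-CpG correlation (~0.96)
    factor_sd, noise_sd = 0.10, 0.02
    for s in sample_ids:
        u = rng.normal(0.0, 1.0, size=n_clusters)
        eps = rng.normal(0.0, 1.0, size=n_cpg)
        shift = np.zeros(n_cpg)
        if groups[s] == "tumor":
            shift[planted] = delta
        elif groups[s] == "normal":
            shift[planted] = delta / 2.0
        beta = base + shift + factor_sd * u[cluster] + noise_sd * eps
        data[s] = np.clip(beta, 0.0, 1.0)

    out = pd.DataFrame({
        "cpg_id": [f"cg{i:06d}" for i in range(n_cpg)],
        "chrom": CHROM,
        "pos": pos,
        **data,
    })
    truth = set(out.loc[planted, "cpg_id"])
    return out, groups, truth


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Emit the cohort's tables in the package's standard text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fragments(cohort.fragments, outdir / "fragments.tsv")
    io.write_methcalls(cohort.methcalls, outdir / "methcalls.tsv")
    io.write_regions_bed(cohort.regions, outdir / "regions.bed")
    io.write_labels(cohort.labels, outdir / "labels.tsv")
    io.write_peaks(cohort.peaks, outdir / "peaks.csv")
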