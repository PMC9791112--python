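"""Readers and writers for the pipeline's plain-text formats.

All tables are tab- or comma-separated text with canonical column orders and
fixed float formatting, so that ``write(read(path))`` reproduces *path*
byte-identically.  Coordinates follow the BED convention: 0-based, half-open.

Formats
-------
fragments.tsv
    sample_id, fragment_id, chrom, start, end, mapq, motif5p, gc
methcalls.tsv
    sample_id, fragment_id, region_id, n_cpg, n_meth, conversion_rate
regions.bed
    chrom, start, end, name (no header)
beta.tsv
    cpg_id, chrom, pos, <one column per sample>  (pos is 1-based)
peaks.csv
    sample_id, size_bp, intensity
labels.tsv
    sample_id, group  (group in {case, control})
"""

from __future__ import annotations

import pandas as pd

FRAGMENT_COLUMNS = [
    "sample_id", "fragment_id", "chrom", "start", "end", "mapq", "motif5p", "gc",
]
METHCALL_COLUMNS = [
    "sample_id", "fragment_id", "region_id", "n_cpg", "n_meth", "conversion_rate",
]
REGION_COLUMNS = ["chrom", "start", "end", "name"]
PEAK_COLUMNS = ["sample_id", "size_bp", "intensity"]
LABEL_COLUMNS = ["sample_id", "group"]


def _require(df: pd.DataFrame, columns: list[str], what: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing columns: {missing}")
    return df.loc[:, columns]


def write_fragments(df: pd.DataFrame, path) -> None:
    out = _require(df, FRAGMENT_COLUMNS, "fragment").copy()
    out["gc"] = out["gc"].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


def read_fragments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "motif5p": str})
    return _require(df, FRAGMENT_COLUMNS, "fragment")


def write_methcalls(df: pd.DataFrame, path) -> None:
    out = _require(df, METHCALL_COLUMNS, "methylation-call").copy()
    out["conversion_rate"] = out["conversion_rate"].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


def read_methcalls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return _require(df, METHCALL_COLUMNS, "methylation-call")


def write_regions_bed(df: pd.DataFrame, path) -> None:
    out = _require(df, REGION_COLUMNS, "region")
    out.to_csv(path, sep="\t", index=False, header=False)


def read_regions_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=REGION_COLUMNS,
                     dtype={"chrom": str, "name": str})
    return df


def write_beta(df: pd.DataFrame, path) -> None:
    """Write a CpG-by-sample beta matrix.

    *df* must carry cpg_id, chrom, pos plus one float column per sample.
    """
    fixed = ["cpg_id", "chrom", "pos"]
    out = _require(df, fixed + [c for c in df.columns if c not in fixed],
                   "beta").copy()
    for c in out.columns[3:]:
        out[c] = out[c].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_beta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cpg_id": str, "chrom": str})
    if list(df.columns[:3]) != ["cpg_id", "chrom", "pos"]:
        raise ValueError("beta table must start with cpg_id, chrom, pos")
    return df


def write_peaks(df: pd.DataFrame, path) -> None:
    out = _require(df, PEAK_COLUMNS, "peak").copy()
    out["size_bp"] = out["size_bp"].map(lambda v: f"{v:.2f}")
    out["intensity"] = out["intensity"].map(lambda v: f"{v:.2f}")
    out.to_csv(path, index=False)


def read_peaks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _require(df, PEAK_COLUMNS, "peak")


def write_labels(df: pd.DataFrame, path) -> None:
    _require(df, LABEL_COLUMNS, "label").to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return _require(df, LABEL_COLUMNS, "label")
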