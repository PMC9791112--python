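"""End-to-end orchestration: simulate -> fragmentomics -> panel -> scores ->
group statistics -> LOOCV, with a machine-readable results.json and a
human-readable report.md.

The configuration is a nested mapping (or a YAML file) with blocks ``sim``,
``fragmentomics``, ``panel``, ``scoring`` and ``classify``; every block is
optional and falls back to the package defaults.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, fragmentomics, io, panel, scoring, sim, stats

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Raised when a pipeline stage fails, labelled with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - relabelled and re-raised
                raise StageError(name, exc) from exc
        return inner
    return wrap


@_stage("simulate")
def _simulate(cfg: dict, outdir: Path) -> sim.SyntheticCohort:
    conf = sim.SimConfig(**cfg.get("sim", {}))
    cohort = sim.generate_cohort(conf)
    sim.write_cohort(cohort, outdir)
    return cohort


@_stage("fragmentomics")
def _fragmentomics(cfg: dict, cohort: sim.SyntheticCohort) -> pd.DataFrame:
    fcfg = cfg.get("fragmentomics", {})
    motif = fcfg.get("motif", "CCCA")
    min_mapq = fcfg.get("min_mapq", fragmentomics.MIN_MAPQ_MOTIF)
    span = fcfg.get("loess_span", 0.75)
    rows = []
    for sample in cohort.sample_ids:
        frags = cohort.fragments[cohort.fragments["sample_id"] == sample]
        peaks = cohort.peaks[cohort.peaks["sample_id"] == sample]
        delfi = fragmentomics.delfi_score(frags, cohort.regions,
                                          loess_span=span)
        rows.append({
            "sample_id": sample,
            "fragmentation_index": fragmentomics.fragmentation_index(peaks),
            "motif_score": fragmentomics.end_motif_frequency(
                frags, motif, min_mapq),
            "delfi_score": delfi.score,
        })
    return pd.DataFrame(rows)


@_stage("panel")
def _panel(cfg: dict, seed: int, outdir: Path) -> dict:
    pcfg = cfg.get("panel", {})
    beta, groups, truth = sim.generate_beta_matrix(
        n_tumor=pcfg.get("n_tumor", 20), n_normal=pcfg.get("n_normal", 20),
        n_blood=pcfg.get("n_blood", 20), n_cpg=pcfg.get("n_cpg", 2000),
        n_planted_dmp=pcfg.get("n_planted_dmp", 100),
        delta=pcfg.get("delta", 0.5), seed=seed)
    io.write_beta(beta, outdir / "beta.tsv")
    tumors = [s for s, g in groups.items() if g == "tumor"]
    blood = [s for s, g in groups.items() if g == "blood"]
    dmp_stats = panel.moderated_t_test(beta, tumors, blood)
    dmps = panel.select_dmps(dmp_stats, mode=pcfg.get("mode", "threshold"),
                             delta_min=pcfg.get("delta_min", 0.3),
                             fdr_max=pcfg.get("fdr_max", 0.05))
    dmps = dmps.merge(beta[["cpg_id", "chrom", "pos"]], on="cpg_id")
    dmrs = panel.merge_dmps_to_dmrs(dmps)
    mcbs = panel.build_mcbs(beta)
    dmps.to_csv(outdir / "dmps.tsv", sep="\t", index=False)
    io.write_regions_bed(panel.regions_to_bed(dmrs), outdir / "dmrs.bed")
    io.write_regions_bed(panel.regions_to_bed(mcbs), outdir / "mcbs.bed")
    recall = (len(set(dmps["cpg_id"]) & truth) / len(truth)) if truth else np.nan
    return {"n_dmps": len(dmps), "n_dmrs": len(dmrs), "n_mcbs": len(mcbs),
            "planted_dmp_recall": recall}


@_stage("scoring")
def _scoring(cfg: dict, cohort: sim.SyntheticCohort, outdir: Path):
    scfg = cfg.get("scoring", {})
    metrics = scoring.region_metrics(
        cohort.methcalls, min_cpg=scfg.get("min_cpg", scoring.MIN_CPG),
        min_conversion=scfg.get("min_conversion", scoring.MIN_CONVERSION))
    metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    features = scoring.select_features(
        metrics, cohort.labels, metric=scfg.get("metric", "mfr"),
        alpha=scfg.get("alpha", 0.05))
    scores = scoring.score_cohort(metrics, cohort.labels, features,
                                  side=scfg.get("side", "upper"))
    table = pd.DataFrame({
        "sample_id": [s.sample_id for s in scores],
        "methylation_score": [s.score for s in scores],
    })
    table.to_csv(outdir / "scores.tsv", sep="\t", index=False)
    return metrics, features, table


def _group_values(table: pd.DataFrame, labels: pd.DataFrame, column: str):
    merged = table.merge(labels, on="sample_id")
    case = merged.loc[merged["group"] == "case", column].dropna()
    control = merged.loc[merged["group"] == "control", column].dropna()
    return case.to_numpy(), control.to_numpy()


@_stage("group_tests")
def _group_tests(frag_table, score_table, labels) -> dict:
    out = {}
    for column, table in (("fragmentation_index", frag_table),
                          ("motif_score", frag_table),
                          ("delfi_score", frag_table),
                          ("methylation_score", score_table)):
        case, control = _group_values(table, labels, column)
        if len(case) == 0 or len(control) == 0:
            continue
        res = stats.exact_rank_sum(case, control)
        out[column] = {
            "mean_case": float(np.mean(case)),
            "mean_control": float(np.mean(control)),
            "U": res.U, "p": res.p_two_sided, "method": res.method,
        }
    return out


@_stage("classify")
def _classify(cfg: dict, metrics, features, labels, seed: int) -> dict:
    if not features:
        return {"skipped": "no selected features"}
    ccfg = cfg.get("classify", {})
    kinds = ccfg.get("models",
                     ["logistic", "decision_tree", "random_forest", "svc"])
    mat = metrics.pivot(index="region_id", columns="sample_id", values="mfr")
    X = mat.loc[features].T.fillna(0.0)
    results = []
    for kind in kinds:
        spec = classify.ModelSpec(kind, ccfg.get("thresholds", {}).get(kind))
        results.append(classify.loocv_predict(X, labels, spec, seed=seed))
    out = {r.spec.kind: {"accuracy": r.accuracy,
                         "threshold": r.spec.resolved_threshold()}
           for r in results}
    if len(results) >= 2:
        agree = classify.concordance(results)
        out["concordance"] = float(agree["agree"].mean())
    return out


def run_pipeline(config: dict | str | Path, outdir) -> dict:
    """Run the full analysis and write results.json, report.md and all
    intermediate tables under ``outdir``; returns the results mapping."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("sim", {}).get("seed", 0))

    cohort = _simulate(config, outdir)
    frag_table = _fragmentomics(config, cohort)
    frag_table.to_csv(outdir / "fragmentomics.tsv", sep="\t", index=False)
    panel_summary = _panel(config, seed, outdir)
    metrics, features, score_table = _scoring(config, cohort, outdir)
    tests = _group_tests(frag_table, score_table, cohort.labels)
    models = _classify(config, metrics, features, cohort.labels, seed)

    alpha = config.get("scoring", {}).get("alpha", 0.05)
    results = {
        "n_samples": len(cohort.labels),
        "panel": panel_summary,
        "n_selected_features": len(features),
        "selected_fraction": len(features) / cohort.params["config"]["n_regions"],
        "alpha": alpha,
        "group_tests": tests,
        "classification": models,
    }
    (outdir / "results.json").write_text(json.dumps(results, indent=2))
    (outdir / "report.md").write_text(_render_report(results))
    return results


def _render_report(results: dict) -> str:
    lines = ["# cfDNA cohort analysis report", ""]
    lines.append(f"Samples analysed: {results['n_samples']}")
    lines.append(f"Selected differential features (p < {results['alpha']}): "
                 f"{results['n_selected_features']}")
    p = results["panel"]
    lines += ["", "## Panel design (synthetic tissue arrays)",
              f"- DMPs selected: {p['n_dmps']}",
              f"- DMRs after 250 bp merging: {p['n_dmrs']}",
              f"- MCBs (>=3 CpGs, <=100 bp, r>=0.95): {p['n_mcbs']}"]
    lines += ["", "## Group comparisons (exact rank-sum)", ""]
    lines.append("| statistic | mean case | mean control | p |")
    lines.append("|---|---|---|---|")
    for name, t in results["group_tests"].items():
        lines.append(f"| {name} | {t['mean_case']:.4f} | "
                     f"{t['mean_control']:.4f} | {t['p']:.4f} |")
    cls = results["classification"]
    lines += ["", "## Leave-one-out classification", ""]
    for kind, info in cls.items():
        if isinstance(info, dict):
            lines.append(f"- {kind}: accuracy {info['accuracy']:.3f} "
                         f"(threshold {info['threshold']})")
    if "concordance" in cls:
        lines.append(f"- model concordance: {cls['concordance']:.3f}")
    return "\n".join(lines) + "\n"
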