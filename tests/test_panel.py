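"""DMP calling (moderated t), FDR, DMR merging and MCB construction."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cfmeth import (bh_fdr, build_mcbs, generate_beta_matrix,
                    merge_dmps_to_dmrs, moderated_t_test, select_dmps)


def beta_frame(values: np.ndarray, samples: list[str],
               pos=None) -> pd.DataFrame:
    n = values.shape[0]
    return pd.DataFrame({
        "cpg_id": [f"cg{i:04d}" for i in range(n)],
        "chrom": "chrS",
        "pos": pos if pos is not None else 100 * np.arange(1, n + 1),
        **{s: values[:, j] for j, s in enumerate(samples)},
    })


class TestModeratedT:
    def test_identical_group_means_give_zero_t(self):
        vals = np.array([[0.5, 0.6, 0.5, 0.6],
                         [0.1, 0.3, 0.2, 0.2],
                         [0.8, 0.9, 0.85, 0.85]])
        df = beta_frame(vals, ["a1", "a2", "b1", "b2"])
        out = moderated_t_test(df, ["a1", "a2"], ["b1", "b2"])
        row = out[out["cpg_id"] == "cg0000"].iloc[0]
        assert row["t"] == 0.0
        assert row["p"] == 1.0

    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.1, 0.9, size=(50, 8))
        samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        df = beta_frame(vals, samples)
        out = moderated_t_test(df, samples[:4], samples[4:], prior_df=0)
        t_ref, p_ref = sps.ttest_ind(vals[:, :4], vals[:, 4:], axis=1)
        assert np.allclose(out["t"], t_ref)
        assert np.allclose(out["p"], p_ref)

    def test_requires_two_samples_per_group(self):
        df = beta_frame(np.ones((3, 3)) * 0.5, ["a1", "b1", "b2"])
        with pytest.raises(ValueError):
            moderated_t_test(df, ["a1"], ["b1", "b2"])

    def test_null_p_values_uniform(self):
        """Moderated-t p-values on pure-noise matrices stay calibrated."""
        ks_ps = []
        samples = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = rng.normal(0.5, 0.1, size=(2000, 12))
            df = beta_frame(vals, samples,
                            pos=100 * np.arange(1, 2001))
            out = moderated_t_test(df, samples[:6], samples[6:])
            ks_ps.append(sps.kstest(out["p"], "uniform").pvalue)
        assert np.median(ks_ps) > 0.01

    def test_matches_limma_on_small_matrix(self):
        """Independent oracle: R limma eBayes on the same matrix."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(12)
        vals = rng.uniform(0.05, 0.95, size=(200, 10))
        samples = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        df = beta_frame(vals, samples)
        out = moderated_t_test(df, samples[:5], samples[5:])

        matrix = "\n".join(",".join(f"{v:.10f}" for v in row)
                           for row in vals)
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            m <- as.matrix(read.csv("stdin", header=FALSE))
            design <- cbind(Intercept=1, Group=c(rep(1,5), rep(0,5)))
            fit <- eBayes(lmFit(m, design))
            out <- cbind(fit$t[,"Group"], fit$p.value[,"Group"],
                         fit$df.prior, fit$s2.prior)
            write.table(format(out, digits=12), stdout(),
                        row.names=FALSE, col.names=FALSE, quote=FALSE)
        """)
        res = subprocess.run(["Rscript", "-e", script], input=matrix,
                             capture_output=True, text=True, check=True)
        ref = np.array([[float(v) for v in line.split()]
                        for line in res.stdout.strip().splitlines()])
        assert np.allclose(out["t"], ref[:, 0], rtol=1e-6)
        assert np.allclose(out["p"], ref[:, 1], rtol=1e-6)


class TestBhFdr:
    def test_step_up_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_stay_equal(self):
        assert np.allclose(bh_fdr([0.3, 0.3, 0.3]), 0.3)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_reapplication_never_decreases(self, p):
        q = bh_fdr(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        assert (bh_fdr(q) >= q - 1e-12).all()


class TestSelectDmps:
    def stats_frame(self, rows):
        return pd.DataFrame(rows, columns=["cpg_id", "delta", "t", "p", "fdr"])

    def test_threshold_mode_filters(self):
        stats = self.stats_frame([
            ("c1", 0.5, 5, 1e-4, 0.01),
            ("c2", 0.35, 3, 0.05, 0.2),    # fails FDR
            ("c3", 0.31, 3, 1e-3, 0.01),
            ("c4", 0.8, 8, 1e-5, 0.04),
        ])
        out = select_dmps(stats, mode="threshold")
        assert list(out["cpg_id"]) == ["c1", "c3", "c4"]

    def test_nothing_passes_fdr_gives_empty(self):
        stats = self.stats_frame([("c1", 0.9, 9, 0.4, 0.6)])
        assert len(select_dmps(stats)) == 0

    def test_topn_takes_largest_absolute_differences(self):
        stats = self.stats_frame([
            ("c1", 0.2, 2, 0.01, 0.02),
            ("c2", -0.6, -6, 0.001, 0.004),
            ("c3", 0.4, 4, 0.005, 0.01),
            ("c4", 0.1, 1, 0.02, 0.03),
        ])
        out = select_dmps(stats, mode="topN", top_n=2)
        assert list(out["cpg_id"]) == ["c2", "c3"]

    def test_planted_dmp_recovery(self):
        """Power check: delta=0.5 planted DMPs recovered with high recall
        and few false selections (median over 20 seeds)."""
        recalls, fdps = [], []
        for seed in range(20):
            beta, groups, truth = generate_beta_matrix(
                20, 20, 20, n_cpg=2000, n_planted_dmp=100, delta=0.5,
                seed=seed)
            tumors = [s for s, g in groups.items() if g == "tumor"]
            blood = [s for s, g in groups.items() if g == "blood"]
            stats = moderated_t_test(beta, tumors, blood)
            sel = set(select_dmps(stats, mode="threshold")["cpg_id"])
            recalls.append(len(sel & truth) / len(truth))
            fdps.append(len(sel - truth) / max(len(sel), 1))
        assert np.median(recalls) >= 0.90
        assert np.median(fdps) <= 0.05


def oracle_merge(positions, max_gap=250):
    """Transitive closure of the pairwise |pi-pj| < max_gap relation."""
    positions = sorted(positions)
    comps, current = [], [positions[0]]
    for p in positions[1:]:
        if any(abs(p - q) < max_gap for q in current):
            current.append(p)
        else:
            comps.append(current)
            current = [p]
    comps.append(current)
    return [(c[0] - 1, c[-1]) for c in comps]


class TestMergeDmrs:
    def dmps(self, positions, chrom="chrS"):
        return pd.DataFrame({
            "cpg_id": [f"cg{i}" for i in range(len(positions))],
            "chrom": chrom, "pos": positions,
        })

    def test_singleton_is_width_one(self):
        regions = merge_dmps_to_dmrs(self.dmps([100]))
        assert (regions[0].start, regions[0].end) == (99, 100)

    def test_gap_rule(self):
        regions = merge_dmps_to_dmrs(self.dmps([100, 300, 700]))
        spans = [(r.start, r.end) for r in regions]
        assert spans == [(99, 300), (699, 700)]

    def test_single_linkage_chains_through(self):
        regions = merge_dmps_to_dmrs(self.dmps([100, 340, 580]))
        assert len(regions) == 1
        assert regions[0].members == ("cg0", "cg1", "cg2")

    def test_chromosomes_never_merge(self):
        dmps = pd.DataFrame({"cpg_id": ["a", "b"],
                             "chrom": ["chr1", "chr2"], "pos": [100, 150]})
        assert len(merge_dmps_to_dmrs(dmps)) == 2

    @given(st.lists(st.integers(min_value=1, max_value=5000), min_size=1,
                    max_size=50, unique=True))
    @settings(max_examples=200, deadline=None)
    def test_equivalent_to_transitive_closure_oracle(self, positions):
        regions = merge_dmps_to_dmrs(self.dmps(sorted(positions)))
        got = [(r.start, r.end) for r in regions]
        assert got == oracle_merge(positions)
        # disjoint cover: every DMP in exactly one region
        members = [m for r in regions for m in r.members]
        assert len(members) == len(positions) == len(set(members))


def oracle_mcbs(pos, values, max_gap=100, min_r=0.95, min_cpgs=3):
    """Enumerate all maximal runs whose every adjacent pair qualifies."""
    n = len(pos)

    def link(i):
        a, b = values[i], values[i + 1]
        if pos[i + 1] - pos[i] > max_gap or a.std() == 0 or b.std() == 0:
            return False
        return np.corrcoef(a, b)[0, 1] >= min_r

    runs, start = [], 0
    for i in range(n - 1):
        if not link(i):
            runs.append((start, i))
            start = i + 1
    runs.append((start, n - 1))
    return [(pos[a] - 1, pos[b]) for a, b in runs if b - a + 1 >= min_cpgs]


class TestBuildMcbs:
    def test_gap_breaks_block(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0.5, 0.1, size=6)
        vals = np.stack([base + rng.normal(0, 0.001, 6) for _ in range(4)])
        df = beta_frame(vals, ["s1", "s2", "s3", "s4", "s5", "s6"],
                        pos=[1, 50, 120, 400])
        blocks = build_mcbs(df)
        assert len(blocks) == 1
        assert blocks[0].members == ("cg0000", "cg0001", "cg0002")

    def test_two_qualifying_sites_insufficient(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0.5, 0.1, size=5)
        vals = np.stack([base + rng.normal(0, 0.001, 5) for _ in range(2)])
        df = beta_frame(vals, ["s1", "s2", "s3", "s4", "s5"], pos=[1, 50])
        assert build_mcbs(df) == []

    def test_weak_correlation_breaks_chain(self):
        rng = np.random.default_rng(2)
        shared = rng.normal(0.5, 0.1, size=6)
        other = rng.normal(0.5, 0.1, size=6)
        vals = np.stack([
            shared + rng.normal(0, 0.001, 6),
            shared + rng.normal(0, 0.001, 6),
            other + rng.normal(0, 0.001, 6),   # decorrelated from site 2
            other + rng.normal(0, 0.001, 6),
        ])
        df = beta_frame(vals, [f"s{i}" for i in range(6)],
                        pos=[1, 50, 100, 150])
        assert build_mcbs(df) == []

    def test_zero_variance_site_breaks_chain(self):
        vals = np.array([[0.1, 0.2, 0.3, 0.4],
                         [0.5, 0.5, 0.5, 0.5],
                         [0.1, 0.2, 0.3, 0.4]]).astype(float)
        df = beta_frame(vals, ["s1", "s2", "s3", "s4"], pos=[1, 50, 100])
        assert build_mcbs(df) == []

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=100, deadline=None)
    def test_equivalent_to_maximal_run_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        pos = np.cumsum(rng.integers(10, 200, size=n)).tolist()
        # latent-factor clusters so some adjacent pairs correlate highly
        cluster = np.cumsum(rng.random(n) < 0.3)
        u = rng.normal(0, 1, size=(int(cluster.max()) + 1, 6))
        noise_sd = rng.choice([0.01, 0.3])
        vals = 0.5 + 0.1 * u[cluster] + rng.normal(0, noise_sd, size=(n, 6))
        df = beta_frame(vals, [f"s{i}" for i in range(6)], pos=pos)
        got = [(r.start, r.end) for r in build_mcbs(df)]
        assert got == oracle_mcbs(pos, vals)
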