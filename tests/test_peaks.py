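import itertools
import shutil
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from brainatlas import (
    GenomicInterval,
    TranscriptModel,
    annotate_feature,
    correlate_peak_gene,
    merge_consensus,
    overlap_chisq,
    peak_tss_distance,
    simulate_linked_signals,
    tmm_factors,
    tmm_log_intensity,
)


def _tx(tid, chrom, strand, exons):
    return TranscriptModel(tid, tid, chrom, strand, exons)


class TestMergeConsensus:
    def test_six_identical_sets(self):
        sets = {f"r{i}": [GenomicInterval("chr1", 100, 200)] for i in range(6)}
        out = merge_consensus(sets)
        assert len(out) == 1
        assert out[0].reproducibility == 6
        assert out[0].interval.name == "reproducible_6"

    def test_disjoint_peaks_stay_separate(self):
        sets = {
            "a": [GenomicInterval("chr1", 0, 100)],
            "b": [GenomicInterval("chr1", 200, 300)],
        }
        out = merge_consensus(sets)
        assert len(out) == 2
        assert all(c.reproducibility == 1 for c in out)

    def test_one_bp_overlap_chain(self):
        """A[0,100) B[99,200) merge transitively; C[250,300) stays apart."""
        sets = {
            "s1": [GenomicInterval("chr1", 0, 100)],
            "s2": [GenomicInterval("chr1", 99, 200)],
            "s3": [GenomicInterval("chr1", 250, 300)],
        }
        out = merge_consensus(sets)
        assert [(c.interval.start, c.interval.end) for c in out] == \
            [(0, 200), (250, 300)]
        assert out[0].presence == {"s1": True, "s2": True, "s3": False}
        assert out[1].reproducibility == 1

    def test_book_ended_intervals_do_not_merge(self):
        # [0,100) and [100,200) share no base
        sets = {"a": [GenomicInterval("chr1", 0, 100),
                      GenomicInterval("chr1", 100, 200)]}
        assert len(merge_consensus(sets)) == 2

    def test_order_independence_and_idempotence(self):
        rng = np.random.default_rng(0)
        sets = {}
        for i in range(4):
            starts = np.sort(rng.integers(0, 5000, size=12))
            sets[f"set{i}"] = [
                GenomicInterval("chr1", int(s), int(s + rng.integers(50, 400)))
                for s in starts
            ]
        ref = merge_consensus(sets)
        for perm in itertools.permutations(sets):
            out = merge_consensus({k: sets[k] for k in perm})
            assert [
                (c.interval.chrom, c.interval.start, c.interval.end,
                 tuple(sorted(c.presence.items())))
                for c in out
            ] == [
                (c.interval.chrom, c.interval.start, c.interval.end,
                 tuple(sorted(c.presence.items())))
                for c in ref
            ]
        # merging the merged set changes nothing
        again = merge_consensus({"m": [c.interval for c in ref]})
        assert [(c.interval.start, c.interval.end) for c in again] == \
            [(c.interval.start, c.interval.end) for c in ref]

    def test_matches_brute_force_transitive_closure(self):
        """Consensus equals an independent union-find over all intervals."""
        rng = np.random.default_rng(7)
        intervals = [
            (int(s), int(s + rng.integers(10, 120)))
            for s in rng.integers(0, 2000, size=30)
        ]
        sets = {"x": [GenomicInterval("chr1", s, e) for s, e in intervals]}
        out = merge_consensus(sets)

        parent = list(range(len(intervals)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i, (s1, e1) in enumerate(intervals):
            for j, (s2, e2) in enumerate(intervals):
                if s1 < e2 and s2 < e1:
                    parent[find(i)] = find(j)
        groups = {}
        for i, (s, e) in enumerate(intervals):
            g = groups.setdefault(find(i), [s, e])
            g[0], g[1] = min(g[0], s), max(g[1], e)
        expected = sorted((s, e) for s, e in groups.values())
        assert [(c.interval.start, c.interval.end) for c in out] == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_consensus({})


class TestTmm:
    def test_identical_columns_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.negative_binomial(5, 0.05, size=200)
        X = pd.DataFrame({"a": col, "b": col, "c": col})
        np.testing.assert_allclose(tmm_factors(X), 1.0, atol=1e-12)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        rng = np.random.default_rng(2)
        col = rng.negative_binomial(5, 0.05, size=300) + 1
        X = pd.DataFrame({"a": col, "b": 2 * col})
        f = tmm_factors(X)
        assert f["a"] / f["b"] == pytest.approx(1.0, abs=1e-6)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.negative_binomial(3, 0.02, size=(150, 6)))
        f = tmm_factors(X)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-10)

    def test_hand_computed_toy_matrix(self):
        """Five peaks, two samples: factor equals the hand-computed
        precision-weighted trimmed mean of M-values."""
        X = pd.DataFrame({"obs": [10, 20, 30, 40, 500],
                          "ref": [10, 25, 28, 45, 400]})
        n_obs, n_ref = 600.0, 508.0
        M = np.log2((X["obs"] / n_obs) / (X["ref"] / n_ref))
        w = (n_obs - X["obs"]) / (n_obs * X["obs"]) \
            + (n_ref - X["ref"]) / (n_ref * X["ref"])
        # n=5: 30% M-trim drops rank 1 and 5; 5% A-trim drops none
        order = np.argsort(M.to_numpy())
        keep = order[1:-1]
        f_obs = 2.0 ** (np.sum(M.iloc[keep] / w.iloc[keep])
                        / np.sum(1.0 / w.iloc[keep]))
        expected = pd.Series([f_obs, 1.0], index=["obs", "ref"])
        expected /= np.exp(np.mean(np.log(expected)))
        got = tmm_factors(X)
        # reference choice may differ; compare the ratio, which is invariant
        assert got["obs"] / got["ref"] == pytest.approx(
            expected["obs"] / expected["ref"], rel=1e-6
        )

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    def test_matches_edger_oracle(self):
        """Factors agree with edgeR's calcNormFactors on a random matrix."""
        rng = np.random.default_rng(42)
        X = rng.negative_binomial(3, 0.02, size=(300, 5))
        X[:30, 0] *= 6  # asymmetric signal in sample 0
        df = pd.DataFrame(X, columns=[f"s{i}" for i in range(5)])
        ours = tmm_factors(df).to_numpy()
        with tempfile.TemporaryDirectory() as d:
            df.to_csv(f"{d}/m.tsv", sep="\t", index=False)
            res = subprocess.run(
                ["Rscript", "-e",
                 f'x<-as.matrix(read.delim("{d}/m.tsv"));'
                 'suppressMessages(library(edgeR));'
                 'cat(calcNormFactors(x,method="TMM"),sep="\\n")'],
                capture_output=True, text=True, timeout=120,
            )
        assert res.returncode == 0, res.stderr
        theirs = np.array([float(v) for v in res.stdout.split()])
        np.testing.assert_allclose(ours, theirs, rtol=1e-5)

    def test_all_zero_sample_rejected(self):
        X = pd.DataFrame({"a": [1, 2, 3], "b": [0, 0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(X)

    def test_log_intensity_shape_and_monotonicity(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.negative_binomial(4, 0.05, size=(50, 4)))
        out = tmm_log_intensity(X)
        assert out.shape == X.shape
        col = X.iloc[:, 0].to_numpy()
        res = out.iloc[:, 0].to_numpy()
        order = np.argsort(col)
        assert (np.diff(res[order]) >= -1e-12).all()


class TestLinking:
    def _coords_models(self, peak_ids, gene_ids, chrom="chr1"):
        coords = {
            p: GenomicInterval(chrom, 1000 * i + 100, 1000 * i + 300, ".", p)
            for i, p in enumerate(peak_ids)
        }
        genes = {
            g: _tx(g, chrom, "+",
                   [(1000 * i + 500, 1000 * i + 700)])
            for i, g in enumerate(gene_ids)
        }
        return coords, genes

    def test_identical_profiles_linked(self):
        rng = np.random.default_rng(5)
        prof = rng.normal(size=12)
        peaks = pd.DataFrame([prof], index=["p0"])
        expr = pd.DataFrame([prof, rng.normal(size=12)], index=["g0", "g1"])
        coords, genes = self._coords_models(["p0"], ["g0", "g1"])
        links, table = correlate_peak_gene(peaks, expr, coords, genes)
        assert {(l.peak_id, l.gene_id) for l in links} == {("p0", "g0")}
        assert links[0].r == pytest.approx(1.0)

    def test_cross_chromosome_pairs_not_tested(self):
        rng = np.random.default_rng(6)
        prof = rng.normal(size=10)
        peaks = pd.DataFrame([prof], index=["p0"])
        expr = pd.DataFrame([prof], index=["g0"])
        coords = {"p0": GenomicInterval("chr1", 0, 100, ".", "p0")}
        genes = {"g0": _tx("g0", "chr2", "+", [(500, 700)])}
        links, table = correlate_peak_gene(peaks, expr, coords, genes)
        assert links == [] and len(table) == 0

    def test_bh_adjustment_monotone(self):
        peaks, expr, _ = simulate_linked_signals(40, 20, 0.5, seed=7)
        coords, genes = self._coords_models(list(peaks.index),
                                            list(expr.index))
        _, table = correlate_peak_gene(peaks, expr, coords, genes)
        t = table.sort_values("p")
        assert (np.diff(t["fdr"].to_numpy()) >= -1e-12).all()
        # BH equals the statsmodels reference on the same p-values
        from statsmodels.stats.multitest import multipletests
        np.testing.assert_allclose(
            t["fdr"], multipletests(t["p"], method="fdr_bh")[1], atol=1e-12
        )

    def test_sample_mismatch_rejected(self):
        peaks = pd.DataFrame(np.zeros((1, 4)), columns=list("abcd"))
        expr = pd.DataFrame(np.zeros((1, 4)), columns=list("abce"))
        with pytest.raises(ValueError):
            correlate_peak_gene(peaks, expr, {}, {})


class TestTssDistance:
    def test_tss_inside_peak(self):
        peak = GenomicInterval("chr1", 100, 200)
        gene = _tx("g", "chr1", "+", [(150, 400)])
        assert peak_tss_distance(peak, gene) == 0

    def test_right_flank_uses_end_minus_one(self):
        peak = GenomicInterval("chr1", 100, 200)
        gene = _tx("g", "chr1", "+", [(250, 400)])
        assert peak_tss_distance(peak, gene) == 51  # 250 - 199

    def test_minus_strand_tss_is_end_minus_one(self):
        peak = GenomicInterval("chr1", 500, 600)
        gene = _tx("g", "chr1", "-", [(100, 400)])  # TSS at 399
        assert peak_tss_distance(peak, gene) == 101  # 500 - 399

    def test_symmetric_flanks_equidistant(self):
        gene = _tx("g", "chr1", "+", [(1000, 1200)])
        left = GenomicInterval("chr1", 800, 900)   # right edge 899
        right = GenomicInterval("chr1", 1101, 1201)
        assert peak_tss_distance(left, gene) == 1000 - 899
        assert peak_tss_distance(right, gene) == 1101 - 1000

    def test_chromosome_mismatch_rejected(self):
        with pytest.raises(ValueError):
            peak_tss_distance(GenomicInterval("chr1", 0, 10),
                              _tx("g", "chr2", "+", [(100, 200)]))


class TestAnnotateFeature:
    @pytest.fixture()
    def gene_models(self):
        # gene spanning [5000,9000) with exons [5000,5500) and [8500,9000)
        return [_tx("g1", "chr1", "+", [(5000, 5500), (8500, 9000)])]

    def test_promoter_priority(self, gene_models):
        peak = GenomicInterval("chr1", 4500, 5100)  # spans the TSS
        assert annotate_feature(peak, gene_models) == "promoter"

    def test_exon(self, gene_models):
        peak = GenomicInterval("chr1", 8600, 8700)
        assert annotate_feature(peak, gene_models) == "exon"

    def test_intron(self, gene_models):
        peak = GenomicInterval("chr1", 7000, 7200)
        assert annotate_feature(peak, gene_models) == "intron"

    def test_distal_intergenic(self, gene_models):
        peak = GenomicInterval("chr1", 20_000, 20_500)
        assert annotate_feature(peak, gene_models) == "distal_intergenic"

    def test_promoter_window_flag(self, gene_models):
        peak = GenomicInterval("chr1", 3900, 4000)  # 1 kb misses, 2 kb hits
        assert annotate_feature(peak, gene_models) == "distal_intergenic"
        assert annotate_feature(peak, gene_models,
                                promoter_window=2000) == "promoter"


class TestChisq:
    def test_equal_proportions_zero(self):
        stat, p = overlap_chisq(10, 90, 10, 90)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_closed_form_value(self):
        stat, _ = overlap_chisq(10, 20, 20, 10)
        assert stat == pytest.approx(20.0 / 3.0, rel=1e-12)

    @given(
        st.tuples(
            st.integers(1, 200), st.integers(1, 200),
            st.integers(1, 200), st.integers(1, 200),
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_expected_count_oracle(self, cells):
        a, b, c, d = cells
        stat, p = overlap_chisq(a, b, c, d)
        obs = np.array([[a, b], [c, d]], float)
        n = obs.sum()
        exp = np.outer(obs.sum(1), obs.sum(0)) / n
        oracle = float(((obs - exp) ** 2 / exp).sum())
        assert stat == pytest.approx(oracle, rel=1e-10)
        assert p == pytest.approx(float(stats.chi2.sf(oracle, 1)), rel=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            overlap_chisq(0, 0, 5, 5)
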