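"""Pairwise co-expression: correlations, binning, decay, nulls, genotype,
mRNA."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import naive_pearson
from ernet import coexpression as cx
from ernet import simulate
from ernet.types import ExpressionMatrix, SampleDesign, StrandedTrack, TTRE


def small_matrix(rows: np.ndarray, ids=None) -> ExpressionMatrix:
    rows = np.asarray(rows, dtype=float)
    if rows.size and rows.min() < 0:
        rows = rows - rows.min()  # global shift leaves Pearson unchanged
    ids = ids or [f"t{i}" for i in range(rows.shape[0])]
    libs = [f"L{j}" for j in range(rows.shape[1])]
    design = SampleDesign(libraries=libs, individual_of={x: x for x in libs})
    return ExpressionMatrix(
        ttre_ids=ids, library_ids=libs,
        values_total=rows, values_plus=rows / 2, values_minus=rows / 2,
        design=design,
    )


class TestPairwiseCorrelation:
    def _ttres(self, centers, chrom="chr1"):
        return [
            TTRE(f"t{i}", chrom, int(c) - 50, int(c) + 50)
            for i, c in enumerate(centers)
        ]

    def test_duplicated_row_r_one(self):
        base = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        m = small_matrix(np.stack([base, base]))
        pairs = cx.pairwise_correlation(m, self._ttres([1000, 3000]), 10_000)
        assert pairs["r"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelated_r_minus_one(self):
        base = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        m = small_matrix(np.stack([base, 10 - base]))
        pairs = cx.pairwise_correlation(m, self._ttres([1000, 3000]), 10_000)
        assert pairs["r"].iloc[0] == pytest.approx(-1.0)

    def test_hand_pearson(self):
        m = small_matrix(
            np.array([[1.0, 2, 3, 4], [2.0, 1, 4, 3]])
        )
        pairs = cx.pairwise_correlation(m, self._ttres([1000, 3000]), 10_000)
        assert pairs["r"].iloc[0] == pytest.approx(0.6)

    def test_matches_naive_formula(self):
        rng = np.random.default_rng(0)
        m = small_matrix(rng.normal(size=(12, 30)))
        rows = m.values_total
        ttres = self._ttres(np.arange(12) * 1000 + 500)
        pairs = cx.pairwise_correlation(m, ttres, 100_000)
        assert len(pairs) == 12 * 11 / 2
        for rec in pairs.itertuples():
            assert rec.r == pytest.approx(
                naive_pearson(rows[rec.idx_a], rows[rec.idx_b]), abs=1e-12
            )

    def test_distance_cap_and_upstream_order(self):
        m = small_matrix(np.random.default_rng(1).normal(size=(3, 10)))
        ttres = self._ttres([1000, 3000, 9000])
        pairs = cx.pairwise_correlation(m, ttres, 7000)
        got = {(a, b) for a, b in zip(pairs["ttre_a"], pairs["ttre_b"])}
        # (t0, t2) at 8 kb exceeds the cap; a is always upstream of b
        assert got == {("t0", "t1"), ("t1", "t2")}

    def test_zero_variance_row_excluded(self):
        rows = np.vstack(
            [np.ones(10), np.random.default_rng(2).normal(size=(1, 10))]
        )
        m = small_matrix(rows)
        pairs = cx.pairwise_correlation(m, self._ttres([1000, 2000]), 10_000)
        assert len(pairs) == 0


class TestBinning:
    def _pairs(self, n):
        rng = np.random.default_rng(4)
        return pd.DataFrame(
            {"distance": np.sort(rng.integers(1, 10**6, n)),
             "r": rng.normal(size=n)}
        )

    def test_equal_count_partial_final_kept(self):
        bins = cx.bin_by_distance(self._pairs(2500), pairs_per_bin=1000)
        assert [len(b) for b in bins] == [1000, 1000, 500]

    def test_equal_count_small_final_dropped(self):
        bins = cx.bin_by_distance(self._pairs(1050), pairs_per_bin=1000)
        assert [len(b) for b in bins] == [1000]

    def test_partition_is_exact(self):
        pairs = self._pairs(3700)
        bins = cx.bin_by_distance(pairs, pairs_per_bin=1000)
        seen = np.concatenate(bins)
        assert len(seen) == len(set(seen.tolist()))
        assert len(seen) == 3700  # 700 = 70% of a bin, kept

    def test_fixed_edges_all_below_1kb(self):
        pairs = pd.DataFrame({"distance": [100.0, 900.0], "r": [0.1, 0.2]})
        bins = cx.bin_by_distance(pairs, mode="fixed_edges")
        assert len(bins) == 1 and len(bins[0]) == 2


class TestDecayCurve:
    def test_upper5_is_50th_highest_of_1000(self):
        vals = np.arange(1, 1001, dtype=float)
        assert cx.bin_stat(vals, "upper5") == 951.0

    def test_constant_bin_every_percentile_equal(self):
        vals = np.full(400, 3.14)
        for spec in ("upper5", "median", "p95_low"):
            assert cx.bin_stat(vals, spec) == pytest.approx(3.14)

    def test_percentiles_are_ordered(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            vals = rng.normal(size=int(rng.integers(20, 500)))
            assert (
                cx.bin_stat(vals, "upper5")
                >= cx.bin_stat(vals, "median")
                >= cx.bin_stat(vals, "p95_low")
            )

    def test_auc_is_unit_bin_width_sum(self):
        pairs = pd.DataFrame(
            {"distance": np.arange(2000, dtype=float), "r": np.ones(2000)}
        )
        bins = cx.bin_by_distance(pairs, pairs_per_bin=1000)
        curve = cx.decay_curve(pairs, bins, "median")
        assert curve.auc == pytest.approx(2.0)


class TestBackgroundNull:
    def test_independent_rows_match_fisher_sd(self, corr_cohort):
        null = cx.background_null(
            corr_cohort["matrix"], corr_cohort["ttres"],
            n_draws=100_000, source="interchromosomal", seed=1,
        )
        n_ind = len(corr_cohort["design"].individuals)
        assert null.sd == pytest.approx(1 / np.sqrt(n_ind - 1), rel=0.10)

    def test_beyond_1mb_source(self, corr_cohort):
        null = cx.background_null(
            corr_cohort["matrix"], corr_cohort["ttres"],
            n_draws=20_000, source="beyond-1Mb", seed=2,
        )
        assert null.sd > 0

    def test_single_chromosome_interchromosomal_errors(self):
        rows = np.random.default_rng(3).normal(size=(4, 20)) + 10
        m = small_matrix(np.abs(rows))
        ttres = [
            TTRE(f"t{i}", "chr1", 1000 * i + 100, 1000 * i + 200)
            for i in range(4)
        ]
        with pytest.raises(ValueError, match="chromosome"):
            cx.background_null(m, ttres, n_draws=100)


class TestCorrelationFdr:
    def test_r_zero_never_significant(self):
        null = cx.CorrelationNull(sd=0.12, source="interchromosomal",
                                  qq_statistic=0.0, n_draws=10)
        pairs = pd.DataFrame({"distance": [1.0], "r": [0.0]})
        out, _ = cx.correlation_fdr(pairs, null)
        assert out["r_p"].iloc[0] == pytest.approx(1.0)

    def test_three_sigma_tail(self):
        null = cx.CorrelationNull(sd=0.1, source="interchromosomal",
                                  qq_statistic=0.0, n_draws=10)
        pairs = pd.DataFrame({"distance": [1.0], "r": [0.3]})
        out, _ = cx.correlation_fdr(pairs, null)
        assert out["r_p"].iloc[0] == pytest.approx(2 * stats.norm.sf(3), rel=1e-9)

    def test_significant_fraction_decays_with_distance(
        self, corr_cohort, pair_table
    ):
        null = cx.background_null(
            corr_cohort["matrix"], corr_cohort["ttres"],
            n_draws=50_000, seed=3,
        )
        bins = cx.bin_by_distance(pair_table, pairs_per_bin=1000)
        _, frac = cx.correlation_fdr(pair_table, null, bins)
        # downward trend over the range where the planted decay is active
        # (beyond ~2 correlation lengths the fraction is flat noise)
        k = min(40, len(frac))
        rho = stats.spearmanr(np.arange(k), frac[:k]).statistic
        assert rho < -0.5
        assert frac[0] > frac[-1]


class TestGenotypeIndependence:
    def test_maf_counting(self):
        g = np.array([[0, 0, 1, 2]])
        assert cx.snp_maf(g)[0] == pytest.approx(0.375)

    def _setup(self, genotype_b=None):
        ttres = [TTRE("a", "chr1", 1000, 1100), TTRE("b", "chr1", 5000, 5100)]
        rng = np.random.default_rng(0)
        ga = rng.binomial(2, 0.4, 40)
        gb = ga if genotype_b is None else genotype_b
        G = np.stack([ga, gb])
        chroms = np.array(["chr1", "chr1"], dtype=object)
        pos = np.array([1050, 5050])
        pairs = pd.DataFrame(
            {"ttre_a": ["a"], "ttre_b": ["b"], "chrom": ["chr1"],
             "distance": [4000.0], "r": [0.5]}
        )
        return pairs, ttres, G, chroms, pos

    def test_identical_genotypes_excluded_from_strict_set(self):
        pairs, ttres, G, chroms, pos = self._setup()
        out, _ = cx.genotype_independence(pairs, ttres, G, chroms, pos)
        assert out["genotype_r"].iloc[0] == pytest.approx(1.0)
        assert not out["strict"].iloc[0]
        assert not out["retained"].iloc[0]

    def test_no_in_span_snp_is_independent(self):
        pairs, ttres, G, chroms, pos = self._setup()
        pos = np.array([1050, 900_000])  # second SNP outside span b
        out, _ = cx.genotype_independence(pairs, ttres, G, chroms, pos)
        assert np.isnan(out["genotype_r"].iloc[0])
        assert out["retained"].iloc[0] and out["strict"].iloc[0]

    def test_low_maf_snp_ignored(self):
        pairs, ttres, G, chroms, pos = self._setup()
        G = np.stack([G[0], np.zeros(40, dtype=int)])  # MAF 0 at tTRE b
        out, _ = cx.genotype_independence(pairs, ttres, G, chroms, pos)
        assert out["retained"].iloc[0]

    def test_linked_pairs_have_higher_r_than_retained(self):
        sizes = {"chr1": 10_000_000}
        ttres = simulate.simulate_ttre_landscape(300, sizes, 0.3, seed=21)
        truth = simulate.SyntheticTruth(ttres=ttres, chrom_sizes=sizes)
        truth.variable_ids = {t.id for t in ttres}
        design = simulate.make_design()
        simulate.simulate_genotypes(
            truth, design.individuals, 300, linked_fraction=0.2, seed=22
        )
        matrix = simulate.simulate_expression(truth, design, seed=23)
        pairs = cx.pairwise_correlation(matrix, ttres, 5_000_000)
        out, report = cx.genotype_independence(
            pairs, ttres, truth.genotypes, truth.snp_chroms,
            truth.snp_positions,
        )
        removed = ~out["retained"]
        assert report["n_removed"].iloc[0] > 0
        assert (
            np.abs(out.loc[removed, "r"]).mean()
            > np.abs(out.loc[~removed, "r"]).mean()
        )


class TestMrna:
    def _procap(self, counts):
        track = StrandedTrack("merged", {"chr1": 1_000_000})
        for (strand, pos), c in counts.items():
            track.add_counts("chr1", strand, np.array([pos]), np.array([c]))
        return track

    def test_promoter_proximity_beats_signal(self):
        # TSS at 1000 near a promoter tTRE wins over a stronger distal TSS
        ann = pd.DataFrame(
            {"gene": ["g"] * 2, "chrom": ["chr1"] * 2,
             "strand": ["+"] * 2, "tss": [1000, 5000]}
        )
        prom = [TTRE("p", "chr1", 900, 1100, class_label="promoter")]
        procap = self._procap({("+", 1000): 50.0, ("+", 5000): 90.0})
        sel = cx.mrna_tss_select(ann, prom, procap)
        assert sel["tss"].tolist() == [1000]

    def test_signal_tie_takes_leftmost(self):
        ann = pd.DataFrame(
            {"gene": ["g"] * 2, "chrom": ["chr1"] * 2,
             "strand": ["+"] * 2, "tss": [1000, 1040]}
        )
        prom = [TTRE("p", "chr1", 900, 1100, class_label="promoter")]
        procap = self._procap({("+", 500): 1.0})  # no signal at either TSS
        sel = cx.mrna_tss_select(ann, prom, procap)
        assert sel["tss"].tolist() == [1000]

    def test_gene_without_candidate_dropped(self):
        ann = pd.DataFrame(
            {"gene": ["g"], "chrom": ["chr1"], "strand": ["+"],
             "tss": [500_000]}
        )
        prom = [TTRE("p", "chr1", 900, 1100, class_label="promoter")]
        sel = cx.mrna_tss_select(ann, prom, self._procap({("+", 1000): 5.0}))
        assert len(sel) == 0

    def test_mrna_correlation_sign_and_filters(self):
        libs = [f"L{j}" for j in range(6)]
        design = SampleDesign(libraries=libs, individual_of={x: x for x in libs})
        rng = np.random.default_rng(6)
        row = rng.gamma(4, 2, 6)
        matrix = ExpressionMatrix(
            ttre_ids=["t"], library_ids=libs,
            values_total=row[None, :], values_plus=row[None, :] / 2,
            values_minus=row[None, :] / 2, design=design,
        )
        # plus-strand gene 10 kb downstream of the tTRE
        ttre = TTRE("t", "chr1", 89_950, 90_050)
        tss_map = pd.DataFrame(
            {"gene": ["g1", "g2"], "chrom": ["chr1", "chr1"],
             "strand": ["+", "+"], "tss": [100_000, 100_000]}
        )
        mrna = pd.DataFrame(
            [row, np.full(6, 0.5)], index=["g1", "g2"], columns=libs
        )
        out = cx.ttre_mrna_correlation(matrix, mrna, tss_map, [ttre])
        assert out["gene"].tolist() == ["g1"]  # g2 under 1 RPKM mean
        assert out["signed_distance"].iloc[0] == pytest.approx(-10_000)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_minus_strand_gene_sign_flips(self):
        libs = [f"L{j}" for j in range(5)]
        design = SampleDesign(libraries=libs, individual_of={x: x for x in libs})
        row = np.array([1.0, 5.0, 2.0, 7.0, 3.0])
        matrix = ExpressionMatrix(
            ttre_ids=["t"], library_ids=libs,
            values_total=row[None, :], values_plus=row[None, :] / 2,
            values_minus=row[None, :] / 2, design=design,
        )
        ttre = TTRE("t", "chr1", 109_950, 110_050)
        tss_map = pd.DataFrame(
            {"gene": ["g"], "chrom": ["chr1"], "strand": ["-"],
             "tss": [100_000]}
        )
        mrna = pd.DataFrame([row], index=["g"], columns=libs)
        out = cx.ttre_mrna_correlation(matrix, mrna, tss_map, [ttre])
        # tTRE downstream of the TSS is upstream in minus-gene orientation
        assert out["signed_distance"].iloc[0] == pytest.approx(-10_000)


class TestDecayRecovery:
    def test_binned_median_matches_planted_rho(self, corr_cohort, pair_table):
        truth = corr_cohort["truth"]
        bins = cx.bin_by_distance(pair_table, pairs_per_bin=1000)
        curve = cx.decay_curve(pair_table, bins, "median")
        d = pair_table["distance"].to_numpy()
        errs = [
            abs(stat - np.median(truth.rho(d[idx])))
            for idx, stat in zip(bins, curve.stat)
        ]
        assert np.mean(errs) < 0.05
        # medians decrease with distance where the planted decay is active
        k = min(40, len(curve.stat))
        rho = stats.spearmanr(np.arange(k), curve.stat[:k]).statistic
        assert rho < -0.9
        assert curve.stat[0] > curve.stat[-1]
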