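"""ΔAUC machinery: pair annotation, grouping, permutation null, clustering."""
import numpy as np
import pandas as pd
import pytest

from conftest import brute_delta_auc, brute_pair_annotation
from ernet import tf_dependency as tfd
from ernet.types import GenomicInterval, TFSiteSet, TTRE


def make_pair_frame(ttres):
    rows = []
    for i, a in enumerate(ttres):
        for b in ttres[i + 1 :]:
            if a.chrom == b.chrom:
                rows.append(
                    {"ttre_a": a.id, "ttre_b": b.id, "chrom": a.chrom,
                     "distance": abs(b.center - a.center)}
                )
    return pd.DataFrame(rows)


class TestAnnotatePairs:
    def _two_ttres(self):
        # spans [100, 400) and [5000, 5300)
        return [TTRE("a", "chr1", 100, 399), TTRE("b", "chr1", 5000, 5299)]

    def test_hand_example_intersection_and_occupancy(self):
        ttres = self._two_ttres()
        sites = TFSiteSet(
            "TF",
            [
                GenomicInterval("chr1", 1000, 1200),
                GenomicInterval("chr1", 2000, 2100),
                GenomicInterval("chr1", 6000, 6100),
            ],
        )
        out = tfd.annotate_pairs(make_pair_frame(ttres), ttres, sites)
        assert out["n_intersecting"].iloc[0] == 2
        assert not out["occupied"].iloc[0]

    def test_site_on_span_is_occupancy_not_intersection(self):
        ttres = self._two_ttres()
        sites = TFSiteSet("TF", [GenomicInterval("chr1", 150, 250)])
        out = tfd.annotate_pairs(make_pair_frame(ttres), ttres, sites)
        assert out["occupied"].iloc[0]
        assert out["n_intersecting"].iloc[0] == 0

    def test_site_abutting_span_end_counts_as_intersecting(self):
        ttres = self._two_ttres()
        # span_a is half-open [100, 400); a site starting at 400 abuts it
        sites = TFSiteSet("TF", [GenomicInterval("chr1", 400, 500)])
        out = tfd.annotate_pairs(make_pair_frame(ttres), ttres, sites)
        assert out["n_intersecting"].iloc[0] == 1
        assert not out["occupied"].iloc[0]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n_t = int(rng.integers(3, 10))
            starts = np.sort(rng.choice(50_000, n_t, replace=False)) * 10
            ttres = [
                TTRE(f"t{i}", "chr1", int(s), int(s) + int(rng.integers(50, 251)))
                for i, s in enumerate(starts)
            ]
            n_s = int(rng.integers(0, 40))
            s_starts = rng.integers(0, 500_000, n_s)
            s_lens = rng.integers(10, 2000, n_s)
            sites = TFSiteSet(
                "TF",
                [
                    GenomicInterval("chr1", int(s), int(s + l))
                    for s, l in zip(s_starts, s_lens)
                ],
            )
            pairs = make_pair_frame(ttres)
            out = tfd.annotate_pairs(pairs, ttres, sites)
            span = {t.id: (t.span.start, t.span.end) for t in ttres}
            raw = [(s.start, s.end) for s in sites.sites]
            for rec in out.itertuples():
                n_int, occ = brute_pair_annotation(
                    span[rec.ttre_a], span[rec.ttre_b], raw
                )
                assert rec.n_intersecting == n_int
                assert rec.occupied == occ

    def test_site_never_both_intersecting_and_occupying(self):
        ttres = self._two_ttres()
        # straddles span_a's downstream edge
        sites = TFSiteSet("TF", [GenomicInterval("chr1", 390, 450)])
        out = tfd.annotate_pairs(make_pair_frame(ttres), ttres, sites)
        assert out["occupied"].iloc[0]
        assert out["n_intersecting"].iloc[0] == 0


class TestDeltaAuc:
    def test_two_bin_hand_case(self):
        # low group percentiles (0.5, 0.3); high group (0.2, 0.1)
        d = np.concatenate([np.arange(4), np.arange(4)]).astype(float)
        v = np.array([0.5, 0.5, 0.3, 0.3, 0.2, 0.2, 0.1, 0.1])
        lab = np.array([False] * 4 + [True] * 4)
        d = np.array([0, 0, 1, 1, 0, 0, 1, 1], dtype=float)
        _, _, delta = tfd.delta_auc(
            d, v, lab, auc_range=(0, 10), percentile_spec="median",
            pairs_per_bin=2, min_bins=1,
        )
        assert delta == pytest.approx(0.8 - 0.3)

    def test_identical_values_give_zero(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0, 1000, 200)
        v = np.full(200, 0.4)
        lab = rng.random(200) < 0.5
        _, _, delta = tfd.delta_auc(
            d, v, lab, auc_range=(0, 1000), pairs_per_bin=20, min_bins=2
        )
        assert delta == 0.0

    def test_small_group_error_names_group(self):
        d = np.arange(100, dtype=float)
        v = np.zeros(100)
        lab = np.zeros(100, dtype=bool)
        lab[:3] = True
        with pytest.raises(ValueError, match="high/with-TF"):
            tfd.delta_auc(d, v, lab, auc_range=(0, 100), pairs_per_bin=10)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            n = int(rng.integers(200, 600))
            d = rng.uniform(0, 10_000, n)
            v = rng.normal(size=n)
            lab = rng.random(n) < 0.5
            for spec in ("upper5", "median"):
                got = tfd.delta_auc(
                    d, v, lab, auc_range=(0, 8000),
                    percentile_spec=spec, pairs_per_bin=25, min_bins=1,
                )[2]
                want = brute_delta_auc(d, v, lab, 0, 8000, 25, spec)
                assert got == pytest.approx(want, abs=1e-12)

    def test_exchangeable_labels_give_small_delta(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0, 1000, 2000)
        v = rng.normal(size=2000)
        deltas = [
            tfd.delta_auc(
                d, v, rng.random(2000) < 0.5, auc_range=(0, 1000),
                pairs_per_bin=100, min_bins=2,
            )[2]
            for _ in range(50)
        ]
        # symmetric around ~0 under exchangeability
        assert abs(np.mean(deltas)) < 3 * np.std(deltas) / np.sqrt(50) + 0.05


class TestShuffleSites:
    def _sites(self):
        rng = np.random.default_rng(4)
        return TFSiteSet(
            "TF",
            [
                GenomicInterval(
                    f"chr{int(rng.integers(1, 3))}",
                    int(s := rng.integers(0, 90_000)),
                    int(s + rng.integers(50, 500)),
                )
                for _ in range(100)
            ],
        )

    def test_lengths_and_chromosomes_preserved(self):
        sites = self._sites()
        sizes = {"chr1": 100_000, "chr2": 100_000}
        shuffled = tfd.shuffle_sites(sites, sizes, seed=7)
        assert sorted(shuffled.lengths()) == sorted(sites.lengths())
        for chrom in sizes:
            assert sum(s.chrom == chrom for s in shuffled.sites) == sum(
                s.chrom == chrom for s in sites.sites
            )

    def test_deterministic_per_seed(self):
        sites = self._sites()
        sizes = {"chr1": 100_000, "chr2": 100_000}
        a = tfd.shuffle_sites(sites, sizes, seed=1)
        b = tfd.shuffle_sites(sites, sizes, seed=1)
        c = tfd.shuffle_sites(sites, sizes, seed=2)
        assert [(s.chrom, s.start) for s in a.sites] == [
            (s.chrom, s.start) for s in b.sites
        ]
        assert [(s.chrom, s.start) for s in a.sites] != [
            (s.chrom, s.start) for s in c.sites
        ]

    def test_oversized_site_errors(self):
        sites = TFSiteSet("TF", [GenomicInterval("chr1", 0, 500)])
        with pytest.raises(ValueError, match="exceeds"):
            tfd.shuffle_sites(sites, {"chr1": 100}, seed=0)


class TestBackground:
    def test_interpolation_exact_at_grid_points(self):
        bg = tfd.PermutationBackground(
            grid=np.array([1000.0, 4000.0, 16000.0]),
            means=np.array([1.0, 2.0, 3.0]),
            sds=np.array([0.5, 0.4, 0.3]),
            normality_p=np.ones(3),
            mode="intersection",
            n_perm=10,
        )
        assert bg.mean_at(4000) == 2.0
        assert bg.sd_at(16000) == 0.3
        # log-linear midpoint between 1000 and 4000
        assert bg.mean_at(2000) == pytest.approx(1.5)
        assert not bg.covers(500)


class TestSignificance:
    def test_worked_example_z(self):
        bg = tfd.PermutationBackground(
            grid=np.array([40_000.0]),
            means=np.array([6.41]),
            sds=np.array([2.56]),
            normality_p=np.ones(1),
            mode="intersection",
            n_perm=1000,
        )
        res = tfd.tf_significance("CTCF", "intersection", 27.8, 41_465, bg)
        assert res.z == pytest.approx((27.8 - 6.41) / 2.56)
        assert res.z == pytest.approx(8.34, rel=0.003)
        assert res.effect == pytest.approx(-27.8)

    def test_delta_equal_to_mean_gives_zero(self):
        bg = tfd.PermutationBackground(
            grid=np.array([100.0]), means=np.array([1.5]),
            sds=np.array([0.5]), normality_p=np.ones(1),
            mode="occupancy", n_perm=10,
        )
        res = tfd.tf_significance("X", "occupancy", 1.5, 100, bg)
        assert res.z == 0.0 and res.p == 1.0

    def test_large_z_tail_arithmetic(self):
        bg = tfd.PermutationBackground(
            grid=np.array([100.0]), means=np.array([0.0]),
            sds=np.array([1.0]), normality_p=np.ones(1),
            mode="intersection", n_perm=10,
        )
        res = tfd.tf_significance("X", "intersection", 8.345, 100, bg)
        assert res.p == pytest.approx(7.2e-17, rel=0.05)


class TestClustering:
    def test_identical_tfs_merge_first(self):
        df = pd.DataFrame(
            {
                "tf_name": ["A", "B", "C", "A", "B", "C"],
                "mode": ["intersection"] * 3 + ["occupancy"] * 3,
                "delta_auc": [2.0, 2.0, -5.0] * 2,
                "q": [0.01, 0.01, 0.001] * 2,
            }
        )
        order, link = tfd.cluster_tfs(df)
        assert link[0, 2] == pytest.approx(0.0)  # A and B at distance 0
        # A and B adjacent in leaf order
        ia, ib = order.index("A"), order.index("B")
        assert abs(ia - ib) == 1

    def test_role_groups_separate_in_clustering(self):
        """A panel of 3 insulators, 3 activators, 3 bivalents and 3 null
        TFs clusters by role: the separable roles (insulator, activator,
        null) recover their groups exactly, and bivalent TFs — whose
        activating arm is power-limited at this scale — never land among
        activators or nulls."""
        from scipy import stats as st
        from scipy.cluster import hierarchy
        from sklearn.metrics import adjusted_rand_score

        from conftest import naive_pearson  # noqa: F401  (env check)
        from ernet import simulate
        from ernet.coexpression import pairwise_correlation

        sizes = {f"chr{i + 1}": 5_000_000 for i in range(4)}
        ttres = simulate.simulate_ttre_landscape(800, sizes, 0.3, seed=701)
        grids = {
            "intersection": (300, 600, 1200),
            "occupancy": (1200, 2400, 4800),
        }
        mode_kw = {
            "intersection": dict(
                auc_range=(0, 200_000), pairs_per_bin=150, min_bins=3
            ),
            "occupancy": dict(
                auc_range=(0, 200_000), pairs_per_bin=60, min_bins=2,
                percentile_spec="median",
            ),
        }
        panel = [
            (f"{role[:3].upper()}{k}", role, n)
            for role, n in (
                ("insulator", 1200), ("activator", 2400),
                ("bivalent", 1200), ("null", 1000),
            )
            for k in range(3)
        ]
        rows = []
        design = simulate.make_design()
        for j, (name, role, n) in enumerate(panel):
            seed = 2000 + 31 * j
            truth = simulate.SyntheticTruth(ttres=ttres, chrom_sizes=sizes)
            truth.variable_ids = {t.id for t in ttres}
            siteset = simulate.simulate_tf_sites(
                truth, name, role, n, seed=seed
            )
            matrix = simulate.simulate_expression(truth, design, seed=seed + 5)
            pairs = pairwise_correlation(matrix, ttres, 200_000)
            annotator = tfd.PairAnnotator(pairs, ttres)
            d = pairs["distance"].to_numpy()
            v = pairs["r"].to_numpy()
            n_int, occ = annotator.annotate(siteset.by_chrom())
            for mode in ("intersection", "occupancy"):
                try:
                    lab = tfd.labels_for_mode(n_int, occ, mode)
                    _, _, delta = tfd.delta_auc(d, v, lab, **mode_kw[mode])
                    bg = tfd.permutation_background(
                        annotator, d, v, sizes, siteset.lengths(),
                        mode=mode, site_grid=grids[mode], n_perm=30,
                        seed=seed + 7, **mode_kw[mode],
                    )
                    rows.append(
                        tfd.tf_significance(name, mode, delta, n, bg).__dict__
                    )
                except ValueError:
                    continue  # mode not computable for this TF; imputed 0
        df = pd.DataFrame(rows)
        for mode in df["mode"].unique():
            m = df["mode"] == mode
            df.loc[m, "q"] = st.false_discovery_control(
                df.loc[m, "p"].to_numpy(), method="bh"
            )
        order, link = tfd.cluster_tfs(df)
        tfs = sorted(df["tf_name"].unique())
        role_of = {name: role for name, role, _ in panel}
        labels = hierarchy.fcluster(link, t=4, criterion="maxclust")
        by_tf = dict(zip(tfs, labels))
        # separable roles recover their groups exactly
        sep = [t for t in tfs if role_of[t] != "bivalent"]
        ari = adjusted_rand_score(
            [role_of[t] for t in sep], [by_tf[t] for t in sep]
        )
        assert ari >= 0.8
        # bivalents share the damping signature: never grouped with
        # activators or nulls
        act_null_clusters = {
            by_tf[t] for t in tfs if role_of[t] in ("activator", "null")
        }
        for t in tfs:
            if role_of[t] == "bivalent":
                assert by_tf[t] not in act_null_clusters

    def test_too_few_tfs_errors(self):
        df = pd.DataFrame(
            {"tf_name": ["A", "B"], "mode": ["intersection"] * 2,
             "delta_auc": [1.0, 2.0], "q": [0.1, 0.2]}
        )
        with pytest.raises(ValueError, match=">= 3"):
            tfd.cluster_tfs(df)
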