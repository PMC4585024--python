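import numpy as np
import pandas as pd
import pytest

from virasm import (
    association_analysis,
    bray_curtis,
    distance_to_ideal,
    hcluster,
    hellinger_distance,
    kruskal_wallis_bh,
    profile_matrix,
    spearman_matrix,
)
from virasm.comparison import bh_adjust, correlation_distance_matrix, hcluster_from_distances


class TestDistances:
    def test_bray_curtis_examples(self):
        assert bray_curtis([2, 2], [2, 2]) == 0.0
        assert bray_curtis([1, 0], [0, 1]) == 1.0  # disjoint supports
        assert bray_curtis([2, 2], [1, 3]) == pytest.approx(0.25)

    def test_hellinger_examples(self):
        assert hellinger_distance([3, 1], [3, 1]) == 0.0
        assert hellinger_distance([1, 0], [0, 1]) == pytest.approx(np.sqrt(2))

    def test_zero_column_leaves_bray_curtis_unchanged(self):
        assert bray_curtis([2, 2, 0], [1, 3, 0]) == bray_curtis([2, 2], [1, 3])

    @pytest.mark.parametrize("metric", [bray_curtis, hellinger_distance])
    def test_metric_axioms_on_random_profiles(self, metric):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.random(8)
            y = rng.random(8)
            assert metric(x, y) == pytest.approx(metric(y, x))
            assert metric(x, y) >= 0
            assert metric(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_refused(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])
        with pytest.raises(ValueError):
            hellinger_distance([0, 0], [1, 1])


class TestProfileMatrix:
    def test_missing_species_fill_zero(self):
        a = pd.DataFrame({"coverage": [1.0, 2.0]}, index=["g1", "g2"])
        b = pd.DataFrame({"coverage": [3.0]}, index=["g2"])
        m = profile_matrix({"a": a, "b": b})
        assert m.loc["b", "g1"] == 0.0
        assert list(m.columns) == ["g1", "g2"]


class TestHCluster:
    def test_two_leaves_single_node_full_support(self):
        profiles = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        res = hcluster(profiles, n_boot=20, seed=0)
        assert res.support[frozenset({"a", "b"})] == 1.0

    def test_separated_pair_joins_first_with_high_support(self):
        profiles = pd.DataFrame(
            {
                "g1": [10.0, 9.5, 0.1],
                "g2": [8.0, 8.5, 0.2],
                "g3": [5.0, 5.2, 9.0],
                "g4": [4.0, 4.1, 8.0],
            },
            index=["a", "b", "c"],
        )
        res = hcluster(profiles, n_boot=50, seed=1)
        assert frozenset({"a", "b"}) in res.support
        assert res.support[frozenset({"a", "b"})] > 0.9
        assert res.newick.endswith(";")

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(5)
        profiles = pd.DataFrame(rng.random((5, 12)), index=list("abcde"))
        r1 = hcluster(profiles, n_boot=30, seed=9)
        r2 = hcluster(profiles, n_boot=30, seed=9)
        assert r1.newick == r2.newick
        assert r1.support == r2.support

    def test_distance_matrix_entry_requires_symmetry(self):
        dm = pd.DataFrame([[0.0, 0.5], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            hcluster_from_distances(dm)

    def test_correlation_distance_matrix(self):
        stats = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0], "s2": [2.0, 4.0, 6.0], "s3": [1.0, 0.0, 5.0]},
            index=["a", "b", "c"],
        )
        d = correlation_distance_matrix(stats)
        assert np.allclose(np.diag(d), 0.0)
        assert (d.to_numpy() >= 0).all()
        assert np.allclose(d, d.T)


class TestKruskalWallisBH:
    def test_identical_groups_large_p(self):
        res = kruskal_wallis_bh({"cmp": [[1, 2, 3, 4], [1, 2, 3, 4]]})
        assert res.loc["cmp", "p"] > 0.9

    def test_bh_step_up_by_hand(self):
        # p=(0.01,0.02,0.03), m=3 -> q=(0.03,0.03,0.03)
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(7)
        p = rng.random(20)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_null_calibration_over_seeds(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            vals = rng.normal(size=12)
            groups = [vals[:4], vals[4:8], vals[8:]]
            ps.append(kruskal_wallis_bh({"c": groups}).loc["c", "p"])
        assert 0.2 < np.mean(np.array(ps) < 0.5) < 0.8  # roughly uniform

    def test_small_group_refused(self):
        with pytest.raises(ValueError):
            kruskal_wallis_bh({"c": [[1], [2, 3]]})


class TestSpearmanMatrix:
    def test_hand_computed_rho(self):
        # ranks (1,2,3) vs (2,1,3): 1 - 6*2/24 = 0.5
        df = pd.DataFrame({"a": [1, 2, 3], "b": [2, 1, 3], "c": [3, 2, 1]})
        res = spearman_matrix(df)
        row = res[(res.stat_a == "a") & (res.stat_b == "b")].iloc[0]
        assert row.rho == pytest.approx(0.5)

    def test_perfect_monotone_pairs(self):
        df = pd.DataFrame({"up": [1, 2, 3, 4], "down": [9, 7, 4, 1], "same": [2, 4, 8, 9]})
        res = spearman_matrix(df)
        updown = res[(res.stat_a == "up") & (res.stat_b == "down")].iloc[0]
        assert updown.rho == pytest.approx(-1.0)
        upsame = res[(res.stat_a == "up") & (res.stat_b == "same")].iloc[0]
        assert upsame.rho == pytest.approx(1.0)

    def test_constant_column_flagged_nan(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "flat": [5, 5, 5, 5]})
        res = spearman_matrix(df)
        row = res.iloc[0]
        assert np.isnan(row.rho) and not row.significant


class TestAssociationAnalysis:
    @staticmethod
    def _design(seed, n=30, p=5):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)]
        )
        return rng, X

    def test_planted_noiseless_signal_recovered_by_all_methods(self):
        rng, X = self._design(0)
        y = pd.Series(np.exp(X["x2"]))  # noiseless monotone function of x2
        res = association_analysis(X, y, seed=0)
        assert res.loc["x2", "spearman_selected"]
        assert res.loc["x2", "glm_selected"]
        assert res.loc["x2", "rf_selected"]
        assert res.loc["x2", "consensus"]

    def test_pure_noise_rarely_reaches_consensus(self):
        hits = 0
        total = 0
        for seed in range(5):
            rng, X = self._design(100 + seed)
            y = pd.Series(rng.normal(size=len(X)))
            res = association_analysis(X, y, seed=seed)
            hits += int(res["consensus"].sum())
            total += len(res)
        assert hits / total < 0.2

    def test_duplicated_predictors_get_identical_spearman(self):
        rng, X = self._design(3)
        X["x0_copy"] = X["x0"]
        y = pd.Series(rng.normal(size=len(X)))
        res = association_analysis(X, y, seed=3)
        assert res.loc["x0", "rho"] == pytest.approx(res.loc["x0_copy", "rho"])

    def test_top_rf_importance_finds_planted_signal(self):
        top_hits = 0
        for seed in range(10):
            rng, X = self._design(200 + seed)
            y = pd.Series(3 * X["x1"] ** 3 + 0.1 * rng.normal(size=len(X)))
            res = association_analysis(X, y, seed=seed)
            if res["rf_incmse"].idxmax() == "x1":
                top_hits += 1
        assert top_hits >= 9

    def test_too_few_rows_refused(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValueError):
            association_analysis(X, pd.Series(np.zeros(5)), seed=0)


class TestDistanceToIdeal:
    def test_ideal_to_itself_excluded_and_zero_profile_distance(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [3.0, 0.5]], index=["ideal", "same", "far"]
        )
        d, _ = distance_to_ideal(profiles, "ideal")
        assert "ideal" not in d.index
        assert d["same"] == pytest.approx(0.0)
        assert d["far"] > 0

    def test_missing_ideal_row_refused(self):
        profiles = pd.DataFrame([[1.0]], index=["a"])
        with pytest.raises(ValueError):
            distance_to_ideal(profiles, "nope")

    def test_fragmentation_distance_grows_with_split_rate(self):
        """At depths where the ideal assembly is near-complete (mean F ~ 1),
        heavier splitting moves the fragmentation profile monotonically
        away from the ideal."""
        from virasm import (
            build_ideal_assembly,
            degrade_assembly,
            generate_genomes,
            sample_abundances,
            simulate_paired_reads,
            species_spectra,
        )

        gs = generate_genomes(20, (2_000, 8_000), seed=11)
        prof = sample_abundances(20, "power_law", alpha=1.0, gis=[g.gi for g in gs])
        _, prov = simulate_paired_reads(gs, prof, 6_000, read_len=300,
                                        qc_loss=0.0, seed=11)
        ideal = build_ideal_assembly(prov, gs.lengths)
        ideal_f = species_spectra(ideal, gs.lengths)["fragmentation"]
        means = []
        for split in (0.0, 0.2, 0.8):
            ds = []
            for s in range(5):
                f = species_spectra(
                    degrade_assembly(ideal, split, 0, 0, seed=s), gs.lengths
                )["fragmentation"].reindex(ideal_f.index).fillna(0)
                ds.append(hellinger_distance(f.values, ideal_f.values))
            means.append(np.mean(ds))
        assert means[0] <= means[1] <= means[2]

    def test_group_comparison_runs(self):
        rng = np.random.default_rng(1)
        profiles = pd.DataFrame(
            rng.random((7, 10)) + 0.1, index=["ideal"] + [f"a{i}" for i in range(6)]
        )
        groups = {f"a{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        d, kw = distance_to_ideal(profiles, "ideal", groups=groups)
        assert kw is not None and "p" in kw.columns
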