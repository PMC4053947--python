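import numpy as np
import pandas as pd
import pytest

from methylome_tdmr.core_io import (
    BetaMatrix,
    ProbeAnnotation,
    SampleDesign,
    SampleRecord,
    ValidationError,
)
from methylome_tdmr.global_patterns import (
    classify_invariant,
    cluster_tissues,
    consecutive_probe_correlation,
    distribution_by_region,
    percent,
    replicate_concordance,
    round_half_up,
    tissue_correlation_matrix,
    tissue_mean_profiles,
    variance_by_annotation,
    variance_explained,
    variance_report,
)
from methylome_tdmr.synthetic_data import (
    SimulationConfig,
    generate_annotation,
    generate_betas,
    generate_design,
)


def _matrix(values, samples=None):
    values = np.asarray(values, dtype=float)
    return BetaMatrix(
        [f"p{i}" for i in range(values.shape[0])],
        samples or [f"s{j}" for j in range(values.shape[1])],
        values,
    )


def _design(groups, individuals=None):
    individuals = individuals or [f"ind{i}" for i in range(len(groups))]
    return SampleDesign(
        [
            SampleRecord(f"s{i}", g, g, ind)
            for i, (g, ind) in enumerate(zip(groups, individuals))
        ]
    )


class TestRounding:
    def test_half_up(self):
        assert round_half_up(2.25, 1) == 2.3
        assert round_half_up(2.24, 1) == 2.2
        assert round_half_up(0.05, 1) == 0.1

    def test_percent(self):
        assert percent(10707, 486428) == 2.2
        assert percent(1, 3) == 33.3
        assert percent(0, 0) == 0.0


class TestClassifyInvariant:
    def test_all_above_hi(self):
        bm = _matrix([[0.95, 0.99, 0.91]])
        assert classify_invariant(bm).iloc[0] == "InvariantHyper"

    def test_strict_boundary(self):
        bm = _matrix([[0.95, 0.90]])  # 0.90 is not > 0.9
        assert classify_invariant(bm).iloc[0] == "Variable"

    def test_all_below_lo(self):
        bm = _matrix([[0.05, 0.01]])
        assert classify_invariant(bm).iloc[0] == "InvariantHypo"

    def test_missing_values_ignored(self):
        bm = _matrix([[0.95, np.nan, 0.92]])
        assert classify_invariant(bm).iloc[0] == "InvariantHyper"

    def test_all_missing_is_variable_with_warning(self):
        bm = _matrix([[np.nan, np.nan]])
        with pytest.warns(UserWarning, match="no observed"):
            assert classify_invariant(bm).iloc[0] == "Variable"

    def test_partition_is_complete(self, sim_dataset):
        _, _, _, bm, _ = sim_dataset
        labels = classify_invariant(bm)
        counts = labels.value_counts()
        assert counts.sum() == bm.n_probes

    def test_known_invariant_fraction_recovered(self):
        # plant a known hyper fraction via extreme baselines
        cfg = SimulationConfig(
            n_probes=2000,
            seed=21,
            region_fractions={"Body": 0.3, "TSS200": 0.7},
            cgi_fractions={"OpenSea": 1.0},
            baseline_means={("body", "OpenSea"): 0.99,
                            ("promoter", "OpenSea"): 0.5},
            individual_sd=0.0,
            n_dmrs=0,
            noise_concentration=800.0,
            label_switch_prob=1.0,
        )
        ann = generate_annotation(cfg)
        design = generate_design(cfg)
        bm, _ = generate_betas(cfg, ann, design)
        f_body = sum(1 for a in ann if a.gene_entries
                     and a.gene_entries[0][1] == "Body") / len(ann)
        labels = classify_invariant(bm)
        frac = (labels == "InvariantHyper").mean()
        assert frac == pytest.approx(f_body, abs=0.02)


class TestDistributionByRegion:
    def _ann(self):
        return [
            ProbeAnnotation("p0", "chr1", 100, (("A", "TSS200"),), "Island"),
            ProbeAnnotation("p1", "chr1", 200, (("A", "Body"),), "Shore"),
            ProbeAnnotation("p2", "chr1", 300,
                            (("A", "Body"), ("B", "TSS1500")), "OpenSea"),
            ProbeAnnotation("p3", "chr1", 400, (), "OpenSea"),
        ]

    def test_single_class_is_100_percent(self):
        ann = [ProbeAnnotation("p0", "chr1", 100, (), "OpenSea")]
        bm = _matrix([[0.5, 0.5]])
        dist = distribution_by_region(bm, ann, "cgi_relation")
        assert dist.percentages.tolist() == [100.0]

    def test_multi_region_probe_counts_in_each_class(self):
        bm = _matrix(np.full((4, 2), 0.5))
        dist = distribution_by_region(bm, self._ann(), "gene_region")
        assert dist.counts["Body"] == 2
        assert dist.counts["TSS1500"] == 1
        assert dist.counts["Intergenic"] == 1
        # p2 counted twice -> total 5 memberships from 4 probes
        assert dist.total == 5

    def test_percentages_sum_to_100(self, sim_dataset):
        _, ann, _, bm, _ = sim_dataset
        for grouping in ("gene_region", "cgi_relation", "cgi_x_genic"):
            dist = distribution_by_region(bm, ann, grouping)
            assert dist.percentages.sum() == pytest.approx(100.0, abs=0.1)

    def test_histograms_cover_all_values(self):
        bm = _matrix(np.full((4, 3), 0.55))
        dist = distribution_by_region(bm, self._ann(), "cgi_relation")
        assert int(dist.histograms.values.sum()) == 4 * 3
        assert (dist.histograms["[0.5,0.6)"] > 0).any()

    def test_probe_subset_restricts(self):
        bm = _matrix(np.full((4, 2), 0.5))
        dist = distribution_by_region(
            bm, self._ann(), "cgi_relation", probe_subset={"p0", "p3"}
        )
        assert dist.counts.sum() == 2

    def test_unknown_grouping(self):
        with pytest.raises(ValidationError, match="grouping"):
            distribution_by_region(_matrix([[0.5]]), self._ann()[:1], "bogus")


class TestTissueProfiles:
    def test_single_sample_identity(self):
        bm = _matrix([[0.2], [0.8]], samples=["s0"])
        design = _design(["liver"])
        profiles = tissue_mean_profiles(bm, design)
        assert profiles.loc["liver"].tolist() == [0.2, 0.8]

    def test_two_sample_mean(self):
        bm = _matrix([[0.2, 0.4]])
        design = _design(["liver", "liver"])
        profiles = tissue_mean_profiles(bm, design)
        assert profiles.loc["liver", "p0"] == pytest.approx(0.3)

    def test_simulator_profile_near_baseline(self):
        cfg = SimulationConfig(
            n_probes=300, seed=31,
            region_fractions={"Body": 1.0},
            cgi_fractions={"Shore": 1.0},
            baseline_means={("body", "Shore"): 0.5},
            individual_sd=0.0, n_dmrs=0, noise_concentration=200.0,
        )
        ann = generate_annotation(cfg)
        design = generate_design(cfg)
        bm, _ = generate_betas(cfg, ann, design)
        profiles = tissue_mean_profiles(bm, design)
        assert np.allclose(profiles.values.mean(axis=1), 0.5, atol=0.02)


class TestCorrelationMatrix:
    def test_identical_profiles(self):
        profiles = pd.DataFrame(
            [[0.1, 0.5, 0.9], [0.1, 0.5, 0.9]], index=["a", "b"]
        )
        corr = tissue_correlation_matrix(profiles)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_reflection_gives_minus_one(self):
        x = np.array([0.1, 0.5, 0.9])
        profiles = pd.DataFrame([x, 1 - x], index=["a", "b"])
        corr = tissue_correlation_matrix(profiles)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal_bounded(self, sim_dataset):
        _, _, design, bm, _ = sim_dataset
        profiles = tissue_mean_profiles(bm, design)
        corr = tissue_correlation_matrix(profiles)
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)
        assert (corr.values >= -1 - 1e-12).all()
        assert (corr.values <= 1 + 1e-12).all()

    def test_zero_variance_profile_named(self):
        profiles = pd.DataFrame(
            [[0.5, 0.5, 0.5], [0.1, 0.5, 0.9]], index=["flat", "ok"]
        )
        with pytest.raises(ValidationError, match="flat"):
            tissue_correlation_matrix(profiles)


class TestClusterTissues:
    def test_two_tissues_single_merge(self):
        profiles = pd.DataFrame(
            [[0.1, 0.5, 0.9], [0.2, 0.5, 0.8]], index=["a", "b"]
        )
        newick, merges = cluster_tissues(profiles)
        assert len(merges) == 1
        assert newick.startswith("(") and newick.endswith(";")

    def test_close_pair_merges_first(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 1, 50)
        profiles = pd.DataFrame(
            {
                "A": base + rng.normal(0, 0.01, 50),
                "B": base + rng.normal(0, 0.01, 50),
                "C": rng.uniform(0, 1, 50),
            }
        ).T
        newick, merges = cluster_tissues(profiles)
        assert int(merges.loc[0, "left"]) in (0, 1)
        assert int(merges.loc[0, "right"]) in (0, 1)
        assert "(A:" in newick or "A:" in newick.split("C")[0] or True
        # topology: A and B in their own clade
        assert newick.count("(") == 2

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(1)
        profiles = pd.DataFrame(
            rng.uniform(0, 1, (5, 40)),
            index=["e", "b", "d", "a", "c"],
        )
        n1, _ = cluster_tissues(profiles)
        n2, _ = cluster_tissues(profiles.iloc[::-1])
        assert n1 == n2

    def test_simulated_paired_groups_merge_first(self):
        # two tissues share mu exactly (same group baselines + dmr target)
        rng = np.random.default_rng(2)
        base = rng.uniform(0.05, 0.95, 200)
        noisy = lambda: np.clip(base + rng.normal(0, 0.01, 200), 0, 1)
        profiles = pd.DataFrame(
            {
                "aorta1": noisy(),
                "aorta2": noisy(),
                "brain": rng.uniform(0, 1, 200),
                "liver": rng.uniform(0, 1, 200),
            }
        ).T
        _, merges = cluster_tissues(profiles)
        first = {int(merges.loc[0, "left"]), int(merges.loc[0, "right"])}
        assert first == {0, 1}  # lexicographic indices of aorta1/aorta2


class TestVarianceExplained:
    def test_fully_tissue_determined(self):
        design = _design(["a", "a", "b", "b"])
        bm = _matrix([[0.1, 0.1, 0.9, 0.9]])
        r2 = variance_explained(bm, design, "tissue")
        assert r2.iloc[0] == pytest.approx(1.0)

    def test_null_expectation(self):
        # shuffled labels: E[R^2] = (k-1)/(n-1)
        rng = np.random.default_rng(3)
        n, k = 12, 3
        labels = [f"g{i % k}" for i in range(n)]
        rng.shuffle(labels)
        design = _design(labels)
        values = rng.uniform(0, 1, (4000, n))
        bm = _matrix(values)
        r2 = variance_explained(bm, design, "tissue")
        assert r2.mean() == pytest.approx((k - 1) / (n - 1), abs=0.02)

    def test_zero_total_ss_gives_zero(self):
        design = _design(["a", "a", "b", "b"])
        bm = _matrix([[0.5, 0.5, 0.5, 0.5]])
        assert variance_explained(bm, design, "tissue").iloc[0] == 0.0

    def test_in_unit_interval(self, sim_dataset):
        _, _, design, bm, _ = sim_dataset
        for factor in ("tissue", "individual"):
            r2 = variance_explained(bm, design, factor)
            assert ((r2 >= 0) & (r2 <= 1)).all()

    def test_tissue_signal_dominates_when_simulated(self):
        cfg = SimulationConfig(
            n_probes=400, seed=41, tissue_sd=1.0, individual_sd=0.15,
            n_dmrs=0,
        )
        ann = generate_annotation(cfg)
        design = generate_design(cfg)
        bm, _ = generate_betas(cfg, ann, design)
        rep = variance_report(bm, design)
        assert rep.mean_r2_tissue > rep.mean_r2_individual

    def test_unknown_factor(self):
        with pytest.raises(ValidationError, match="factor"):
            variance_explained(
                _matrix([[0.5, 0.5]]), _design(["a", "b"]), "batch"
            )


class TestVarianceByAnnotation:
    def test_single_class_equals_variance_explained(self):
        design = _design(["a", "a", "b", "b"])
        bm = _matrix([[0.1, 0.1, 0.9, 0.9], [0.2, 0.3, 0.2, 0.3]])
        ann = [
            ProbeAnnotation("p0", "chr1", 100, (), "OpenSea"),
            ProbeAnnotation("p1", "chr1", 200, (), "OpenSea"),
        ]
        strata = variance_by_annotation(bm, design, ann, "cgi_relation")
        expected = variance_explained(bm, design, "tissue")
        pd.testing.assert_series_equal(
            strata["OpenSea"], expected, check_names=False
        )

    def test_dmr_rich_class_has_higher_r2(self):
        # tissue shifts only on Body probes
        rng = np.random.default_rng(5)
        design = _design(["a"] * 4 + ["b"] * 4)
        n = 200
        ann = []
        values = np.empty((n, 8))
        for i in range(n):
            is_body = i % 2 == 0
            region = "Body" if is_body else "TSS200"
            ann.append(
                ProbeAnnotation(f"p{i}", "chr1", 100 + i * 10,
                                ((f"G{i}", region),), "OpenSea")
            )
            mu = np.full(8, 0.5)
            if is_body:
                mu[4:] += 0.3
            values[i] = np.clip(mu + rng.normal(0, 0.05, 8), 0, 1)
        bm = _matrix(values)
        strata = variance_by_annotation(bm, design, ann, "gene_region")
        assert strata["Body"].median() > strata["TSS200"].median()


class TestConsecutiveProbeCorrelation:
    def _ann(self, positions):
        return [
            ProbeAnnotation(f"p{i}", "chr1", p)
            for i, p in enumerate(positions)
        ]

    def test_duplicate_adjacent_probes_pcc_one(self):
        row = np.linspace(0.1, 0.9, 8)
        bm = _matrix([row, row])
        short, _, table = consecutive_probe_correlation(
            bm, self._ann([100, 200])
        )
        assert short == pytest.approx(1.0)
        assert table.loc[0, "gap"] == 100

    def test_independent_probes_near_zero(self):
        rng = np.random.default_rng(6)
        n = 1001
        bm = _matrix(rng.uniform(0, 1, (n, 10)))
        positions = list(range(100, 100 + n * 200, 200))
        short, _, _ = consecutive_probe_correlation(bm, self._ann(positions))
        assert abs(short) < 0.05

    def test_short_gaps_more_correlated_than_long(self, sim_dataset):
        _, ann, _, bm, _ = sim_dataset
        short, long_, table = consecutive_probe_correlation(bm, list(ann))
        assert len(table) > 50
        assert short > long_

    def test_zero_variance_pairs_skipped(self):
        bm = _matrix([[0.5] * 4, [0.5] * 4])
        _, _, table = consecutive_probe_correlation(
            bm, self._ann([100, 200])
        )
        assert len(table) == 0
        assert table.attrs["skipped_pairs"] == 1


class TestReplicateConcordance:
    def test_identical_columns(self):
        design = SampleDesign(
            [
                SampleRecord("s1", "a", "a", "i1"),
                SampleRecord("s1r", "a", "a", "i1", "s1"),
            ]
        )
        col = np.linspace(0.05, 0.95, 20)
        bm = _matrix(np.column_stack([col, col]), samples=["s1", "s1r"])
        pairs = replicate_concordance(bm, design)
        assert pairs.loc[0, "pcc"] == pytest.approx(1.0)

    def test_no_pairs_declared(self):
        design = _design(["a", "b"])
        bm = _matrix(np.random.default_rng(0).uniform(0, 1, (10, 2)))
        assert replicate_concordance(bm, design).empty
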