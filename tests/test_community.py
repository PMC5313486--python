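"""OTU filters, rarefaction, Bray-Curtis/PCoA, PERMANOVA, differential OTUs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

import skbio.stats.distance as skbio_distance
import skbio.stats.ordination as skbio_ordination

from methanotype import community, simulate
from methanotype.community import OtuTable


def toy_table(counts: dict, n_otus: int, cows=("c1", "c2"), periods=(1,)) -> OtuTable:
    """Build a small table; counts maps library id -> count vector."""
    idx = [f"OTU{i}" for i in range(n_otus)]
    counts_df = pd.DataFrame(counts, index=idx)
    meta = []
    for lib in counts_df.columns:
        cow, period, rep = lib.rsplit("_", 2)
        meta.append((lib, cow, int(period), int(rep)))
    samples = pd.DataFrame(meta, columns=["library_id", "cow_id", "period", "replicate"]).set_index("library_id")
    tax = pd.DataFrame(
        {"lineage": ["k__Bacteria; p__X; c__; o__; f__; g__G"] * n_otus,
         "domain": ["bacteria"] * n_otus,
         "clade": [""] * n_otus},
        index=idx,
    )
    return OtuTable(counts=counts_df, samples=samples, taxonomy=tax)


class TestReplicateConsistency:
    def test_absent_in_one_replicate_dropped(self):
        t = toy_table(
            {"c1_1_1": [5, 1], "c1_1_2": [5, 1], "c1_1_3": [0, 1]}, n_otus=2
        )
        out = community.filter_replicate_consistency(t)
        assert list(out.counts.index) == ["OTU1"]

    def test_present_in_all_replicates_of_one_sample_retained(self):
        t = toy_table(
            {
                "c1_1_1": [2, 1], "c1_1_2": [3, 1], "c1_1_3": [1, 1],
                "c2_1_1": [0, 1], "c2_1_2": [0, 1], "c2_1_3": [0, 1],
            },
            n_otus=2,
        )
        assert "OTU0" in community.filter_replicate_consistency(t).counts.index
        # strict reading drops it
        strict = community.filter_replicate_consistency(t, mode="every-sample")
        assert "OTU0" not in strict.counts.index

    def test_wrong_replicate_count_errors(self):
        t = toy_table({"c1_1_1": [1], "c1_1_2": [1]}, n_otus=1)
        with pytest.raises(ValueError, match="replicates"):
            community.filter_replicate_consistency(t)


class TestMinReads:
    def test_threshold_arithmetic(self):
        assert community.min_reads_threshold(5_700_000, 1e-5) == 57
        assert community.min_reads_threshold(62 * 93_323, 0.001) == 5786

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            community.min_reads_threshold(100, 1.5)

    def test_tiny_fraction_keeps_all_nonzero(self):
        t = toy_table({"c1_1_1": [1, 0], "c1_1_2": [1, 0], "c1_1_3": [1, 0]}, n_otus=2)
        out = community.filter_min_reads(t, 1e-9)
        assert list(out.counts.index) == ["OTU0"]

    def test_boundary_is_strict(self):
        # grand total 1000, fraction 0.1 -> threshold 100: OTU at exactly 100 dropped
        t = toy_table({"c1_1_1": [100, 900]}, n_otus=2)
        out = community.filter_min_reads(t, 0.1)
        assert list(out.counts.index) == ["OTU1"]


class TestSubsample:
    def test_columns_sum_to_depth(self):
        rng = np.random.default_rng(0)
        t = toy_table(
            {f"c1_1_{r}": rng.integers(0, 50, size=8) for r in (1, 2, 3)}, n_otus=8
        )
        out = community.subsample_even_depth(t, depth=40, seed=1)
        assert (out.counts.sum(axis=0) == 40).all()

    def test_depth_equal_to_total_unchanged(self):
        t = toy_table({"c1_1_1": [10, 20, 30]}, n_otus=3)
        out = community.subsample_even_depth(t, depth=60, seed=1)
        assert out.counts["c1_1_1"].tolist() == [10, 20, 30]

    def test_shallow_library_dropped_with_warning(self, caplog):
        t = toy_table({"c1_1_1": [10, 10], "c1_1_2": [3, 2]}, n_otus=2)
        with caplog.at_level("WARNING"):
            out = community.subsample_even_depth(t, depth=10, seed=1)
        assert list(out.counts.columns) == ["c1_1_1"]
        assert "dropped" in caplog.text

    def test_rarefied_mean_matches_hypergeometric(self):
        col = np.array([60, 30, 10])
        t = toy_table({"c1_1_1": col}, n_otus=3)
        draws = np.stack(
            [
                community.subsample_even_depth(t, depth=50, seed=s).counts["c1_1_1"].to_numpy()
                for s in range(1000)
            ]
        )
        expect = 50 * col / col.sum()
        var = 50 * (col / 100) * (1 - col / 100) * (100 - 50) / 99
        se = np.sqrt(var / 1000)
        assert np.all(np.abs(draws.mean(axis=0) - expect) < 3 * se + 1e-9)

    def test_per_library_streams_independent(self):
        t = toy_table(
            {"c1_1_1": [40, 40, 20], "c1_1_2": [30, 30, 40], "c1_1_3": [50, 25, 25]},
            n_otus=3,
        )
        full = community.subsample_even_depth(t, depth=60, seed=5)
        dropped = community.subsample_even_depth(
            t._with_counts(t.counts.drop(columns="c1_1_2")), depth=60, seed=5
        )
        pd.testing.assert_series_equal(full.counts["c1_1_3"], dropped.counts["c1_1_3"])


class TestRelativeAbundance:
    def test_rows_sum_to_one_at_all_ranks(self, small_herd):
        params = simulate.default_community_params(n_filler=20, library_size=3000)
        t = simulate.gen_otu_table(small_herd, params, seed=2)
        for level in ("otu", "genus", "family", "phylum"):
            rel = community.relative_abundance(t, level=level)
            assert np.allclose(rel.sum(axis=1), 1.0)

    def test_unknown_rank_errors(self, small_herd):
        params = simulate.default_community_params(n_filler=5, library_size=500)
        t = simulate.gen_otu_table(small_herd, params, seed=2)
        with pytest.raises(ValueError, match="rank"):
            community.relative_abundance(t, level="species-group")

    def test_planted_methanobrevibacter_share_of_archaea(self):
        """~88.8 % of archaeal reads are Methanobrevibacter by construction."""
        herd = simulate.make_herd(n_cows=10, n_periods=3, seed=4)
        params = simulate.default_community_params()
        t = simulate.gen_otu_table(herd, params, seed=4)
        rel = community.relative_abundance(t, level="genus", domain="archaea")
        mbb = [c for c in rel.columns if "Methanobrevibacter" in c]
        share = rel[mbb].sum(axis=1).mean() * 100
        assert share == pytest.approx(88.8, abs=3.0)


class TestBrayCurtis:
    def test_formula_and_extremes(self):
        df = pd.DataFrame([[1, 2, 3], [3, 2, 1], [1, 2, 3], [0, 0, 4]],
                          index=["a", "b", "c", "d"], dtype=float)
        dm = community.bray_curtis(df)
        assert dm["a", "b"] == pytest.approx(4 / 12)
        assert dm["a", "c"] == 0.0
        d2 = community.bray_curtis(pd.DataFrame([[1, 0], [0, 1]], index=["x", "y"]))
        assert d2["x", "y"] == pytest.approx(1.0)

    def test_two_zero_samples_error(self):
        df = pd.DataFrame([[0, 0], [0, 0], [1, 1]], index=list("abc"))
        with pytest.raises(ValueError, match="all-zero"):
            community.bray_curtis(df)

    @given(
        st.integers(min_value=2, max_value=6),
        st.integers(min_value=2, max_value=5),
        st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=30)
    def test_metric_properties_on_random_tables(self, n, k, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((n, k)) + 1e-6
        dm = community.bray_curtis(pd.DataFrame(x, index=[f"s{i}" for i in range(n)]))
        d = dm.data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert np.all((d >= 0) & (d <= 1 + 1e-12))


class TestPcoa:
    def test_two_samples_closed_form(self):
        res = community.pcoa(np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert sorted(res.coordinates.iloc[:, 0].tolist()) == pytest.approx([-1.0, 1.0])
        assert res.explained_pct[0] == pytest.approx(100.0)

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 4))
        d = squareform(pdist(pts))
        res = community.pcoa(d)
        dhat = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(d - dhat).max() < 1e-8

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(5)
        x = rng.random((6, 8))
        dm = community.bray_curtis(pd.DataFrame(x, index=[f"s{i}" for i in range(6)]))
        d = dm.data
        n = d.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d**2) @ j
        res = community.pcoa(dm)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(b), abs=1e-9)

    def test_asymmetric_input_errors(self):
        with pytest.raises(ValueError):
            community.pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(7)
        x = rng.random((7, 12))
        dm = community.bray_curtis(pd.DataFrame(x, index=[f"s{i}" for i in range(7)]))
        ours = community.pcoa(dm)
        ref = skbio_ordination.pcoa(dm, method="eigh")
        ref_pos = np.sort(ref.eigvals[ref.eigvals > 1e-10].to_numpy())[::-1]
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues[ours.eigenvalues > 1e-10])[::-1], ref_pos, atol=1e-9
        )
        np.testing.assert_allclose(
            np.abs(ours.coordinates.iloc[:, 0].to_numpy()),
            np.abs(ref.samples.iloc[:, 0].to_numpy()),
            atol=1e-8,
        )


class TestPermanova:
    @staticmethod
    def clustered_dm(seed=0, n=8, shift=1.0):
        rng = np.random.default_rng(seed)
        x = rng.random((n, 5))
        x[n // 2 :, 0] += shift
        labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
        df = pd.DataFrame(x, index=[f"s{i}" for i in range(n)])
        return community.bray_curtis(df), pd.Series(labels, index=df.index)

    def test_detects_planted_separation(self):
        dm, labels = self.clustered_dm(n=12, shift=3.0)
        res = community.permanova(dm, labels, n_permutations=999, seed=0)
        assert res.p_value <= 0.01

    def test_degenerate_separation_smallest_p(self):
        x = np.array([[0.0, 1], [0, 1], [0, 1], [5, 0], [5, 0], [5, 0]])
        dm = community.bray_curtis(pd.DataFrame(x + 1e-9, index=[f"s{i}" for i in range(6)]))
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=list(dm.ids))
        res = community.permanova(dm, labels, n_permutations=999, seed=0)
        assert np.isinf(res.statistic) or res.statistic > 1e6
        # the permutation distribution puts mass 2/C(6,3) = 0.1 on the exact
        # split (both labelings), so ~0.1 is the smallest attainable p here
        assert res.p_value == pytest.approx(0.1, abs=0.04)

    def test_matches_reference_statistic(self):
        dm, labels = self.clustered_dm(seed=2, shift=0.5)
        ours = community.permanova(dm, labels, n_permutations=99, seed=0)
        ref = skbio_distance.permanova(dm, labels.to_numpy(), permutations=99)
        assert ours.statistic == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_single_group_errors(self):
        dm, labels = self.clustered_dm()
        with pytest.raises(ValueError, match="2 groups"):
            community.permanova(dm, pd.Series("A", index=labels.index), seed=0)

    def test_unit_restricted_permutation_requires_consistent_units(self):
        dm, labels = self.clustered_dm(n=8)
        units = pd.Series(["u1", "u1", "u2", "u2", "u3", "u3", "u4", "u4"],
                          index=labels.index)
        res = community.permanova(dm, labels, n_permutations=99, seed=1, permute_unit=units)
        assert 0 < res.p_value <= 1
        bad_units = pd.Series(["u1"] * 8, index=labels.index)
        with pytest.raises(ValueError, match="spans multiple groups"):
            community.permanova(dm, labels, n_permutations=99, seed=1, permute_unit=bad_units)


class TestDifferentialOtus:
    @staticmethod
    def rel_frame(n_cows=10, n_periods=3, n_otus=6, seed=0, effect=None):
        rng = np.random.default_rng(seed)
        cows = [f"c{i}" for i in range(n_cows)]
        clusters = pd.Series(["L"] * (n_cows // 2) + ["H"] * (n_cows - n_cows // 2), index=cows)
        idx = pd.MultiIndex.from_product([cows, range(1, n_periods + 1)],
                                         names=["cow_id", "period"])
        base = np.full(n_otus, 1.0 / n_otus)
        rows = []
        for cow, _ in idx:
            p = base.copy()
            if effect and clusters[cow] == "H":
                p[0] *= effect
            p = p / p.sum()
            rows.append(rng.dirichlet(400 * p))
        return pd.DataFrame(rows, index=idx, columns=[f"o{i}" for i in range(n_otus)]), clusters

    def test_constant_otu_scores_zero(self):
        rel, clusters = self.rel_frame(seed=1)
        rel["o0"] = 0.2
        out = community.differential_otus(rel, clusters).set_index("otu_id")
        assert out.loc["o0", "statistic"] == 0.0
        assert out.loc["o0", "q"] == 1.0

    def test_planted_effect_detected_and_sorted(self):
        rel, clusters = self.rel_frame(effect=3.0, seed=2)
        out = community.differential_otus(rel, clusters)
        row = out.set_index("otu_id").loc["o0"]
        assert row["q"] < 0.05
        assert row["enriched_in"] == "H"
        assert (out.groupby("enriched_in")["mean_L"].apply(lambda s: s.is_monotonic_decreasing)).all()

    def test_min_fraction_excludes_rare_otus(self):
        rel, clusters = self.rel_frame()
        rel["o0"] = 1e-5
        out = community.differential_otus(rel, clusters, min_fraction=0.001)
        assert "o0" not in set(out["otu_id"])

    def test_small_cluster_errors(self):
        rel, clusters = self.rel_frame(n_cows=3)
        with pytest.raises(ValueError, match="at least 2"):
            community.differential_otus(rel, pd.Series(["L", "H", "H"], index=clusters.index))

    def test_q_at_least_p(self):
        rel, clusters = self.rel_frame(seed=3)
        out = community.differential_otus(rel, clusters)
        assert (out["q"] >= out["p"] - 1e-12).all()


class TestCladeRatio:
    def test_direct_quotients(self):
        df = pd.DataFrame({"gottschalkii": [0.34, 0.5], "ruminantium": [0.53, 0.5]},
                          index=["s1", "s2"])
        per_sample, _ = community.clade_ratio(df)
        assert per_sample["s1"] == pytest.approx(34 / 53, rel=1e-6)
        assert per_sample["s2"] == pytest.approx(1.0)

    def test_zero_ruminantium_flagged_infinite(self, caplog):
        df = pd.DataFrame({"gottschalkii": [0.4], "ruminantium": [0.0]}, index=["s1"])
        with caplog.at_level("WARNING"):
            per_sample, _ = community.clade_ratio(df)
        assert np.isinf(per_sample["s1"])
        assert "infinite" in caplog.text

    def test_monotone_over_planted_emitter_groups(self):
        herd = simulate.make_herd(n_cows=21, n_periods=2, seed=6)
        params = simulate.default_community_params()
        t = simulate.gen_otu_table(herd, params, seed=6)
        rel = community.relative_abundance(t, level="otu", domain="archaea")
        clades = t.taxonomy.loc[rel.columns, "clade"]
        shares = rel.T.groupby(clades).sum().T
        groups = pd.Series(
            [herd.true_groups[c] for c, _ in shares.index], index=shares.index
        )
        _, by_group = community.clade_ratio(shares, groups=groups)
        assert by_group["L"] < by_group["M"] < by_group["H"]
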