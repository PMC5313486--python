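"""Generators: seeded determinism, planted truth, distributional laws."""

import numpy as np
import pandas as pd
import pytest

from methanotype import community, phenotype, qpcr, simulate


class TestGasTrace:
    def test_zero_emitter_has_no_pulses(self, trace_params):
        tr = simulate.gen_gas_trace(0.0, trace_params, 300.0, seed=1)
        assert len(tr.events) == 0
        envelope = trace_params.baseline_level + 3 * (
            trace_params.baseline_drift_sd + trace_params.noise_sd
        )
        assert tr.c.max() < envelope + 3 * trace_params.noise_sd

    def test_seeded_determinism(self, trace_params):
        a = simulate.gen_gas_trace(300.0, trace_params, 300.0, seed=4, cow_id="c1")
        b = simulate.gen_gas_trace(300.0, trace_params, 300.0, seed=4, cow_id="c1")
        assert np.array_equal(a.c, b.c)
        c = simulate.gen_gas_trace(300.0, trace_params, 300.0, seed=5, cow_id="c1")
        assert not np.array_equal(a.c, c.c)

    def test_pulse_count_follows_poisson_law(self):
        """1 event/min over 600 s: mean count over many seeds ~ Poisson(10)."""
        params = simulate.TraceParams(eructation_rate=1.0)
        counts = [
            len(simulate.gen_gas_trace(300.0, params, 600.0, seed=s).events)
            for s in range(1000)
        ]
        se = np.sqrt(10.0 / len(counts))
        assert abs(np.mean(counts) - 10.0) < 3 * se

    def test_expected_pulse_mass_proportional_to_rate(self, trace_params):
        """Mean undiluted pulse area per minute is rate/station_gain."""
        for rate in (250.0, 400.0):
            areas = []
            for s in range(200):
                ev = simulate.gen_gas_trace(rate, trace_params, 600.0, seed=s).events
                areas.append(ev["area"].sum() * trace_params.dilution_factor / 10.0)
            expect = rate / trace_params.station_gain
            assert abs(np.mean(areas) - expect) / expect < 0.05

    def test_validation(self, trace_params):
        with pytest.raises(ValueError):
            simulate.gen_gas_trace(-1.0, trace_params, 300.0, seed=0)
        with pytest.raises(ValueError):
            simulate.gen_gas_trace(300.0, trace_params, 30.0, seed=0)
        with pytest.raises(ValueError):
            simulate.TraceParams(dilution_factor=0.5)


class TestHerd:
    def test_structure_and_determinism(self):
        herd = simulate.make_herd(n_cows=21, seed=2)
        assert len(herd.true_rates) == 21
        assert (herd.true_rates > 0).all()
        assert set(herd.cluster_assignment.unique()) <= {"L", "H"}
        again = simulate.make_herd(n_cows=21, seed=2)
        pd.testing.assert_series_equal(herd.true_rates, again.true_rates)

    def test_groups_ordered_by_rate(self):
        herd = simulate.make_herd(n_cows=30, seed=3)
        means = herd.true_rates.groupby(herd.true_groups).mean()
        assert means["L"] < means["M"] < means["H"]


class TestOtuTable:
    def test_library_totals_and_determinism(self, small_herd):
        params = simulate.default_community_params(n_filler=30, library_size=5000)
        t1 = simulate.gen_otu_table(small_herd, params, seed=6)
        assert (t1.counts.sum(axis=0) == 5000).all()
        assert t1.counts.shape[1] == small_herd.n_cows * small_herd.n_periods * 3
        t2 = simulate.gen_otu_table(small_herd, params, seed=6)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_unknown_planted_otu_errors(self):
        params = simulate.default_community_params(n_filler=10)
        with pytest.raises(ValueError, match="unknown OTU"):
            simulate.CommunityParams(
                base_proportions=params.base_proportions,
                taxonomy=params.taxonomy,
                planted_effects={"OTU_nope": 2.0},
            )

    def test_planted_fold_change_recovered(self):
        """The 4.5x state effect (1.99 % vs 0.44 %) is recovered within 20 %."""
        herd = simulate.make_herd(n_cows=20, n_periods=1, seed=8)
        params = simulate.default_community_params(library_size=20_000)
        table = simulate.gen_otu_table(herd, params, seed=8)
        rel = community.relative_abundance(table, level="otu")
        cows = rel.index.get_level_values("cow_id")
        states = herd.cluster_assignment[cows].to_numpy()
        target = rel["OTU_807342"]
        ratio = target[states == "L"].mean() / target[states == "H"].mean()
        assert ratio == pytest.approx(1.99 / 0.44, rel=0.20)

    def test_archaeal_clades_labelled(self):
        params = simulate.default_community_params()
        tax = params.taxonomy
        arch = tax[tax["domain"] == "archaea"]
        assert {"ruminantium", "gottschalkii"} <= set(arch["clade"])


class TestQpcrGen:
    CURVE = qpcr.StandardCurve(slope=-3.46, intercept=38.0)

    def test_standards_span_nine_decades(self):
        std, _ = simulate.gen_qpcr_data({"c1": 1e7}, self.CURVE, seed=0)
        assert sorted(std["copies"].unique()) == [10.0**k for k in range(9)]

    def test_zero_noise_round_trip(self):
        truth = pd.Series({"c1": 2.2e7, "c2": 6.8e6})
        _, samp = simulate.gen_qpcr_data(truth, self.CURVE, noise_sd=0.0, seed=0)
        est = qpcr.quantify_samples(samp, self.CURVE).set_index("cow_id")
        for cow, val in truth.items():
            assert est.loc[cow, "copies_per_ml"] == pytest.approx(val, rel=1e-9)

    def test_noisy_round_trip_median_error(self):
        """0.2 Cq noise: median |log10 error| of recovered copies < 0.1."""
        errors = []
        for seed in range(100):
            _, samp = simulate.gen_qpcr_data({"c1": 1e7}, self.CURVE, seed=seed)
            est = qpcr.quantify_samples(samp, self.CURVE)["copies_per_ml"].iloc[0]
            errors.append(abs(np.log10(est / 1e7)))
        assert np.median(errors) < 0.1

    def test_nonpositive_dilution_errors(self):
        with pytest.raises(ValueError):
            simulate.gen_qpcr_data({"c1": 1e7}, self.CURVE, dilutions=(0,), seed=0)


class TestGeneratorDeterminism:
    def test_qpcr_and_phenotype_generators_are_seed_stable(self, small_herd):
        curve = qpcr.StandardCurve(slope=-3.46, intercept=38.0)
        s1, q1 = simulate.gen_qpcr_data({"c1": 1e7}, curve, seed=9)
        s2, q2 = simulate.gen_qpcr_data({"c1": 1e7}, curve, seed=9)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(q1, q2)
        t1 = simulate.gen_phenotype_tables(small_herd, seed=9)
        t2 = simulate.gen_phenotype_tables(small_herd, seed=9)
        for name in ("intake", "feces", "milk", "vfa"):
            pd.testing.assert_frame_equal(getattr(t1, name), getattr(t2, name))


class TestPhenotypeGen:
    def test_marker_conservation_by_construction(self, small_herd):
        tabs = simulate.gen_phenotype_tables(small_herd, seed=1, fecal_conc_rel_sd=0.0)
        merged = tabs.intake.merge(tabs.feces, on=["cow_id", "period"],
                                   suffixes=("_in", "_fec"))
        merged = merged.merge(tabs.truth["fecal_dm"], on=["cow_id", "period"])
        aia_in = merged["dmi_kg"] * merged["AIA_g_per_kg_in"] / 1000.0
        aia_out = merged["fecal_dm_kg"] * merged["AIA_g_per_kg_fec"] / 1000.0
        assert np.allclose(aia_in, aia_out)

    def test_zero_noise_digestibility_round_trip(self, small_herd):
        tabs = simulate.gen_phenotype_tables(small_herd, seed=2, fecal_conc_rel_sd=0.0)
        dig = phenotype.digestibility_table(tabs.intake, tabs.feces)
        for nutrient, d in tabs.truth["digestibility"].items():
            assert np.allclose(dig[nutrient], d * 1000.0)

    def test_planted_butyrate_shift_between_states(self):
        herd = simulate.make_herd(n_cows=40, n_periods=2, seed=3)
        tabs = simulate.gen_phenotype_tables(herd, seed=3)
        by_state = tabs.vfa.groupby(
            herd.cluster_assignment[tabs.vfa["cow_id"]].to_numpy()
        )["butyrate"].mean()
        assert by_state["H"] - by_state["L"] == pytest.approx(17.3 - 14.7, abs=0.5)

    def test_vfa_rows_sum_to_100(self, small_herd):
        tabs = simulate.gen_phenotype_tables(small_herd, seed=4)
        acids = tabs.vfa.drop(columns=["cow_id", "period"])
        assert np.allclose(acids.sum(axis=1), 100.0)

    def test_invalid_digestibility_errors(self, small_herd):
        with pytest.raises(ValueError, match="digestibility"):
            simulate.gen_phenotype_tables(
                small_herd, true_digestibility={"DM": 1.2, "OM": 0.7, "NDF": 0.6, "CP": 0.7}
            )
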