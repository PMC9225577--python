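import numpy as np
import pandas as pd
import pytest

from spentmed import (
    NoiseModel,
    generate_truth,
    simulate_monocultures,
    simulate_sequential,
)


class TestGenerateTruth:
    def test_seeded_determinism(self):
        a = generate_truth(n_isolates=8, n_metabolites=60, seed=1)
        b = generate_truth(n_isolates=8, n_metabolites=60, seed=1)
        pd.testing.assert_frame_equal(a.consumption, b.consumption)
        pd.testing.assert_frame_equal(a.secretion, b.secretion)
        pd.testing.assert_series_equal(a.yield_coef, b.yield_coef)

    def test_archetype_richness_ordering(self):
        t = generate_truth(n_isolates=8, n_metabolites=60, seed=2,
                           generalist_support=40, specialist_support=10)
        richness = (t.consumption > 0).sum(axis=1)
        gen = richness[t.groups == "generalist"]
        spec = richness[t.groups == "specialist"]
        assert gen.min() > spec.max()

    def test_pure_competition_has_no_consumable_secretions(self):
        t = generate_truth(seed=3, n_secreted_per_isolate=0)
        assert t.secretion.shape[1] == 0
        assert t.consumability.shape[1] == 0

    def test_infeasible_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            generate_truth(n_metabolites=10, generalist_support=40)


class TestMonocultures:
    def test_table_dimensions(self, small_truth, small_mono):
        n = 3
        n_iso = len(small_truth.isolates)
        n_analytes = len(small_truth.metabolites) + len(
            small_truth.secreted_features
        )
        # spent per isolate + early/late controls + extraction blanks
        assert small_mono.peaks.heights.shape == (
            n_analytes, n_iso * n + 3 * n
        )

    def test_fully_consumed_metabolite_is_exactly_zero_noiseless(self):
        t = generate_truth(n_isolates=2, n_metabolites=4, seed=4,
                           generalist_support=3, specialist_support=2,
                           n_secreted_per_isolate=0)
        t.consumption.iloc[0, 0] = 1.0
        mono = simulate_monocultures(t, NoiseModel(cv=0.0, seed=4))
        iso = t.isolates[0]
        m = t.metabolites[0]
        spent_cols = [s for s in mono.peaks.sample_ids if s.startswith(f"{iso}_spent")]
        assert (mono.peaks.heights.loc[m, spent_cols] == 0.0).all()

    def test_mass_consistency_noiseless(self):
        t = generate_truth(n_isolates=3, n_metabolites=10, seed=5,
                           generalist_support=6, specialist_support=3,
                           n_secreted_per_isolate=0)
        mono = simulate_monocultures(t, NoiseModel(cv=0.0, seed=5))
        ctrl = mono.peaks.heights[["ctrl_early_1"]].to_numpy()[:, 0]
        for iso in t.isolates:
            spent = mono.peaks.heights[f"{iso}_spent_1"].to_numpy()
            expected = ctrl * (1 - t.consumption.loc[iso].to_numpy())
            np.testing.assert_allclose(spent, expected, rtol=1e-12)

    def test_same_seed_identical_outputs(self, small_truth):
        noise = NoiseModel(cv=0.1, seed=99)
        a = simulate_monocultures(small_truth, noise)
        b = simulate_monocultures(small_truth, noise)
        pd.testing.assert_frame_equal(a.peaks.heights, b.peaks.heights)
        pd.testing.assert_frame_equal(a.growth.od, b.growth.od)


class TestSequential:
    @pytest.fixture()
    def seq_setup(self):
        truth = generate_truth(n_isolates=4, n_metabolites=12, seed=6,
                               generalist_support=8, specialist_support=4,
                               n_secreted_per_isolate=2)
        noise = NoiseModel(cv=0.0, seed=6)
        mono = simulate_monocultures(truth, noise)
        return truth, mono, simulate_sequential(mono, noise)

    def test_double_spent_mass_consistency(self, seq_setup):
        truth, mono, seq = seq_setup
        r, i = truth.isolates[2], truth.isolates[0]
        spent = seq.peaks.heights[f"{i}_spent_1"].to_numpy()[: len(truth.metabolites)]
        double = seq.peaks.heights[f"{i}__{r}_double_1"].to_numpy()[
            : len(truth.metabolites)
        ]
        expected = spent * (1 - truth.consumption.loc[r].to_numpy())
        np.testing.assert_allclose(double, expected, rtol=1e-12)

    def test_true_mis_boundary_cases(self):
        truth = generate_truth(n_isolates=2, n_metabolites=6, seed=7,
                               generalist_support=4, specialist_support=2,
                               n_secreted_per_isolate=0)
        # influencer consumes everything the recipient uses
        truth.consumption.iloc[0] = [1, 1, 1, 1, 1, 1]
        truth.consumption.iloc[1] = [0.5, 0.5, 0, 0, 0, 0]
        mis = truth.expected_mis()
        r, i = truth.isolates[1], truth.isolates[0]
        assert mis.loc[r, i] == pytest.approx(-1.0)
        # disjoint supports, no secretion -> no effect
        truth.consumption.iloc[0] = [1, 1, 1, 0, 0, 0]
        truth.consumption.iloc[1] = [0, 0, 0, 0.5, 0.5, 0]
        assert truth.expected_mis().loc[r, i] == pytest.approx(0.0)

    def test_secretion_can_create_facilitation(self):
        truth = generate_truth(n_isolates=2, n_metabolites=4, seed=8,
                               generalist_support=3, specialist_support=2,
                               n_secreted_per_isolate=1,
                               consumability_prob=1.0)
        iso_a, iso_b = truth.isolates
        truth.consumption.loc[iso_a] = [0.9, 0.9, 0, 0]
        truth.consumption.loc[iso_b] = [0.1, 0, 0, 0]
        truth.secretion.loc[iso_a, f"sec_{iso_a}_1"] = 5e6  # 50 substrate units
        truth.consumability.loc[iso_b, f"sec_{iso_a}_1"] = True
        mis = truth.expected_mis()
        assert mis.loc[iso_b, iso_a] > 0

    def test_growth_table_structure(self, seq_setup):
        truth, mono, seq = seq_setup
        n_iso = len(truth.isolates)
        media = set(seq.growth.od["medium"])
        assert "SDM" in media and len(media) == n_iso + 1
        assert seq.growth.respiration is not None
        # true MIS bounded below by -1 for pure resource loss + secretion
        assert (seq.true_mis.fillna(0) >= -1 - 1e-12).all().all()

    def test_respiration_couples_to_growth(self, seq_setup):
        truth, mono, seq = seq_setup
        resp = seq.growth.respiration
        samples = resp[resp["isolate"] != ""]
        drops = samples.assign(drop=lambda d: d["a570_initial"] - d["a570_final"])
        finals = (
            seq.growth.od.groupby(["isolate", "medium", "replicate"])
            .last()["od600"]
            .reset_index()
        )
        merged = drops.merge(finals, on=["isolate", "medium", "replicate"])
        corr = np.corrcoef(merged["drop"], merged["od600"])[0, 1]
        assert corr > 0.5
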