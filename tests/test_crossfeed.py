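import numpy as np
import pandas as pd
import pytest

from spentmed import (
    NoiseModel,
    call_production,
    classify_crossfeeding,
    filter_background,
    generate_truth,
    simulate_monocultures,
    simulate_sequential,
)
from spentmed.crossfeed import _classify
from spentmed.io import PeakHeightTable, TableValidationError

from conftest import toy_metadata


def feature_table(values: dict[str, dict[str, list[float]]]):
    """Build a table from {feature: {group: [replicates]}} with standard
    roles: sdm (medium control), spent (isolate isoI), double (isoI->isoR),
    blank (extraction control)."""
    roles = {
        "sdm": {"role": "medium_control_early", "control_group": "g"},
        "spent": {"role": "spent", "isolate_id": "isoI", "control_group": "g"},
        "double": {"role": "double_spent", "influencer_id": "isoI",
                   "recipient_id": "isoR", "control_group": "g"},
        "blank": {"role": "extraction_control"},
    }
    cols: dict[str, list[float]] = {}
    rows = []
    features = list(values)
    for grp, spec in roles.items():
        n = len(next(iter(values.values()))[grp])
        for k in range(n):
            sid = f"{grp}_{k + 1}"
            cols[sid] = [values[f][grp][k] for f in features]
            rows.append({"sample_id": sid, "replicate": k + 1, **spec})
    table = PeakHeightTable(pd.DataFrame(cols, index=features),
                            table_kind="untargeted")
    return table, toy_metadata(rows)


class TestFilterBackground:
    def test_signal_above_blanks_retained(self):
        table, meta = feature_table({
            "f1": {"sdm": [1000, 1050, 950], "spent": [1000, 1050, 950],
                   "double": [1000, 1050, 950], "blank": [100, 110, 90]},
        })
        assert filter_background(table, meta) == ["f1"]

    def test_feature_identical_to_blanks_removed(self):
        table, meta = feature_table({
            "f1": {"sdm": [100, 110, 90], "spent": [100, 110, 90],
                   "double": [100, 110, 90], "blank": [100, 110, 90]},
        })
        assert filter_background(table, meta) == []

    def test_feature_higher_in_blanks_removed(self):
        table, meta = feature_table({
            "f1": {"sdm": [10, 11, 9], "spent": [10, 11, 9],
                   "double": [10, 11, 9], "blank": [1000, 1100, 900]},
        })
        assert filter_background(table, meta) == []

    def test_requires_extraction_controls(self):
        table, meta = feature_table({
            "f1": {"sdm": [1, 1, 1], "spent": [1, 1, 1],
                   "double": [1, 1, 1], "blank": [1, 1, 1]},
        })
        stripped = meta.frame[meta.frame["role"] != "extraction_control"]
        from spentmed.io import SampleMetadata
        with pytest.raises(TableValidationError, match="extraction_control"):
            filter_background(table, SampleMetadata(stripped.reset_index(drop=True)))


class TestCallProduction:
    def test_percentage_is_produced_over_retained(self):
        values = {}
        for j in range(10):
            up = j < 2  # two features produced by isoI
            values[f"f{j}"] = {
                "sdm": [500, 520, 480],
                "spent": [2000, 2100, 1900] if up else [500, 520, 480],
                "double": [500, 520, 480],
                "blank": [10, 11, 9],
            }
        table, meta = feature_table(values)
        prod = call_production(table, meta)
        assert prod.loc["isoI", "n_retained"] == 10
        assert prod.loc["isoI", "n_produced"] == 2
        assert prod.loc["isoI", "pct_produced"] == pytest.approx(20.0)
        assert set(prod.loc["isoI", "produced"]) == {"f0", "f1"}

    def test_depleted_feature_not_called_produced(self):
        table, meta = feature_table({
            "f1": {"sdm": [1000, 1050, 950], "spent": [100, 105, 95],
                   "double": [100, 105, 95], "blank": [1, 1.1, 0.9]},
        })
        prod = call_production(table, meta)
        assert prod.loc["isoI", "n_produced"] == 0


class TestClassifyRules:
    @pytest.mark.parametrize(
        "dir1, dir2, expected",
        [
            ("up", "down", "cross_fed"),
            ("down", "down", "sequentially_depleted"),
            ("up", "up", "recipient_produced"),
            ("down", "up", "recipient_produced"),
            ("unchanged", "up", "recipient_produced"),
            ("up", "unchanged", "produced_not_consumed"),
            ("unchanged", "unchanged", "unchanged"),
            ("down", "unchanged", "unchanged"),
            ("unchanged", "down", "unchanged"),
        ],
    )
    def test_taxonomy_closure(self, dir1, dir2, expected):
        assert _classify(dir1, dir2) == expected

    def test_crossfed_trajectory(self):
        table, meta = feature_table({
            "f1": {"sdm": [100, 105, 95], "spent": [400, 420, 380],
                   "double": [150, 155, 145], "blank": [1, 1.1, 0.9]},
        })
        res = classify_crossfeeding(table, meta)
        assert res.calls["class"].tolist() == ["cross_fed"]

    def test_sequential_depletion_trajectory(self):
        table, meta = feature_table({
            "f1": {"sdm": [100, 105, 95], "spent": [40, 42, 38],
                   "double": [10, 10.5, 9.5], "blank": [0.5, 0.55, 0.45]},
        })
        res = classify_crossfeeding(table, meta)
        assert res.calls["class"].tolist() == ["sequentially_depleted"]

    def test_no_change_either_leg(self):
        table, meta = feature_table({
            "f1": {"sdm": [100, 105, 95], "spent": [100, 106, 94],
                   "double": [101, 104, 95], "blank": [1, 1.1, 0.9]},
        })
        res = classify_crossfeeding(table, meta)
        assert res.calls["class"].tolist() == ["unchanged"]

    def test_summary_percentages_sum_to_hundred(self):
        values = {
            "f1": {"sdm": [100, 105, 95], "spent": [400, 420, 380],
                   "double": [150, 155, 145], "blank": [1, 1.1, 0.9]},
            "f2": {"sdm": [100, 105, 95], "spent": [40, 42, 38],
                   "double": [10, 10.5, 9.5], "blank": [1, 1.1, 0.9]},
            "f3": {"sdm": [100, 105, 95], "spent": [101, 104, 96],
                   "double": [99, 103, 97], "blank": [1, 1.1, 0.9]},
        }
        table, meta = feature_table(values)
        res = classify_crossfeeding(table, meta)
        assert res.summary.sum(axis=1).to_numpy() == pytest.approx(100.0)

    def test_feature_order_permutation_permutes_output(self):
        values = {
            "f1": {"sdm": [100, 105, 95], "spent": [400, 420, 380],
                   "double": [150, 155, 145], "blank": [1, 1.1, 0.9]},
            "f2": {"sdm": [100, 105, 95], "spent": [40, 42, 38],
                   "double": [10, 10.5, 9.5], "blank": [1, 1.1, 0.9]},
        }
        table, meta = feature_table(values)
        res1 = classify_crossfeeding(table, meta)
        flipped = PeakHeightTable(table.heights.iloc[::-1], "untargeted")
        res2 = classify_crossfeeding(flipped, meta)
        merged = res1.calls.set_index("feature")["class"]
        for f, cls in res2.calls.set_index("feature")["class"].items():
            assert merged[f] == cls


class TestPlantedRecovery:
    def test_noiseless_precision_and_recall_are_perfect(self):
        truth = generate_truth(n_isolates=4, n_metabolites=15, seed=21,
                               generalist_support=10, specialist_support=4,
                               n_secreted_per_isolate=3)
        noise = NoiseModel(cv=0.0, seed=21)
        mono = simulate_monocultures(truth, noise)
        seq = simulate_sequential(mono, noise)
        retained = filter_background(seq.peaks, seq.metadata)
        res = classify_crossfeeding(seq.peaks, seq.metadata, retained=retained)
        calls = res.calls.set_index(["recipient", "influencer", "feature"])["class"]
        planted = {
            (r, i, f)
            for r in truth.isolates for i in truth.isolates if r != i
            for f in truth.secreted_features
            if truth.secretion.loc[i, f] > 0 and truth.consumability.loc[r, f]
        }
        called = {
            (rec, inf, f)
            for (rec, inf, f), cls in calls.items() if cls == "cross_fed"
        }
        assert called == planted
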