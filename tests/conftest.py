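import numpy as np
import pandas as pd
import pytest

from spentmed import NoiseModel, generate_truth, simulate_monocultures
from spentmed.io import GrowthTable, PeakHeightTable, SampleMetadata


@pytest.fixture(scope="session")
def small_truth():
    return generate_truth(n_isolates=4, n_metabolites=20, seed=11,
                          generalist_support=12, specialist_support=5,
                          n_secreted_per_isolate=2)


@pytest.fixture(scope="session")
def small_mono(small_truth):
    return simulate_monocultures(small_truth, NoiseModel(cv=0.1, seed=11))


def toy_metadata(rows):
    defaults = {
        "isolate_id": None, "role": "spent", "influencer_id": None,
        "recipient_id": None, "replicate": 1, "ionization_mode": "positive",
        "control_group": None,
    }
    return SampleMetadata(pd.DataFrame([{**defaults, **r} for r in rows]))


@pytest.fixture
def toy_targeted():
    """5 metabolites x 9 samples: one isolate in triplicate plus early and
    late control triplicates; isoA halves m1 and fully depletes m2."""
    rng = np.random.default_rng(0)
    base = np.array([100.0, 200.0, 50.0, 80.0, 120.0])
    cols = {}
    rows = []
    for k in range(1, 4):
        cols[f"spent_{k}"] = base * np.array([0.5, 0.0, 1.0, 1.0, 1.0]) * (
            1 + 0.01 * rng.normal(size=5)
        )
        rows.append({"sample_id": f"spent_{k}", "isolate_id": "isoA",
                     "role": "spent", "replicate": k, "control_group": "early"})
    for k in range(1, 4):
        cols[f"early_{k}"] = base * (1 + 0.01 * rng.normal(size=5))
        rows.append({"sample_id": f"early_{k}", "role": "medium_control_early",
                     "replicate": k, "control_group": "early"})
        cols[f"late_{k}"] = base * (1 + 0.01 * rng.normal(size=5))
        rows.append({"sample_id": f"late_{k}", "role": "medium_control_late",
                     "replicate": k, "control_group": "late"})
    heights = pd.DataFrame(cols, index=[f"m{j}" for j in range(1, 6)])
    return PeakHeightTable(heights.clip(lower=0)), toy_metadata(rows)


@pytest.fixture
def toy_growth():
    t = np.linspace(0, 48, 97)
    K, N0, r = 0.8, 0.02, 0.5
    od = K / (1 + ((K - N0) / N0) * np.exp(-r * t))
    rows = []
    for medium, scale in (("SDM", 1.0), ("isoB", 0.5)):
        for rep in (1, 2, 3):
            rows.append(pd.DataFrame({
                "isolate": "isoA", "medium": medium, "replicate": rep,
                "time_h": t, "od600": od * scale,
            }))
            rows.append(pd.DataFrame({
                "isolate": "", "medium": medium, "replicate": rep,
                "time_h": t, "od600": 0.005,
            }))
    resp = pd.DataFrame([
        {"isolate": "isoA", "medium": "SDM", "replicate": k,
         "a570_initial": 1.0, "a570_final": 0.6} for k in (1, 2, 3)
    ] + [
        {"isolate": "isoA", "medium": "isoB", "replicate": k,
         "a570_initial": 1.0, "a570_final": 0.8} for k in (1, 2, 3)
    ] + [
        {"isolate": "", "medium": m, "replicate": k,
         "a570_initial": 1.0, "a570_final": 0.95}
        for m in ("SDM", "isoB") for k in (1, 2, 3)
    ])
    return GrowthTable(pd.concat(rows, ignore_index=True), resp)
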