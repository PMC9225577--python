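"""Per-isolate substrate-utilization metrics.

Three summaries of a depletion profile p (fractions in [0, 1] over the
medium metabolites):

* richness   -- number of substrates significantly depleted;
* abundance  -- sum of the depletion percentages (one fully depleted
  substrate contributes 100);
* diversity  -- inverse Simpson index 1 / sum(pi_m^2) with pi_m the
  depletion fractions normalized over the significant support.  D equals
  the richness for perfectly even utilization and approaches 1 as use
  concentrates on a single substrate; it is undefined on an empty support.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan

import numpy as np
import pandas as pd


@dataclass
class SubstrateMetrics:
    richness: int
    abundance: float  # summed percent depletion
    diversity: float  # inverse Simpson; NaN on empty support


def substrate_metrics(profile: pd.Series | np.ndarray) -> SubstrateMetrics:
    """Richness, abundance and inverse-Simpson diversity of one profile."""
    p = np.asarray(profile, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("depletion fractions must lie in [0, 1]")
    support = p[p > 0]
    richness = int(support.size)
    abundance = float(100.0 * support.sum())
    if richness == 0:
        return SubstrateMetrics(0, 0.0, nan)
    pi = support / support.sum()
    diversity = float(1.0 / np.square(pi).sum())
    return SubstrateMetrics(richness, abundance, diversity)


def metrics_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Metrics for every isolate column of a profile matrix."""
    rows = []
    for iso in profiles.columns:
        m = substrate_metrics(profiles[iso])
        rows.append(
            {"isolate": iso, "richness": m.richness,
             "abundance": m.abundance, "diversity": m.diversity}
        )
    return pd.DataFrame(rows).set_index("isolate")
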