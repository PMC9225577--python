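"""Significance-gated relative fold changes of defined-medium metabolites.

For each metabolite and isolate the spent-medium replicates are compared
with the matched uninoculated-medium control replicates.  The relative fold
change is mean(spent)/mean(control) - 1 when the comparison is significant,
and exactly 0 otherwise -- the gate that keeps measurement noise out of the
downstream utilization profiles and overlap predictions.

Comparison families are formed per control group and per metabolite: every
isolate sampled against the same early (or late) control enters one
Dunnett's many-to-one test, which controls the familywise error across the
isolates sharing that control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PeakHeightTable, SampleMetadata, TableValidationError
from .stats import dunnett_pvalues_rows


@dataclass
class FoldChangeMatrix:
    """Gated relative fold changes, metabolites x isolates.

    ``fc`` entries lie in [-1, inf): negative means depletion, positive means
    production, exactly 0 means no significant change.  ``pvalues`` holds the
    Dunnett p-value behind each gate; ``undefined`` flags cells where the
    control mean was 0 with nonzero spent signal (the ratio is meaningless).
    """

    fc: pd.DataFrame
    pvalues: pd.DataFrame
    alpha: float = 0.05
    n_replicates: pd.DataFrame | None = None
    undefined: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        gate_broken = (self.pvalues > self.alpha) & (self.fc != 0) & self.fc.notna()
        if gate_broken.to_numpy().any():
            raise ValueError("fold change nonzero where p > alpha")


def gated_fold_changes(
    table: PeakHeightTable,
    meta: SampleMetadata,
    alpha: float = 0.05,
    log_transform: bool = False,
    missing_policy: str = "drop",
) -> FoldChangeMatrix:
    """Compute significance-gated fold changes for every (metabolite, isolate).

    Parameters
    ----------
    table
        Targeted peak-height table (metabolites x samples).
    meta
        Sample metadata; spent samples are matched to their controls through
        ``control_group``.
    alpha
        Significance level of the gate.
    log_transform
        Run the tests on log10(height + 1) instead of raw heights.  The fold
        change itself is always computed from raw group means.
    missing_policy
        "drop" removes metabolites with any missing height; "impute"
        replaces missing values with half the metabolite's observed minimum.
    """
    if missing_policy == "drop":
        table = table.drop_missing()
    elif missing_policy == "impute":
        table = table.impute_half_minimum()
    else:
        raise ValueError(f"unknown missing policy {missing_policy!r}")

    meta.validate_control_links()
    heights = table.heights
    spent = meta.samples_with_role("spent")
    if spent.empty:
        raise TableValidationError("no spent samples in metadata")
    isolates = sorted(spent["isolate_id"].unique())
    metabolites = table.analyte_ids

    fc = pd.DataFrame(np.nan, index=metabolites, columns=isolates)
    pvals = pd.DataFrame(np.nan, index=metabolites, columns=isolates)
    nreps = pd.DataFrame(0, index=metabolites, columns=isolates, dtype=int)
    undef = pd.DataFrame(False, index=metabolites, columns=isolates)

    test = np.log10(heights + 1.0) if log_transform else heights

    for group, grp_spent in spent.groupby("control_group"):
        controls = meta.controls_for_group(group)
        ctrl_ids = [s for s in controls["sample_id"] if s in heights.columns]
        if len(ctrl_ids) < 2:
            raise TableValidationError(
                f"control_group {group!r}: fewer than 2 control samples in table"
            )
        family = sorted(grp_spent["isolate_id"].unique())
        member_ids = {
            iso: [
                s
                for s in grp_spent.loc[grp_spent["isolate_id"] == iso, "sample_id"]
                if s in heights.columns
            ]
            for iso in family
        }
        for iso, ids in member_ids.items():
            if len(ids) < 2:
                raise TableValidationError(
                    f"isolate {iso!r}: fewer than 2 spent replicates"
                )

        ctrl_test = test[ctrl_ids].to_numpy(dtype=float)
        treat_test = [test[member_ids[iso]].to_numpy(dtype=float) for iso in family]
        p = dunnett_pvalues_rows(treat_test, ctrl_test)  # metabolites x family
        ctrl_mean = heights[ctrl_ids].mean(axis=1).to_numpy()
        for j, iso in enumerate(family):
            spent_mean = heights[member_ids[iso]].mean(axis=1).to_numpy()
            pvals[iso] = p[:, j]
            nreps[iso] = len(member_ids[iso])
            gated = p[:, j] > alpha
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = spent_mean / ctrl_mean - 1.0
            col = np.where(gated, 0.0, ratio)
            bad = ~gated & (ctrl_mean == 0.0)
            col = np.where(bad & (spent_mean == 0.0), 0.0, col)
            undef[iso] = bad & (spent_mean != 0.0)
            col = np.where(undef[iso], np.nan, col)
            fc[iso] = col

    return FoldChangeMatrix(fc, pvals, alpha=alpha, n_replicates=nreps, undefined=undef)


def utilization_profiles(fc: FoldChangeMatrix) -> pd.DataFrame:
    """Depletion fractions p_{m,r} in [0, 1], metabolites x isolates.

    p_{m,r} = -FC_{m,r} for significantly depleted metabolites and 0
    otherwise; production (positive fold change) does not enter the profile.
    """
    p = (-fc.fc).clip(lower=0.0)
    return p.fillna(0.0)


def profile_support(profiles: pd.DataFrame, isolate: str) -> list[str]:
    """Metabolites significantly depleted by one isolate."""
    col = profiles[isolate]
    return list(col.index[col > 0])
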