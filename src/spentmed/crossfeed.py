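"""Untargeted feature filtering, production calls and cross-feeding patterns.

Untargeted LC-MS features are first screened against extraction blanks:
only features significantly higher in at least one sample group than in the
blanks are real signal.  Production in a monoculture is a significant
increase of a retained feature in the isolate's spent medium over the
defined-medium control.

Cross-feeding is inferred from the trajectory of a feature across the
sequential growth experiment: a feature that rises in the influencer's
spent medium (the influencer secreted it) and then falls in the double-
spent medium (the recipient consumed it) displays the cross-feeding
pattern.  A feature that falls on both legs was sequentially depleted by
both isolates -- evidence of resource competition.  The remaining classes
close the taxonomy so that every retained feature lands in exactly one
bin:

* ``cross_fed``              up on leg 1, down on leg 2;
* ``sequentially_depleted``  down on both legs;
* ``recipient_produced``     up on leg 2 (and not cross_fed);
* ``produced_not_consumed``  up on leg 1, leg 2 unchanged;
* ``unchanged``              everything else.

Leg 1 compares spent_i with the matched defined-medium control; leg 2
compares double_spent_ri with the abiotic (uninoculated, incubated) spent
control for influencer i when present, else with the spent_i samples
themselves.  Direction tests are two-sided with the direction read from the
sign of the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PeakHeightTable, SampleMetadata, TableValidationError
from .stats import dunnett_pvalues_rows, welch_pvalues_rows

CLASSES = [
    "cross_fed",
    "sequentially_depleted",
    "recipient_produced",
    "produced_not_consumed",
    "unchanged",
]


def _biological_groups(meta: SampleMetadata, table: PeakHeightTable) -> dict:
    """Replicate sample groups (excluding extraction blanks) present in the
    table, keyed by (role, isolate, influencer, recipient)."""
    groups: dict[tuple, list[str]] = {}
    in_table = set(table.sample_ids)
    for _, row in meta.frame.iterrows():
        if row["role"] == "extraction_control" or row["sample_id"] not in in_table:
            continue
        key = (
            row["role"],
            row["isolate_id"] if pd.notna(row["isolate_id"]) else "",
            row["influencer_id"] if pd.notna(row["influencer_id"]) else "",
            row["recipient_id"] if pd.notna(row["recipient_id"]) else "",
        )
        groups.setdefault(key, []).append(row["sample_id"])
    return {k: v for k, v in groups.items() if len(v) >= 2}


def filter_background(
    table: PeakHeightTable, meta: SampleMetadata, alpha: float = 0.05
) -> list[str]:
    """Features significantly above the extraction blanks in >=1 sample group.

    One Dunnett family per feature (every biological group against the
    blanks); a feature is retained when at least one group is significant
    with a mean above the blank mean.
    """
    blanks = meta.samples_with_role("extraction_control")
    blank_ids = [s for s in blanks["sample_id"] if s in table.sample_ids]
    if len(blank_ids) < 2:
        raise TableValidationError("need >=2 extraction_control samples")
    groups = _biological_groups(meta, table)
    if not groups:
        raise TableValidationError("no replicated sample groups in table")
    heights = table.heights
    group_ids = list(groups.values())
    blank = heights[blank_ids].to_numpy(dtype=float)
    treats = [heights[ids].to_numpy(dtype=float) for ids in group_ids]
    p = dunnett_pvalues_rows(treats, blank)  # features x groups
    higher = np.stack(
        [t.mean(axis=1) > blank.mean(axis=1) for t in treats], axis=1
    )
    keep = ((p <= alpha) & higher).any(axis=1)
    return [f for f, k in zip(table.analyte_ids, keep) if k]


def call_production(
    table: PeakHeightTable,
    meta: SampleMetadata,
    alpha: float = 0.05,
    retained: list[str] | None = None,
) -> pd.DataFrame:
    """Per-isolate produced-feature calls among retained features.

    A feature is produced by an isolate when its abundance is significantly
    higher in the isolate's spent medium than in the matched defined-medium
    control.  Returns one row per isolate with the produced feature list,
    count and percentage of retained features.
    """
    if retained is None:
        retained = filter_background(table, meta, alpha)
    if not retained:
        raise TableValidationError("no retained features to test")
    heights = table.heights.loc[retained]
    spent = meta.samples_with_role("spent")
    rows = []
    for (group, iso), grp in spent.groupby(["control_group", "isolate_id"]):
        ctrl = meta.controls_for_group(group)
        ctrl_ids = [s for s in ctrl["sample_id"] if s in heights.columns]
        ids = [s for s in grp["sample_id"] if s in heights.columns]
        if len(ctrl_ids) < 2:
            raise TableValidationError(
                f"isolate {iso!r}: no matched medium control in table"
            )
        sp = heights[ids].to_numpy(dtype=float)
        ct = heights[ctrl_ids].to_numpy(dtype=float)
        p = welch_pvalues_rows(sp, ct)
        up = (p <= alpha) & (sp.mean(axis=1) > ct.mean(axis=1))
        produced = [f for f, flag in zip(retained, up) if flag]
        rows.append(
            {
                "isolate": iso,
                "n_retained": len(retained),
                "n_produced": len(produced),
                "pct_produced": 100.0 * len(produced) / len(retained),
                "produced": produced,
            }
        )
    return pd.DataFrame(rows).set_index("isolate")


def _directions(
    a: np.ndarray, b: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise (direction of a vs b, p-value, fold change).

    Direction is "unchanged" iff p > alpha, otherwise the sign of the mean
    difference.
    """
    p = welch_pvalues_rows(a, b)
    am, bm = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(bm > 0, am / bm - 1.0, np.nan)
    dirs = np.where(p > alpha, "unchanged", np.where(am > bm, "up", "down"))
    return dirs, p, fc


def _classify(dir1: str, dir2: str) -> str:
    if dir1 == "up" and dir2 == "down":
        return "cross_fed"
    if dir1 == "down" and dir2 == "down":
        return "sequentially_depleted"
    if dir2 == "up":
        return "recipient_produced"
    if dir1 == "up":  # leg 2 unchanged
        return "produced_not_consumed"
    return "unchanged"


@dataclass
class CrossFeedResult:
    """Per-feature class calls and per-pair summary percentages."""

    calls: pd.DataFrame  # influencer, recipient, feature, mode, class, p1, p2, fc1, fc2
    summary: pd.DataFrame  # per (recipient, influencer, mode): pct per class


def classify_crossfeeding(
    table: PeakHeightTable,
    meta: SampleMetadata,
    alpha: float = 0.05,
    retained: list[str] | None = None,
) -> CrossFeedResult:
    """Classify retained features for every (influencer, recipient) pair."""
    if retained is None:
        retained = filter_background(table, meta, alpha)
    if not retained:
        raise TableValidationError("no retained features to classify")
    heights = table.heights.loc[retained]
    df = meta.frame
    in_table = set(table.sample_ids)

    def ids_of(mask) -> list[str]:
        return [s for s in df.loc[mask, "sample_id"] if s in in_table]

    doubles = df[df["role"] == "double_spent"]
    if doubles.empty:
        raise TableValidationError("no double_spent samples in metadata")

    records = []
    for (inf, rec), grp in doubles.groupby(["influencer_id", "recipient_id"]):
        mode = grp["ionization_mode"].iloc[0]
        double_ids = [s for s in grp["sample_id"] if s in in_table]
        spent_rows = df[(df["role"] == "spent") & (df["isolate_id"] == inf)]
        spent_ids = [s for s in spent_rows["sample_id"] if s in in_table]
        if len(spent_ids) < 2 or len(double_ids) < 2:
            raise TableValidationError(
                f"pair ({rec!r}, {inf!r}): missing spent or double-spent replicates"
            )
        ctrl_group = spent_rows["control_group"].iloc[0]
        sdm_ids = [
            s
            for s in meta.controls_for_group(ctrl_group)["sample_id"]
            if s in in_table
        ]
        if len(sdm_ids) < 2:
            raise TableValidationError(
                f"pair ({rec!r}, {inf!r}): missing defined-medium control"
            )
        # leg-2 reference: abiotic spent control when available, else spent_i
        abiotic = ids_of(
            (df["role"] == "uninoculated_spent_control")
            & (df["influencer_id"] == inf)
        )
        ref2_ids = abiotic if len(abiotic) >= 2 else spent_ids

        sp = heights[spent_ids].to_numpy(dtype=float)
        sdm = heights[sdm_ids].to_numpy(dtype=float)
        dbl = heights[double_ids].to_numpy(dtype=float)
        ref2 = heights[ref2_ids].to_numpy(dtype=float)
        dir1, p1, fc1 = _directions(sp, sdm, alpha)
        dir2, p2, fc2 = _directions(dbl, ref2, alpha)
        for j, f in enumerate(retained):
            records.append(
                {
                    "influencer": inf, "recipient": rec, "feature": f,
                    "mode": mode, "class": _classify(dir1[j], dir2[j]),
                    "p1": p1[j], "p2": p2[j], "fc1": fc1[j], "fc2": fc2[j],
                }
            )

    calls = pd.DataFrame(records)
    counts = (
        calls.groupby(["recipient", "influencer", "mode"])["class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=CLASSES, fill_value=0)
    )
    summary = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    return CrossFeedResult(calls, summary)


def recipient_summary(result: CrossFeedResult, cls: str = "cross_fed") -> pd.DataFrame:
    """Mean +/- sd percentage of one class per recipient across influencers."""
    s = result.summary[cls]
    g = s.groupby(level="recipient")
    return pd.DataFrame({"mean_pct": g.mean(), "sd_pct": g.std(ddof=1)})
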