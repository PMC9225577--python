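"""Reading, validation and writing of the pipeline's tabular formats.

All tables are UTF-8 CSV with a header row and "." as the decimal mark.
Peak-height tables are analytes (rows) x samples (columns), with the first
column holding the analyte id (a metabolite name for targeted data, or an
``m/z@rt`` feature id for untargeted data).  Missing peak heights are empty
cells and are kept as NaN in memory -- never silently converted to zero.
Untargeted data are one table per ionization mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_ROLES = frozenset(
    {
        "spent",
        "double_spent",
        "medium_control_early",
        "medium_control_late",
        "extraction_control",
        "sdm_culture_control",
        "uninoculated_spent_control",
    }
)

CONTROL_ROLES = frozenset(
    {"medium_control_early", "medium_control_late", "extraction_control",
     "uninoculated_spent_control"}
)

VALID_MODES = frozenset({"positive", "negative", "not_applicable"})

METADATA_COLUMNS = [
    "sample_id",
    "isolate_id",
    "role",
    "influencer_id",
    "recipient_id",
    "replicate",
    "ionization_mode",
    "control_group",
]


class TableValidationError(ValueError):
    """A tabular input violated one of the documented contracts."""


@dataclass
class SampleMetadata:
    """Per-sample annotations linking measurements to the experimental design.

    ``control_group`` ties each biological sample to its matched uninoculated
    control samples (the early control for fast growers, the late control for
    slow growers); the mapping is explicit metadata, never inferred.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise TableValidationError(f"metadata missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise TableValidationError(f"duplicate sample ids: {dupes}")
        bad_roles = sorted(set(df["role"]) - VALID_ROLES)
        if bad_roles:
            raise TableValidationError(f"unknown role value(s): {bad_roles}")
        bad_modes = sorted(set(df["ionization_mode"]) - VALID_MODES)
        if bad_modes:
            raise TableValidationError(f"unknown ionization mode(s): {bad_modes}")
        if (pd.to_numeric(df["replicate"], errors="coerce") <= 0).any():
            raise TableValidationError("replicate must be a positive integer")
        ds = df[df["role"] == "double_spent"]
        if ds["influencer_id"].isna().any() or ds["recipient_id"].isna().any():
            raise TableValidationError(
                "double_spent samples must carry influencer_id and recipient_id"
            )
        self.frame = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples_with_role(self, role: str) -> pd.DataFrame:
        return self.frame[self.frame["role"] == role]

    def controls_for_group(self, group: str) -> pd.DataFrame:
        """Matched uninoculated-medium controls for a control group."""
        df = self.frame
        mask = (df["control_group"] == group) & df["role"].isin(
            ("medium_control_early", "medium_control_late")
        )
        return df[mask]

    def validate_control_links(self) -> None:
        """Every non-control biological sample must resolve to >=2 controls."""
        df = self.frame
        bio = df[~df["role"].isin(CONTROL_ROLES) & df["control_group"].notna()]
        for group in bio["control_group"].unique():
            if len(self.controls_for_group(group)) < 2:
                raise TableValidationError(
                    f"control_group {group!r} resolves to fewer than 2 "
                    "medium-control samples"
                )


@dataclass
class PeakHeightTable:
    """LC-MS peak heights, analytes x samples.

    ``heights`` keeps analyte ids on the index and sample ids on the columns;
    entries are non-negative intensities in arbitrary units, NaN where the
    peak was not observed.
    """

    heights: pd.DataFrame
    table_kind: str = "targeted"

    def __post_init__(self) -> None:
        if self.table_kind not in ("targeted", "untargeted"):
            raise TableValidationError(f"unknown table_kind {self.table_kind!r}")
        if self.heights.index.duplicated().any():
            dupes = self.heights.index[self.heights.index.duplicated()].tolist()
            raise TableValidationError(f"duplicate analyte id(s): {dupes}")
        vals = self.heights.to_numpy(dtype=float)
        if (vals[np.isfinite(vals)] < 0).any():
            raise TableValidationError("negative peak height")

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.heights.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.heights.columns)

    def subset_analytes(self, analytes) -> "PeakHeightTable":
        return PeakHeightTable(self.heights.loc[list(analytes)], self.table_kind)

    def drop_missing(self) -> "PeakHeightTable":
        """Drop analytes with any missing height (default missing policy)."""
        keep = self.heights.notna().all(axis=1)
        return PeakHeightTable(self.heights[keep], self.table_kind)

    def impute_half_minimum(self) -> "PeakHeightTable":
        """Replace missing heights with half the analyte's observed minimum."""
        filled = self.heights.apply(
            lambda row: row.fillna(row.min(skipna=True) / 2.0), axis=1
        )
        return PeakHeightTable(filled, self.table_kind)


@dataclass
class GrowthTable:
    """OD600 time series, optionally paired with MicroResp A570 readings.

    ``od`` is long format with columns (isolate, medium, replicate, time_h,
    od600); an empty ``isolate`` marks an uninoculated control series for that
    medium.  ``respiration`` has (isolate, medium, replicate, a570_initial,
    a570_final) with the same control convention.
    """

    od: pd.DataFrame
    respiration: pd.DataFrame | None = None

    OD_COLUMNS = ["isolate", "medium", "replicate", "time_h", "od600"]
    RESP_COLUMNS = ["isolate", "medium", "replicate", "a570_initial", "a570_final"]

    def __post_init__(self) -> None:
        df = self.od
        missing = [c for c in self.OD_COLUMNS if c not in df.columns]
        if missing:
            raise TableValidationError(f"growth table missing columns: {missing}")
        if (df["od600"] < 0).any():
            raise TableValidationError("negative OD600 reading")
        df = df.copy()
        df["isolate"] = df["isolate"].fillna("")
        df = df.sort_values(
            ["isolate", "medium", "replicate", "time_h"], kind="mergesort"
        ).reset_index(drop=True)
        for key, grp in df.groupby(["isolate", "medium", "replicate"], sort=False):
            t = grp["time_h"].to_numpy()
            if len(t) > 1 and (np.diff(t) <= 0).any():
                raise TableValidationError(f"non-increasing time points in series {key}")
        self.od = df
        if self.respiration is not None:
            rdf = self.respiration
            missing = [c for c in self.RESP_COLUMNS if c not in rdf.columns]
            if missing:
                raise TableValidationError(
                    f"respiration table missing columns: {missing}"
                )
            if (rdf[["a570_initial", "a570_final"]] < 0).to_numpy().any():
                raise TableValidationError("negative A570 reading")
            rdf = rdf.copy()
            rdf["isolate"] = rdf["isolate"].fillna("")
            self.respiration = rdf.reset_index(drop=True)

    def series(self, isolate: str, medium: str, replicate: int) -> pd.DataFrame:
        df = self.od
        return df[
            (df["isolate"] == isolate)
            & (df["medium"] == medium)
            & (df["replicate"] == replicate)
        ]

    def n_series(self) -> int:
        return self.od.groupby(["isolate", "medium", "replicate"]).ngroups


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, dtype={"sample_id": str})
    return SampleMetadata(df)


def read_peak_table(
    path: str | Path,
    metadata_path: str | Path,
    table_kind: str = "targeted",
) -> tuple[PeakHeightTable, SampleMetadata]:
    """Read a peak-height CSV and its sample metadata, cross-validating ids."""
    meta = read_metadata(metadata_path)
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    table = PeakHeightTable(df.astype(float), table_kind=table_kind)
    unknown = set(table.sample_ids) - set(meta.sample_ids)
    if unknown:
        raise TableValidationError(
            f"sample(s) in peak table absent from metadata: {sorted(unknown)}"
        )
    return table, meta


def write_peak_table(table: PeakHeightTable, path: str | Path) -> None:
    write_matrix(table.heights, path)


def read_growth_table(
    path: str | Path, respiration_path: str | Path | None = None
) -> GrowthTable:
    od = pd.read_csv(path)
    resp = pd.read_csv(respiration_path) if respiration_path is not None else None
    return GrowthTable(od, resp)


def write_growth_table(growth: GrowthTable, path: str | Path,
                       respiration_path: str | Path | None = None) -> None:
    growth.od.to_csv(path, index=False, lineterminator="\n")
    if respiration_path is not None and growth.respiration is not None:
        growth.respiration.to_csv(respiration_path, index=False, lineterminator="\n")


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled result matrix as CSV; missing entries are empty cells.

    Repeated writes of the same object are byte-identical.
    """
    matrix.to_csv(path, na_rep="", float_format="%.12g", lineterminator="\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
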