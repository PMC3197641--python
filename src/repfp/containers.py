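"""Core in-memory containers for replication-timing data.

Replication timing is measured as the log2 ratio of a locus's abundance in
early- versus late-S-phase nascent DNA ("timing ratio"; positive = early
replicating).  Per-probe profiles are averaged into fixed-size genomic
windows, giving a windows x samples matrix that every downstream stage
(region selection, classification, PCR verification) operates on.

Coordinates are 0-based half-open throughout (BED/bedGraph convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

PROBE_COLUMNS = ["chrom", "start", "end", "value"]
LABEL_COLUMNS = ["sample_id", "cell_type", "replicate"]


@dataclass
class ProbeProfile:
    """One sample's per-probe log2(early/late) timing ratios along the genome.

    ``records`` holds one row per probe with columns chrom/start/end/value,
    sorted by (chrom, start).  Probe midpoints decide window membership.
    """

    sample_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in PROBE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"probe records missing columns {missing}")
        df = df[PROBE_COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["value"] = df["value"].astype(float)
        if len(df) == 0:
            raise ValueError(f"probe profile {self.sample_id!r} has no records")
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"probe with start >= end at row {bad}")
        if not np.isfinite(df["value"]).all():
            raise ValueError("non-finite timing values in probe profile")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self.records = df

    @property
    def midpoints(self) -> pd.Series:
        return (self.records["start"] + self.records["end"]) / 2.0

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.records["chrom"].unique())

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeProfile):
            return NotImplemented
        return self.sample_id == other.sample_id and self.records.equals(other.records)


def validate_labels(labels: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-label table and return a normalized copy.

    Required columns: sample_id, cell_type, replicate.  Extra columns are
    treated as grouping schemes (e.g. a potency column with values
    pluripotent/committed).  (cell_type, replicate) pairs must be unique.
    """
    missing = [c for c in LABEL_COLUMNS if c not in labels.columns]
    if missing:
        raise ValueError(f"label table missing columns {missing}")
    out = labels.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    if out["sample_id"].duplicated().any():
        dup = out.loc[out["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in label table")
    pairs = out[["cell_type", "replicate"]].apply(tuple, axis=1)
    if pairs.duplicated().any():
        raise ValueError("duplicate (cell_type, replicate) pair in label table")
    return out.reset_index(drop=True)


@dataclass
class WindowMatrix:
    """Regions x samples table of window-averaged timing values.

    ``windows``: one row per genomic window with columns
    region_id/chrom/start/end/partial (partial flags truncated terminal
    windows).  ``labels``: sample-label table (see :func:`validate_labels`).
    ``values``: DataFrame indexed by region_id with one column per
    sample_id; missing entries are NaN.
    """

    windows: pd.DataFrame
    labels: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = validate_labels(self.labels)
        w = self.windows.copy()
        for col in ("region_id", "chrom", "start", "end"):
            if col not in w.columns:
                raise ValueError(f"windows table missing column {col!r}")
        if "partial" not in w.columns:
            w["partial"] = False
        w["region_id"] = w["region_id"].astype(str)
        if w["region_id"].duplicated().any():
            raise ValueError("duplicate region_id in windows table")
        w = w.reset_index(drop=True)
        self.windows = w

        v = self.values.copy()
        v.index = v.index.astype(str)
        if list(v.index) != list(w["region_id"]):
            raise ValueError("values index does not match windows region_ids")
        sample_ids = list(self.labels["sample_id"])
        if sorted(v.columns) != sorted(sample_ids):
            raise ValueError(
                "values columns do not match labelled samples: "
                f"{sorted(v.columns)} vs {sorted(sample_ids)}"
            )
        self.values = v[sample_ids].astype(float)

    # -- views -------------------------------------------------------------

    @property
    def region_ids(self) -> list[str]:
        return list(self.windows["region_id"])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels["sample_id"])

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def complete_case(self) -> "WindowMatrix":
        """Restrict to windows with a value in every sample."""
        keep = ~self.values.isna().any(axis=1)
        return WindowMatrix(
            windows=self.windows[keep.to_numpy()].reset_index(drop=True),
            labels=self.labels,
            values=self.values.loc[keep],
        )

    def restrict(self, region_ids: list[str]) -> "WindowMatrix":
        """Restrict to the given regions, preserving matrix window order."""
        wanted = set(region_ids)
        unknown = wanted - set(self.region_ids)
        if unknown:
            raise KeyError(f"unknown region ids: {sorted(unknown)[:5]}")
        keep = self.windows["region_id"].isin(wanted).to_numpy()
        return WindowMatrix(
            windows=self.windows[keep].reset_index(drop=True),
            labels=self.labels,
            values=self.values.loc[keep],
        )

    def scheme_values(self, scheme: str) -> pd.Series:
        """Per-sample group value under a labelling scheme (e.g. cell_type)."""
        if scheme not in self.labels.columns:
            raise KeyError(f"no labelling scheme {scheme!r} in label table")
        s = self.labels.set_index("sample_id")[scheme]
        if s.isna().any():
            missing = s.index[s.isna()][0]
            raise ValueError(f"sample {missing!r} unlabelled under {scheme!r}")
        return s

    def equals(self, other: "WindowMatrix") -> bool:
        return (
            self.windows.equals(other.windows)
            and self.labels.equals(other.labels)
            and self.values.equals(other.values)
        )


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
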