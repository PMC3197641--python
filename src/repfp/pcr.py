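"""Classify a sample from PCR band intensities at fingerprint loci.

Replication timing at a locus is quantified from early- and late-S-phase
nascent-strand PCR as the percent-early abundance early/(early+late).
Because percent-early values live on a different scale than array log2
ratios, the query vector is rescaled to the training values' mean and SD
over the shared regions before Euclidean-distance kNN classification —
which makes classification invariant to any monotone affine distortion of
the raw measurements.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassificationResult, ClassifierModel, classify, fit_classifier
from .containers import WindowMatrix

MIN_SHARED_REGIONS = 5

PCR_COLUMNS = ["sample_id", "region_id", "replicate", "early_intensity", "late_intensity", "is_control"]


@dataclass
class PcrSample:
    """Background-subtracted band intensities for one sample.

    ``measurements`` has one row per (region_id, replicate) with columns
    region_id/replicate/early_intensity/late_intensity/is_control.
    Control loci (e.g. mitochondrial DNA, alpha/beta-globin) are quality
    checks only and never enter the distance.
    """

    sample_id: str
    measurements: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.measurements.copy()
        for col in ("region_id", "replicate", "early_intensity", "late_intensity"):
            if col not in df.columns:
                raise ValueError(f"PCR measurements missing column {col!r}")
        if "is_control" not in df.columns:
            df["is_control"] = False
        df["early_intensity"] = df["early_intensity"].astype(float)
        df["late_intensity"] = df["late_intensity"].astype(float)
        df["is_control"] = df["is_control"].astype(bool)
        if (df["early_intensity"] < 0).any() or (df["late_intensity"] < 0).any():
            raise ValueError("negative band intensity")
        self.measurements = df.reset_index(drop=True)

    def percent_early_table(self) -> pd.DataFrame:
        """Per-region mean percent-early with SEM over replicates."""
        df = self.measurements
        pe = percent_early(
            df["early_intensity"].to_numpy(), df["late_intensity"].to_numpy()
        )
        tab = pd.DataFrame(
            {"region_id": df["region_id"], "is_control": df["is_control"], "pe": pe}
        )
        out = (
            tab.groupby(["region_id", "is_control"], sort=False)["pe"]
            .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
            .reset_index()
        )
        out["sem"] = out["sd"] / np.sqrt(out["n"])
        return out[["region_id", "is_control", "mean", "sem", "n"]]


def percent_early(early, late):
    """Early-fraction signal as a fraction of total: early / (early + late)."""
    early = np.asarray(early, dtype=float)
    late = np.asarray(late, dtype=float)
    total = early + late
    if np.any(total <= 0):
        raise ValueError("no signal at locus (early + late = 0)")
    result = early / total
    return float(result) if result.ndim == 0 else result


def rescale_pcr(values, reference: tuple[float, float]) -> np.ndarray:
    """Map a percent-early vector onto the array timing scale.

    Standardizes to mean 0 / unit sample SD, then applies the reference
    (mean, sd) — the training array values over the same regions.  Output
    mean and SD equal the reference; any affine distortion a*v+b of the
    input (a > 0) yields an identical result.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values to rescale")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread in PCR values, cannot rescale")
    ref_mean, ref_sd = reference
    if ref_sd <= 0:
        raise ValueError("reference sd must be positive")
    return ref_mean + (v - v.mean()) / sd * ref_sd


def classify_pcr(model: ClassifierModel, sample: PcrSample) -> ClassificationResult:
    """Classify a PCR-measured sample against an array-trained model.

    Restricted to the non-control regions shared with the model (>= 5
    required); theta is refit on the training distances over that subset
    because absolute distances shrink with fewer regions.  Euclidean
    distances are used, as for reported distance matrices.
    """
    pe = sample.percent_early_table()
    pe = pe[~pe["is_control"]]
    shared = [r for r in model.regions if r in set(pe["region_id"])]
    if len(shared) < MIN_SHARED_REGIONS:
        raise ValueError(
            f"only {len(shared)} non-control regions shared with the model "
            f"(need >= {MIN_SHARED_REGIONS})"
        )
    training = model.training.loc[shared]
    ref = (float(training.to_numpy().mean()), float(training.to_numpy().std(ddof=1)))
    query = rescale_pcr(
        pe.set_index("region_id").loc[shared, "mean"].to_numpy(), ref
    )
    windows = pd.DataFrame(
        {"region_id": shared, "chrom": ".", "start": 0, "end": 0, "partial": False}
    )
    train_matrix = WindowMatrix(
        windows=windows, labels=model.labels, values=training
    )
    submodel = fit_classifier(
        train_matrix, None, shared, k=model.k, metric="euclidean", scheme=model.scheme
    )
    return classify(submodel, query, sample_id=sample.sample_id)


def read_pcr_samples(path: str | pathlib.Path) -> list[PcrSample]:
    """Read a long-format PCR intensity TSV (one row per region x replicate)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PCR_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"PCR table missing columns {missing}")
    return [
        PcrSample(sample_id=str(sid), measurements=sub.drop(columns=["sample_id"]))
        for sid, sub in df.groupby("sample_id", sort=False)
    ]
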