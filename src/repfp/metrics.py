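"""Distances between replication profiles and the distance-ratio objective.

The distance between two samples over a region set is either the sum of
absolute timing differences (L1, the selection objective's metric) or the
Euclidean distance (used for reported distance matrices and PCR
classification).  Pairwise distances split into within-type pairs (mean
chi_S) and between-type pairs (mean chi_D); their ratio chi_D/chi_S is the
separation objective maximized by region selection, and the overlap of the
two distributions yields the open-set rejection threshold theta.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import WindowMatrix

METRICS = ("L1", "euclidean")


def _check_metric(metric: str) -> None:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


@dataclass
class DistanceDistributions:
    """Distances split into within-type and between-type pairs."""

    within: np.ndarray
    between: np.ndarray

    def __post_init__(self) -> None:
        self.within = np.asarray(self.within, dtype=float)
        self.between = np.asarray(self.between, dtype=float)

    @property
    def chi_s(self) -> float:
        """Mean within-type distance."""
        return float(np.mean(self.within))

    @property
    def chi_d(self) -> float:
        """Mean between-type distance."""
        return float(np.mean(self.between))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_type": ["within"] * len(self.within) + ["between"] * len(self.between),
                "distance": np.concatenate([self.within, self.between]),
            }
        )


@dataclass
class ThresholdFit:
    """Distance cutoff minimizing misclassified within/between pairs.

    theta is the midpoint of ``tie_interval``, the lowest-distance interval
    of cutoffs achieving the minimal error count.  Pairs at distance
    exactly theta classify as same-type (<= theta).
    """

    theta: float
    n_errors: int
    error_rate: float
    tie_interval: tuple[float, float]


def profile_distance(a, b, metric: str = "L1") -> float:
    """Distance between two sample vectors over a shared region set."""
    _check_metric(metric)
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        if list(a.index) != list(b.index):
            raise ValueError("mismatched region sets between vectors")
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"vector length mismatch: {av.shape} vs {bv.shape}")
    if np.isnan(av).any() or np.isnan(bv).any():
        raise ValueError("missing values in distance computation")
    diff = av - bv
    if metric == "L1":
        return float(np.abs(diff).sum())
    return float(np.sqrt((diff ** 2).sum()))


def pairwise_distances(
    matrix: WindowMatrix, regions: list[str], metric: str = "L1"
) -> pd.DataFrame:
    """Symmetric sample x sample distance matrix over a region set.

    Regions must lie in the complete-case rows of the matrix.
    """
    _check_metric(metric)
    if not regions:
        raise ValueError("empty region set")
    sub = matrix.restrict(list(regions))
    if sub.values.isna().any().any():
        bad = sub.values.columns[sub.values.isna().any()][0]
        raise ValueError(f"missing values in regions for sample {bad!r}")
    ids = sub.sample_ids
    X = sub.values.to_numpy().T  # samples x regions
    n = len(ids)
    dm = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = profile_distance(X[i], X[j], metric=metric)
        dm[i, j] = dm[j, i] = d
    return pd.DataFrame(dm, index=ids, columns=ids)


def split_distances(
    dm: pd.DataFrame, labels: pd.DataFrame, scheme: str = "cell_type"
) -> DistanceDistributions:
    """Partition unordered off-diagonal pairs into within/between the scheme.

    Self-pairs (the zero diagonal) are excluded; they carry no information.
    """
    if scheme not in labels.columns:
        raise KeyError(f"no labelling scheme {scheme!r}")
    lab = labels.set_index("sample_id")[scheme]
    ids = list(dm.index)
    missing = [s for s in ids if s not in lab.index or pd.isna(lab[s])]
    if missing:
        raise ValueError(f"unlabelled samples under {scheme!r}: {missing}")
    within, between = [], []
    vals = dm.to_numpy()
    for i, j in combinations(range(len(ids)), 2):
        (within if lab[ids[i]] == lab[ids[j]] else between).append(vals[i, j])
    dists = DistanceDistributions(np.array(within), np.array(between))
    if len(dists.between) == 0:
        import warnings

        warnings.warn("all samples share one type: no between-type pairs", stacklevel=2)
    return dists


def distance_ratio(dists: DistanceDistributions, within_floor: float | None = None) -> float:
    """Separation objective chi_D / chi_S (between-mean over within-mean)."""
    if len(dists.within) == 0 or len(dists.between) == 0:
        raise ValueError("both within and between distance lists must be non-empty")
    chi_s = dists.chi_s
    if chi_s == 0:
        if within_floor is None:
            raise ValueError("degenerate within-type distances (mean 0)")
        chi_s = within_floor
    return dists.chi_d / chi_s


def estimate_threshold(dists: DistanceDistributions) -> ThresholdFit:
    """Fit the classification threshold theta.

    error(theta) = #{within > theta} + #{between <= theta}; candidate
    cutoffs are the open intervals between consecutive pooled distance
    values plus the two extremes.  Among intervals achieving the minimal
    error the lowest-distance one is chosen (conservative toward calling
    divergent queries "Unseen"); theta is its midpoint.
    """
    w = np.sort(dists.within)
    b = np.sort(dists.between)
    if len(w) == 0 or len(b) == 0:
        raise ValueError("both distance lists must be non-empty")
    pooled = np.unique(np.concatenate([w, b]))
    pad = max(float(pooled[-1] - pooled[0]), 1.0)
    # candidate intervals (lo, hi): theta anywhere inside gives the same error
    intervals = [(float(pooled[0]) - pad, float(pooled[0]))]
    intervals += [(float(pooled[i]), float(pooled[i + 1])) for i in range(len(pooled) - 1)]
    intervals.append((float(pooled[-1]), float(pooled[-1]) + pad))

    def err(theta: float) -> int:
        return int((w > theta).sum() + (b <= theta).sum())

    errors = [err((lo + hi) / 2.0) for lo, hi in intervals]
    best = min(errors)
    lo, hi = intervals[int(np.argmin(errors))]  # first == lowest-distance interval
    n_pairs = len(w) + len(b)
    return ThresholdFit(
        theta=(lo + hi) / 2.0,
        n_errors=best,
        error_rate=best / n_pairs,
        tie_interval=(lo, hi),
    )


def empirical_error_rate(dists: DistanceDistributions, theta: float) -> float:
    """Fraction of pairs misclassified by the cutoff theta."""
    w, b = dists.within, dists.between
    if len(w) == 0 or len(b) == 0:
        raise ValueError("both distance lists must be non-empty")
    return float(((w > theta).sum() + (b <= theta).sum()) / (len(w) + len(b)))


def write_distance_matrix(dm: pd.DataFrame, path: str | pathlib.Path) -> None:
    dm.to_csv(path, sep="\t", float_format="%.12g", index_label="sample_id")


def read_distance_matrix(path: str | pathlib.Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
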