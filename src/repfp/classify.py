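"""Open-set k-nearest-neighbor classification against fingerprint regions.

A query profile is compared to every training profile over the fingerprint
regions.  Training samples within the threshold theta are eligible
neighbors; if none remain the query is called "Unseen" (a cell type absent
from training).  Otherwise the (up to) k nearest eligible neighbors vote
by majority on the cell type.  Crossvalidation harnesses re-run region
selection per fold: leave-one-out (LOOCV, one experiment held out) and
leave-cell-type-out (LCTO, all replicates of a type held out, where the
correct call is "Unseen").
"""

from __future__ import annotations

import json
import pathlib
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import WindowMatrix
from .metrics import (
    DistanceDistributions,
    ThresholdFit,
    empirical_error_rate,
    estimate_threshold,
    pairwise_distances,
    profile_distance,
    split_distances,
)
from .selection import MCParams, _spawn_seeds, consensus_fingerprint, run_selections

UNSEEN = "Unseen"


@dataclass
class ClassifierModel:
    """Fingerprint regions + training values + k + fitted threshold."""

    regions: list[str]
    training: pd.DataFrame  # regions x training samples
    labels: pd.DataFrame
    scheme: str
    k: int
    metric: str
    theta: ThresholdFit
    dists: DistanceDistributions

    def to_json(self, path: str | pathlib.Path) -> None:
        payload = {
            "regions": self.regions,
            "training": {c: list(self.training[c]) for c in self.training.columns},
            "labels": self.labels.to_dict(orient="list"),
            "scheme": self.scheme,
            "k": self.k,
            "metric": self.metric,
            "theta": {
                "theta": self.theta.theta,
                "n_errors": self.theta.n_errors,
                "error_rate": self.theta.error_rate,
                "tie_interval": list(self.theta.tie_interval),
            },
            "dists": {
                "within": list(self.dists.within),
                "between": list(self.dists.between),
            },
        }
        pathlib.Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | pathlib.Path) -> "ClassifierModel":
        payload = json.loads(pathlib.Path(path).read_text())
        training = pd.DataFrame(
            payload["training"], index=pd.Index(payload["regions"], name="region_id")
        )
        th = payload["theta"]
        return cls(
            regions=payload["regions"],
            training=training,
            labels=pd.DataFrame(payload["labels"]),
            scheme=payload["scheme"],
            k=payload["k"],
            metric=payload["metric"],
            theta=ThresholdFit(
                theta=th["theta"],
                n_errors=th["n_errors"],
                error_rate=th["error_rate"],
                tie_interval=tuple(th["tie_interval"]),
            ),
            dists=DistanceDistributions(
                np.array(payload["dists"]["within"]),
                np.array(payload["dists"]["between"]),
            ),
        )


@dataclass
class ClassificationResult:
    """Outcome for one query: a training cell type or "Unseen"."""

    sample_id: str
    predicted: str
    neighbors: list[tuple[str, float]]  # (training sample, distance), ascending
    below_theta: int
    error_estimate: float


def fit_classifier(
    matrix: WindowMatrix,
    labels: pd.DataFrame | None,
    regions: list[str],
    k: int = 3,
    metric: str = "L1",
    scheme: str = "cell_type",
) -> ClassifierModel:
    """Fit the open-set kNN model on training samples over fingerprint regions."""
    if labels is not None:
        matrix = WindowMatrix(matrix.windows, labels, matrix.values)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix.sample_ids):
        raise ValueError(
            f"k={k} exceeds the training set size ({len(matrix.sample_ids)})"
        )
    types = matrix.scheme_values(scheme)
    if types.nunique() < 2:
        raise ValueError("need >= 2 cell types to fit a classifier")
    sub = matrix.restrict(regions)
    training = sub.values.loc[regions]
    if training.isna().any().any():
        raise ValueError("missing values in fingerprint regions of training matrix")
    dm = pairwise_distances(sub, regions, metric=metric)
    dists = split_distances(dm, matrix.labels, scheme=scheme)
    theta = estimate_threshold(dists)
    return ClassifierModel(
        regions=list(regions),
        training=training,
        labels=matrix.labels,
        scheme=scheme,
        k=k,
        metric=metric,
        theta=theta,
        dists=dists,
    )


def classify(
    model: ClassifierModel, query, sample_id: str = "query"
) -> ClassificationResult:
    """Assign a query vector (over the model regions) a type or "Unseen".

    Only training samples at distance <= theta are eligible neighbors; the
    min(k, #eligible) nearest vote by majority.  Vote ties break by the
    smallest mean distance among tied types, then lexicographically.
    """
    if isinstance(query, pd.Series):
        if list(query.index) != list(model.regions):
            query = query.reindex(model.regions)
        if query.isna().any():
            raise ValueError("query missing values on model regions")
        sample_id = query.name if query.name is not None else sample_id
    q = np.asarray(query, dtype=float)
    if q.shape != (len(model.regions),):
        raise ValueError(
            f"query has {q.shape} values, model has {len(model.regions)} regions"
        )
    types = model.labels.set_index("sample_id")[model.scheme]
    dists = [
        (sid, profile_distance(q, model.training[sid].to_numpy(), metric=model.metric))
        for sid in model.training.columns
    ]
    dists.sort(key=lambda t: (t[1], t[0]))
    eligible = [(sid, d) for sid, d in dists if d <= model.theta.theta]
    below = len(eligible)
    if below == 0:
        predicted = UNSEEN
        nearest_d = dists[0][1]
    else:
        chosen = eligible[: min(model.k, below)]
        votes = Counter(types[sid] for sid, _ in chosen)
        top = max(votes.values())
        tied = sorted(t for t, c in votes.items() if c == top)
        if len(tied) > 1:
            mean_d = {
                t: float(np.mean([d for sid, d in chosen if types[sid] == t]))
                for t in tied
            }
            tied.sort(key=lambda t: (mean_d[t], t))
        predicted = tied[0]
        nearest_d = chosen[0][1]
    return ClassificationResult(
        sample_id=str(sample_id),
        predicted=predicted,
        neighbors=dists,
        below_theta=below,
        error_estimate=empirical_error_rate(model.dists, nearest_d),
    )


def _drop_samples(matrix: WindowMatrix, drop: list[str]) -> WindowMatrix:
    keep = [s for s in matrix.sample_ids if s not in set(drop)]
    return WindowMatrix(
        windows=matrix.windows,
        labels=matrix.labels[matrix.labels["sample_id"].isin(keep)].reset_index(drop=True),
        values=matrix.values[keep],
    )


def _fold_regions(
    train: WindowMatrix, params: MCParams, runs_per_fold: int, fold_seed: int
) -> list[str]:
    fps, _ = run_selections(train, replace(params, seed=fold_seed), runs_per_fold)
    cons = consensus_fingerprint(fps, matrix=train, scheme=params.scheme)
    return cons.top(params.n_min)


def loocv(
    matrix: WindowMatrix,
    labels: pd.DataFrame | None = None,
    params: MCParams | None = None,
    runs_per_fold: int = 10,
    k: int = 3,
) -> tuple[pd.DataFrame, float]:
    """Leave-one-out crossvalidation with per-fold region re-selection.

    For every experiment: regions are selected (consensus over
    ``runs_per_fold`` seeded runs) with that experiment excluded, a
    classifier is fitted on the remaining samples, and the held-out
    experiment is classified.  Accuracy is scored at the cell-type level of
    the labelling scheme.
    """
    params = params or MCParams()
    if labels is not None:
        matrix = WindowMatrix(matrix.windows, labels, matrix.values)
    types = matrix.scheme_values(params.scheme)
    fold_seeds = _spawn_seeds(params.seed, len(matrix.sample_ids))
    rows = []
    correct = 0
    for fold_seed, held in zip(fold_seeds, matrix.sample_ids):
        train = _drop_samples(matrix, [held])
        if train.scheme_values(params.scheme).nunique() < 2:
            raise ValueError(f"fold holding out {held!r} leaves < 2 cell types")
        regions = _fold_regions(train, params, runs_per_fold, fold_seed)
        model = fit_classifier(
            train, None, regions, k=k, metric=params.metric, scheme=params.scheme
        )
        res = classify(model, matrix.values.loc[regions, held], sample_id=held)
        ok = res.predicted == types[held]
        correct += ok
        rows.append(
            {
                "sample_id": held,
                "true_label": types[held],
                "predicted": res.predicted,
                "n_below_theta": res.below_theta,
                "nearest": res.neighbors[0][0],
                "nearest_distance": res.neighbors[0][1],
                "error_estimate": res.error_estimate,
                "correct": bool(ok),
            }
        )
    return pd.DataFrame(rows), correct / len(rows)


def lcto(
    matrix: WindowMatrix,
    labels: pd.DataFrame | None = None,
    params: MCParams | None = None,
    runs_per_fold: int = 10,
    k: int = 3,
) -> pd.DataFrame:
    """Leave-cell-type-out: every held-out type should be called "Unseen".

    All replicates of one type are excluded from selection and training;
    each is then classified.  Reports, per type, the fraction called
    Unseen and any alternative labels chosen.
    """
    params = params or MCParams()
    if labels is not None:
        matrix = WindowMatrix(matrix.windows, labels, matrix.values)
    types = matrix.scheme_values(params.scheme)
    all_types = sorted(types.unique())
    if len(all_types) < 3:
        raise ValueError("LCTO needs >= 3 cell types (folds must retain >= 2)")
    fold_seeds = _spawn_seeds(params.seed, len(all_types))
    rows = []
    for fold_seed, held_type in zip(fold_seeds, all_types):
        held = [s for s in matrix.sample_ids if types[s] == held_type]
        train = _drop_samples(matrix, held)
        regions = _fold_regions(train, params, runs_per_fold, fold_seed)
        model = fit_classifier(
            train, None, regions, k=k, metric=params.metric, scheme=params.scheme
        )
        preds = [
            classify(model, matrix.values.loc[regions, s], sample_id=s).predicted
            for s in held
        ]
        n_unseen = sum(p == UNSEEN for p in preds)
        rows.append(
            {
                "cell_type": held_type,
                "n_samples": len(held),
                "n_unseen": n_unseen,
                "fraction_unseen": n_unseen / len(held),
                "alternative_labels": ",".join(sorted({p for p in preds if p != UNSEEN}))
                or "",
            }
        )
    return pd.DataFrame(rows)


def results_to_frame(results: list[ClassificationResult], k: int = 3) -> pd.DataFrame:
    """Tabulate classification results with the k nearest neighbors."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "sample_id": r.sample_id,
            "predicted": r.predicted,
            "n_below_theta": r.below_theta,
            "error_estimate": r.error_estimate,
        }
        for i, (sid, d) in enumerate(r.neighbors[:k], start=1):
            row[f"nearest_{i}"] = sid
            row[f"d_{i}"] = d
        rows.append(row)
    return pd.DataFrame(rows)
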