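"""Monte-Carlo selection of fingerprint regions.

A replication fingerprint is a small set of genomic windows whose timing
values are consistently different between cell types but stable between
replicates.  Selection maximizes the distance ratio dR = chi_D/chi_S over
region subsets by simulated annealing: starting from a random half of a
candidate pool (the windows with the highest across-sample SD), each
iteration proposes adding, removing or swapping one region and accepts with
probability min(1, exp((dR_proposed - dR_current)/T)) under a geometrically
cooling temperature.  Because single runs are stochastic, a consensus over
repeated runs keeps regions selected in at least a threshold fraction
(default 75%) of runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import WindowMatrix
from .metrics import _check_metric


@dataclass
class MCParams:
    """Tunables of the annealed subset search.

    Defaults follow the genome-scale procedure: a 2000-region candidate
    pool, at least 20000 moves, and a 20-region final fingerprint.  t0=None
    auto-calibrates the initial temperature so that roughly half of
    ratio-worsening proposals are accepted during a 200-move burn-in.
    """

    n_candidates: int = 2000
    n_iterations: int = 20_000
    n_min: int = 20
    start_fraction: float = 0.5
    t0: float | None = None
    cooling: float = 0.9995
    metric: str = "L1"
    seed: int | None = None
    scheme: str = "cell_type"
    within_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 < self.start_fraction <= 1):
            raise ValueError("start_fraction must be in (0, 1]")
        if not (0 < self.cooling < 1):
            raise ValueError("cooling must be in (0, 1)")
        if self.n_min < 2:
            raise ValueError("n_min must be >= 2")
        _check_metric(self.metric)


@dataclass
class Fingerprint:
    """A selected region set with its achieved distance ratio."""

    regions: list[str]
    achieved_ratio: float
    scheme: str
    params: MCParams


@dataclass
class ConsensusFingerprint:
    """Per-region inclusion frequencies over repeated selection runs."""

    inclusion: dict[str, float]
    selected: list[str]
    n_runs: int
    threshold: float
    ranking: list[str] = field(default_factory=list)
    top_regions: list[str] | None = None

    def top(self, n: int) -> list[str]:
        return self.ranking[:n]


def candidate_pool(matrix: WindowMatrix, n_candidates: int) -> list[str]:
    """Regions with the highest across-sample SD among complete-case rows.

    Restricting the search to high-variance windows removes regions whose
    timing is conserved in all cell types.  Ties break by genomic order.
    """
    cc = matrix.complete_case()
    if len(cc.values) < n_candidates:
        raise ValueError(
            f"only {len(cc.values)} complete-case regions < n_candidates={n_candidates}"
        )
    sd = cc.values.std(axis=1, ddof=1).to_numpy()
    order = np.argsort(-sd, kind="stable")[:n_candidates]
    rids = np.asarray(cc.region_ids)
    return [str(r) for r in rids[order]]


class _RatioScorer:
    """Incremental distance-ratio evaluation over subsets of a candidate pool.

    Precomputes per-region |diff| (L1) or diff^2 (Euclidean) for every
    within- and between-type sample pair; a subset's pair distances are
    column sums over its rows, maintained incrementally across moves.
    """

    def __init__(
        self,
        matrix: WindowMatrix,
        pool: list[str],
        scheme: str,
        metric: str,
        within_floor: float,
    ) -> None:
        sub = matrix.restrict(pool)
        # restrict() preserves matrix order; re-order rows to pool order
        vals = sub.values.loc[pool].to_numpy()  # pool x samples
        types = sub.scheme_values(scheme)
        ids = sub.sample_ids
        if types.nunique() < 2:
            raise ValueError(f"need >= 2 groups under scheme {scheme!r}")
        wpairs, bpairs = [], []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                (wpairs if types[ids[i]] == types[ids[j]] else bpairs).append((i, j))
        if not wpairs:
            raise ValueError("no within-type pairs: every type has a single sample")
        self.pool = list(pool)
        self.metric = metric
        self.within_floor = within_floor
        self._warned = False
        diff_w = vals[:, [p[0] for p in wpairs]] - vals[:, [p[1] for p in wpairs]]
        diff_b = vals[:, [p[0] for p in bpairs]] - vals[:, [p[1] for p in bpairs]]
        if metric == "L1":
            self.W, self.B = np.abs(diff_w), np.abs(diff_b)
        else:
            self.W, self.B = diff_w ** 2, diff_b ** 2

    def sums(self, members: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.flatnonzero(members)
        return self.W[idx].sum(axis=0), self.B[idx].sum(axis=0)

    def ratio_from_sums(self, wsum: np.ndarray, bsum: np.ndarray) -> float:
        if self.metric == "euclidean":
            wd, bd = np.sqrt(wsum), np.sqrt(bsum)
        else:
            wd, bd = wsum, bsum
        chi_s = wd.mean()
        if chi_s == 0:
            if not self._warned:
                warnings.warn(
                    "within-type mean distance 0; substituting configured floor",
                    stacklevel=2,
                )
                self._warned = True
            chi_s = self.within_floor
        return float(bd.mean() / chi_s)

    def score(self, members: np.ndarray) -> float:
        return self.ratio_from_sums(*self.sums(members))


def _propose(
    rng: np.random.Generator, members: np.ndarray, n_min: int
) -> tuple[str, int, int]:
    """Draw one move: ('add'|'remove'|'swap', region_in, region_out).

    While the set is above the minimum size removal dominates (0.5/0.4/0.1
    remove/swap/add) so the set shrinks toward n_min while the ratio
    climbs; at n_min only swap (0.8) and add (0.2) are feasible.
    """
    size = int(members.sum())
    n = len(members)
    inside = np.flatnonzero(members)
    outside = np.flatnonzero(~members)
    while True:
        if size > n_min:
            u = rng.random()
            move = "remove" if u < 0.5 else ("swap" if u < 0.9 else "add")
        else:
            move = "swap" if rng.random() < 0.8 else "add"
        if move == "add" and len(outside) == 0:
            continue
        if move == "swap" and (len(outside) == 0 or len(inside) == 0):
            continue
        break
    if move == "add":
        return move, int(outside[rng.integers(len(outside))]), -1
    if move == "remove":
        return move, -1, int(inside[rng.integers(len(inside))])
    return (
        move,
        int(outside[rng.integers(len(outside))]),
        int(inside[rng.integers(len(inside))]),
    )


def _calibrate_t0(
    scorer: _RatioScorer,
    members: np.ndarray,
    n_min: int,
    rng: np.random.Generator,
    n_probe: int = 200,
) -> float:
    """Initial temperature accepting ~50% of worsening probe moves."""
    cur = scorer.score(members)
    wsum, bsum = scorer.sums(members)
    drops = []
    for _ in range(n_probe):
        move, r_in, r_out = _propose(rng, members, n_min)
        w2, b2 = wsum.copy(), bsum.copy()
        if r_in >= 0:
            w2 += scorer.W[r_in]
            b2 += scorer.B[r_in]
        if r_out >= 0:
            w2 -= scorer.W[r_out]
            b2 -= scorer.B[r_out]
        delta = scorer.ratio_from_sums(w2, b2) - cur
        if delta < 0:
            drops.append(-delta)
    if not drops:
        return 1e-3
    return float(np.median(drops) / math.log(2.0))


def select_fingerprint(
    matrix: WindowMatrix,
    labels: pd.DataFrame | None = None,
    params: MCParams | None = None,
    pool: list[str] | None = None,
) -> tuple[Fingerprint, pd.DataFrame]:
    """Run one annealed search for a fingerprint of size ``params.n_min``.

    Returns the best-scoring visited state of size exactly n_min together
    with an iteration trace (iteration, size, dR, dR_best).  ``labels`` may
    be omitted when the matrix already carries its label table; ``pool``
    overrides the SD-based candidate pool.
    """
    params = params or MCParams()
    if labels is not None:
        matrix = WindowMatrix(matrix.windows, labels, matrix.values)
    if pool is None:
        pool = candidate_pool(matrix, params.n_candidates)
    if len(pool) < params.n_min:
        raise ValueError(f"candidate pool ({len(pool)}) smaller than n_min ({params.n_min})")
    scorer = _RatioScorer(matrix, pool, params.scheme, params.metric, params.within_floor)
    rng = np.random.default_rng(params.seed)

    n = len(pool)
    n_start = max(params.n_min, int(round(params.start_fraction * n)))
    members = np.zeros(n, dtype=bool)
    members[rng.choice(n, size=n_start, replace=False)] = True

    t = params.t0 if params.t0 is not None else _calibrate_t0(scorer, members, params.n_min, rng)
    wsum, bsum = scorer.sums(members)
    dr = scorer.ratio_from_sums(wsum, bsum)
    dr_best = dr
    best_nmin_ratio = -np.inf
    best_nmin_members: np.ndarray | None = None
    if members.sum() == params.n_min:
        best_nmin_ratio, best_nmin_members = dr, members.copy()

    trace = np.empty((params.n_iterations, 4))
    for it in range(params.n_iterations):
        move, r_in, r_out = _propose(rng, members, params.n_min)
        w2, b2 = wsum.copy(), bsum.copy()
        if r_in >= 0:
            w2 += scorer.W[r_in]
            b2 += scorer.B[r_in]
        if r_out >= 0:
            w2 -= scorer.W[r_out]
            b2 -= scorer.B[r_out]
        dr_new = scorer.ratio_from_sums(w2, b2)
        delta = dr_new - dr
        if delta >= 0 or rng.random() < math.exp(delta / t):
            members_new = members.copy()
            if r_in >= 0:
                members_new[r_in] = True
            if r_out >= 0:
                members_new[r_out] = False
            members, wsum, bsum, dr = members_new, w2, b2, dr_new
            dr_best = max(dr_best, dr)
            if members.sum() == params.n_min and dr > best_nmin_ratio:
                best_nmin_ratio, best_nmin_members = dr, members.copy()
        t *= params.cooling
        trace[it] = (it, members.sum(), dr, dr_best)
        if (it + 1) % 1000 == 0:  # guard against float drift in running sums
            wsum, bsum = scorer.sums(members)
            dr = scorer.ratio_from_sums(wsum, bsum)

    if best_nmin_members is None:
        warnings.warn(
            "state of size n_min never visited; returning best visited state",
            stacklevel=2,
        )
        best_nmin_members = members
    region_arr = np.asarray(pool)
    regions = [str(r) for r in region_arr[best_nmin_members]]
    achieved = scorer.score(best_nmin_members)  # fresh re-score: exact on re-evaluation
    trace_df = pd.DataFrame(trace, columns=["iteration", "size", "dR", "dR_best"])
    trace_df["iteration"] = trace_df["iteration"].astype(int)
    trace_df["size"] = trace_df["size"].astype(int)
    fp = Fingerprint(
        regions=regions, achieved_ratio=achieved, scheme=params.scheme, params=params
    )
    return fp, trace_df


def run_selections(
    matrix: WindowMatrix,
    params: MCParams,
    n_runs: int,
    labels: pd.DataFrame | None = None,
    pool: list[str] | None = None,
) -> tuple[list[Fingerprint], list[pd.DataFrame]]:
    """Repeat selection with seeds spawned deterministically from params.seed."""
    seeds = _spawn_seeds(params.seed, n_runs)
    fps, traces = [], []
    for s in seeds:
        fp, tr = select_fingerprint(matrix, labels=labels, params=replace(params, seed=s), pool=pool)
        fps.append(fp)
        traces.append(tr)
    return fps, traces


def _spawn_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def region_separation_scores(
    matrix: WindowMatrix, regions: list[str], scheme: str = "cell_type"
) -> pd.Series:
    """Per-region mean between-type minus mean within-type |timing difference|."""
    sub = matrix.restrict(regions)
    vals = sub.values.loc[regions].to_numpy()
    types = sub.scheme_values(scheme)
    ids = sub.sample_ids
    wd, bd = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = np.abs(vals[:, i] - vals[:, j])
            (wd if types[ids[i]] == types[ids[j]] else bd).append(d)
    score = np.mean(bd, axis=0) - np.mean(wd, axis=0)
    return pd.Series(score, index=regions)


def consensus_fingerprint(
    runs: list[Fingerprint],
    threshold: float = 0.75,
    top_n: int | None = None,
    matrix: WindowMatrix | None = None,
    labels: pd.DataFrame | None = None,
    scheme: str = "cell_type",
) -> ConsensusFingerprint:
    """Aggregate repeated selection runs into a consensus fingerprint.

    ``selected`` holds regions included in >= ``threshold`` of runs.
    Ranking is by inclusion frequency, ties by per-region separation score
    when a matrix is supplied (needed to pick e.g. a top-200 set), then by
    first-seen order.
    """
    if not runs:
        raise ValueError("no selection runs given")
    counts: dict[str, int] = {}
    for fp in runs:
        for rid in fp.regions:
            counts[rid] = counts.get(rid, 0) + 1
    inclusion = {rid: c / len(runs) for rid, c in counts.items()}
    order = list(counts)  # first-seen order
    if matrix is not None:
        if labels is not None:
            matrix = WindowMatrix(matrix.windows, labels, matrix.values)
        sep = region_separation_scores(matrix, order, scheme=scheme)
        ranking = sorted(
            order, key=lambda r: (-inclusion[r], -sep[r], order.index(r))
        )
    else:
        ranking = sorted(order, key=lambda r: (-inclusion[r], order.index(r)))
    selected = [r for r in ranking if inclusion[r] >= threshold]
    cons = ConsensusFingerprint(
        inclusion=inclusion,
        selected=selected,
        n_runs=len(runs),
        threshold=threshold,
        ranking=ranking,
    )
    if top_n is not None:
        cons.top_regions = ranking[:top_n]
    return cons


def annotate_directions(
    matrix: WindowMatrix,
    labels: pd.DataFrame | None,
    scheme: str,
    group_a: str,
    group_b: str,
    regions: list[str],
) -> pd.DataFrame:
    """Direction of each region's timing change between two groups.

    EtoL: earlier (higher timing ratio) in group A than B — e.g. early in
    pluripotent cells, later after commitment; LtoE the reverse.
    """
    if labels is not None:
        matrix = WindowMatrix(matrix.windows, labels, matrix.values)
    types = matrix.scheme_values(scheme)
    a_ids = [s for s in matrix.sample_ids if types[s] == group_a]
    b_ids = [s for s in matrix.sample_ids if types[s] == group_b]
    if not a_ids or not b_ids:
        raise ValueError(f"empty group under scheme {scheme!r}: {group_a!r} or {group_b!r}")
    sub = matrix.restrict(regions)
    vals = sub.values.loc[regions]
    if vals.isna().any().any():
        raise ValueError("missing values in requested regions")
    mean_a = vals[a_ids].mean(axis=1)
    mean_b = vals[b_ids].mean(axis=1)
    diff = mean_a - mean_b
    direction = np.where(diff > 0, "EtoL", np.where(diff < 0, "LtoE", "none"))
    return pd.DataFrame(
        {
            "region_id": regions,
            "mean_a": mean_a.to_numpy(),
            "mean_b": mean_b.to_numpy(),
            "difference": diff.to_numpy(),
            "direction": direction,
            "magnitude": np.abs(diff.to_numpy()),
        }
    )
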