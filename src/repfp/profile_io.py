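"""Reading, windowing, normalizing and smoothing replication profiles.

Probe-level log2(early/late) profiles arrive as bedGraph (chrom start end
value) or 3-column TSV (chrom position value).  They are averaged into
non-overlapping windows (default 200 kb, the scale at which developmental
timing changes of 400-800 kb are well resolved), normalized across samples,
and optionally LOESS-smoothed for display.
"""

from __future__ import annotations

import io
import pathlib

import numpy as np
import pandas as pd

from .containers import ProbeProfile, WindowMatrix, validate_labels, warn

DEFAULT_WINDOW_SIZE = 200_000
DEFAULT_MIN_PROBES = 5
DEFAULT_LOESS_SPAN = 300_000

_SKIP_PREFIXES = ("track", "browser", "#")


def read_probe_profile(
    path: str | pathlib.Path,
    format: str = "bedgraph",
    sample_id: str | None = None,
) -> ProbeProfile:
    """Parse a probe-level timing profile.

    ``format="bedgraph"``: whitespace-delimited chrom/start/end/value, track
    and comment lines ignored.  ``format="tsv3col"``: chrom/position/value,
    where position is the probe midpoint; stored as the 1 bp interval
    [position, position+1) so that windowing by midpoint is identical to the
    bedGraph representation.
    """
    path = pathlib.Path(path)
    if format not in ("bedgraph", "tsv3col"):
        raise ValueError(f"unknown format {format!r}")
    ncol = 4 if format == "bedgraph" else 3
    rows: list[tuple[str, int, int, float]] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(_SKIP_PREFIXES):
                continue
            parts = stripped.split()
            if len(parts) < ncol:
                errors.append(f"line {lineno}: expected {ncol} fields, got {len(parts)}")
                continue
            try:
                if format == "bedgraph":
                    chrom, start, end, value = (
                        parts[0], int(parts[1]), int(parts[2]), float(parts[3]),
                    )
                else:
                    chrom = parts[0]
                    pos = int(parts[1])
                    start, end, value = pos, pos + 1, float(parts[2])
            except ValueError:
                errors.append(f"line {lineno}: could not parse {stripped!r}")
                continue
            rows.append((chrom, start, end, value))
    if errors:
        raise ValueError(f"parse errors in {path}:\n  " + "\n  ".join(errors))
    if not rows:
        raise ValueError(f"no probe records in {path}")
    records = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return ProbeProfile(sample_id=sample_id or path.stem, records=records)


def read_labels(path: str | pathlib.Path) -> pd.DataFrame:
    """Read a sample-label TSV with header sample_id/cell_type/replicate[/group...]."""
    labels = pd.read_csv(path, sep="\t", dtype=str)
    return validate_labels(labels)


def window_profiles(
    profiles: list[ProbeProfile],
    labels: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_probes: int = DEFAULT_MIN_PROBES,
) -> WindowMatrix:
    """Average probe profiles into non-overlapping genomic windows.

    Windows tile each chromosome from coordinate 0 in steps of
    ``window_size``; a probe belongs to the window containing its midpoint.
    The window value is the arithmetic mean of its probes' timing ratios; a
    window with fewer than ``min_probes`` probes in a sample is missing
    (NaN) for that sample.  Terminal windows truncated by the chromosome
    extent are kept and flagged ``partial``.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if not profiles:
        raise ValueError("no probe profiles given")
    labels = validate_labels(labels)
    by_id = {p.sample_id: p for p in profiles}
    if set(by_id) != set(labels["sample_id"]):
        raise ValueError("profiles and label table list different samples")

    # chromosome extents: furthest probe end seen in any sample
    extents: dict[str, int] = {}
    for p in profiles:
        for chrom, sub in p.records.groupby("chrom", sort=False):
            extents[chrom] = max(extents.get(chrom, 0), int(sub["end"].max()))

    windows_rows = []
    for chrom in sorted(extents):
        extent = extents[chrom]
        n_win = int(np.ceil(extent / window_size))
        for i in range(n_win):
            start = i * window_size
            end = min(start + window_size, extent)
            windows_rows.append(
                (f"{chrom}:{start}-{end}", chrom, start, end, end - start < window_size)
            )
    windows = pd.DataFrame(
        windows_rows, columns=["region_id", "chrom", "start", "end", "partial"]
    )

    n_win_per_chrom = windows.groupby("chrom").size()
    sample_ids = list(labels["sample_id"])
    values = pd.DataFrame(
        np.nan, index=pd.Index(windows["region_id"], name="region_id"), columns=sample_ids
    )
    for sid in sample_ids:
        prof = by_id[sid]
        present = set(prof.records["chrom"].unique())
        absent = set(extents) - present
        if absent:
            warn(f"sample {sid!r}: no probes on {sorted(absent)}; windows missing")
        mids = prof.midpoints.to_numpy()
        idx = np.minimum(
            (mids // window_size).astype(int),
            prof.records["chrom"].map(n_win_per_chrom).to_numpy() - 1,
        )
        keyed = pd.DataFrame(
            {
                "chrom": prof.records["chrom"].to_numpy(),
                "widx": idx,
                "value": prof.records["value"].to_numpy(),
            }
        )
        agg = keyed.groupby(["chrom", "widx"])["value"].agg(["mean", "count"])
        agg = agg[agg["count"] >= min_probes]
        region_ids = [
            _region_id_at(windows, chrom, widx, window_size)
            for chrom, widx in agg.index
        ]
        values.loc[region_ids, sid] = agg["mean"].to_numpy()
    return WindowMatrix(windows=windows, labels=labels, values=values)


def _region_id_at(windows: pd.DataFrame, chrom: str, widx: int, window_size: int) -> str:
    start = widx * window_size
    hit = windows[(windows["chrom"] == chrom) & (windows["start"] == start)]
    return hit["region_id"].iloc[0]


def normalize_scales(
    matrix: WindowMatrix,
    method: str = "zscore",
    reference: tuple[float, float] | None = None,
) -> WindowMatrix:
    """Bring all sample columns to equivalent scales.

    zscore: each column centered to mean 0 and scaled to unit sample SD
    (n-1), then mapped affinely to ``reference`` (mean, sd) if given.
    quantile: every column is assigned the sorted-value distribution of the
    column-wise mean (rank-average ties); requires a matrix without missing
    entries.  none: identity.
    """
    if method == "none":
        return WindowMatrix(matrix.windows, matrix.labels, matrix.values.copy())
    v = matrix.values.copy()
    if method == "zscore":
        for sid in v.columns:
            col = v[sid]
            obs = col.dropna()
            if len(obs) < 2 or obs.std(ddof=1) == 0:
                raise ValueError(f"sample {sid!r}: zero spread, cannot z-score")
            z = (col - obs.mean()) / obs.std(ddof=1)
            if reference is not None:
                ref_mean, ref_sd = reference
                z = ref_mean + z * ref_sd
            v[sid] = z
        return WindowMatrix(matrix.windows, matrix.labels, v)
    if method == "quantile":
        if v.isna().any().any():
            raise ValueError("quantile normalization requires a complete matrix")
        ranked = v.rank(method="average")
        ref = np.sort(v.to_numpy(), axis=0).mean(axis=1)  # mean of per-column sorted values
        # rank r (1-based, possibly fractional for ties) -> interpolated reference value
        grid = np.arange(1, len(ref) + 1, dtype=float)
        out = {
            sid: np.interp(ranked[sid].to_numpy(), grid, ref) for sid in v.columns
        }
        v = pd.DataFrame(out, index=v.index)[list(matrix.sample_ids)]
        return WindowMatrix(matrix.windows, matrix.labels, v)
    raise ValueError(f"unknown normalization method {method!r}")


def loess_smooth(
    profile: ProbeProfile,
    span_bp: int = DEFAULT_LOESS_SPAN,
    degree: int = 2,
) -> ProbeProfile:
    """LOESS-smooth a probe profile for display.

    Per chromosome, a locally weighted polynomial regression (tricube
    weights, degree 2) is evaluated at every probe midpoint.  The
    neighborhood size k is chosen per chromosome so that the median
    neighborhood width (bp spanned by the k nearest probes) approximates
    ``span_bp``.
    """
    out = profile.records.copy()
    for chrom, sub in profile.records.groupby("chrom", sort=False):
        x = ((sub["start"] + sub["end"]) / 2.0).to_numpy(float)
        y = sub["value"].to_numpy(float)
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        n = len(xs)
        if n < degree + 1:
            raise ValueError(
                f"chromosome {chrom}: {n} probes < degree+1 = {degree + 1}"
            )
        spacing = np.diff(xs)
        if len(spacing) and span_bp < np.median(spacing):
            raise ValueError(
                f"span {span_bp} bp smaller than median probe spacing on {chrom}"
            )
        k = _neighborhood_size(xs, span_bp, k_min=min(n, degree + 2))
        smoothed = np.empty(n)
        for i in range(n):
            lo, hi = _nearest_window(xs, i, k)
            xn, yn = xs[lo:hi], ys[lo:hi]
            d = np.abs(xn - xs[i])
            dmax = d.max()
            w = np.ones_like(d) if dmax == 0 else (1 - (d / dmax) ** 3) ** 3
            w = np.maximum(w, 1e-12)
            smoothed[i] = _wpolyfit_at(xn - xs[i], yn, w, degree)
        out.loc[sub.index, "value"] = _unsort(smoothed, order)
    return ProbeProfile(sample_id=profile.sample_id, records=out)


def _unsort(values_sorted: np.ndarray, order: np.ndarray) -> np.ndarray:
    res = np.empty_like(values_sorted)
    res[order] = values_sorted
    return res


def _neighborhood_size(xs: np.ndarray, span_bp: float, k_min: int) -> int:
    """Smallest k whose median k-nearest-neighborhood width reaches span_bp."""
    n = len(xs)
    lo, hi = k_min, n
    if _median_width(xs, n) < span_bp:
        return n
    while lo < hi:
        mid = (lo + hi) // 2
        if _median_width(xs, mid) >= span_bp:
            hi = mid
        else:
            lo = mid + 1
    return lo


def _median_width(xs: np.ndarray, k: int) -> float:
    widths = [xs[hi - 1] - xs[lo] for lo, hi in (_nearest_window(xs, i, k) for i in range(len(xs)))]
    return float(np.median(widths))


def _nearest_window(xs: np.ndarray, i: int, k: int) -> tuple[int, int]:
    """[lo, hi) bounds of the k nearest sorted points to xs[i] (two-pointer)."""
    n = len(xs)
    lo, hi = i, i + 1
    while hi - lo < k:
        if lo == 0:
            hi += 1
        elif hi == n:
            lo -= 1
        elif xs[i] - xs[lo - 1] <= xs[hi] - xs[i]:
            lo -= 1
        else:
            hi += 1
    return lo, hi


def _wpolyfit_at(xc: np.ndarray, y: np.ndarray, w: np.ndarray, degree: int) -> float:
    """Weighted polynomial fit on centered x, evaluated at 0 (the intercept)."""
    deg = min(degree, len(np.unique(xc)) - 1)
    if deg <= 0:
        return float(np.average(y, weights=w))
    X = np.vander(xc, deg + 1, increasing=True)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return float(coef[0])


# ---------------------------------------------------------------------------
# Window-matrix serialization: TSV with the label table embedded as
# '#label' header lines, missing values written as NA, 12 significant
# digits (lossless round-trip at >= 9 significant digits).

_FLOAT_FMT = "%.12g"


def write_window_matrix(matrix: WindowMatrix, path: str | pathlib.Path) -> None:
    buf = io.StringIO()
    label_cols = list(matrix.labels.columns)
    buf.write("#labels\t" + "\t".join(label_cols) + "\n")
    for _, row in matrix.labels.iterrows():
        buf.write("#label\t" + "\t".join(str(row[c]) for c in label_cols) + "\n")
    sample_ids = matrix.sample_ids
    buf.write("\t".join(["region_id", "chrom", "start", "end", "partial"] + sample_ids) + "\n")
    vals = matrix.values.to_numpy()
    for i, (_, w) in enumerate(matrix.windows.iterrows()):
        cells = [
            str(w["region_id"]), str(w["chrom"]), str(int(w["start"])),
            str(int(w["end"])), "1" if bool(w["partial"]) else "0",
        ]
        cells += ["NA" if np.isnan(v) else _FLOAT_FMT % v for v in vals[i]]
        buf.write("\t".join(cells) + "\n")
    pathlib.Path(path).write_text(buf.getvalue())


def read_window_matrix(path: str | pathlib.Path) -> WindowMatrix:
    label_cols: list[str] | None = None
    label_rows: list[list[str]] = []
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#labels\t"):
                label_cols = line.rstrip("\n").split("\t")[1:]
            elif line.startswith("#label\t"):
                label_rows.append(line.rstrip("\n").split("\t")[1:])
            elif line.strip():
                data_lines.append(line)
    if label_cols is None or not label_rows:
        raise ValueError(f"{path}: no embedded label header")
    labels = pd.DataFrame(label_rows, columns=label_cols)
    df = pd.read_csv(io.StringIO("".join(data_lines)), sep="\t", na_values=["NA"])
    sample_ids = [c for c in df.columns if c not in ("region_id", "chrom", "start", "end", "partial")]
    if sorted(sample_ids) != sorted(labels["sample_id"]):
        raise ValueError(f"{path}: matrix columns disagree with label header")
    windows = df[["region_id", "chrom", "start", "end", "partial"]].copy()
    windows["partial"] = windows["partial"].astype(bool)
    values = df[sample_ids].copy()
    values.index = pd.Index(df["region_id"].astype(str), name="region_id")
    return WindowMatrix(windows=windows, labels=labels, values=values)


def write_regions_bed(
    matrix: WindowMatrix,
    region_ids: list[str],
    path: str | pathlib.Path,
    scores: dict[str, float] | None = None,
) -> None:
    """Export a region set as BED (chrom start end name [score])."""
    w = matrix.windows.set_index("region_id")
    lines = []
    for rid in region_ids:
        row = w.loc[rid]
        cells = [str(row["chrom"]), str(int(row["start"])), str(int(row["end"])), rid]
        if scores is not None:
            cells.append(_FLOAT_FMT % scores.get(rid, 0.0))
        lines.append("\t".join(cells))
    pathlib.Path(path).write_text("\n".join(lines) + "\n")
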