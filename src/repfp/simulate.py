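"""Synthetic replication-timing data with known cell-type structure.

The generator emulates the features of genome-wide timing profiles that
the pipeline depends on: a shared, domain-structured base profile (log2
ratios mostly within [-3, 3], autocorrelated over ~1.2 Mb so adjacent
windows are redundant), contiguous planted blocks (default 2-4 windows,
i.e. the 400-800 kb scale of developmental timing changes) in which a
random subset of cell types is offset early or late, and i.i.d. replicate
noise.  The returned ground-truth ledger records every planted block and
its per-type offsets, serving as the oracle for recovery and
classification tests.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ProbeProfile, WindowMatrix


@dataclass
class SimParams:
    """Study conditions for the simulator.

    effect_size is the magnitude of the early/late timing-ratio offset a
    type takes inside a planted block (types on opposite sides of a block's
    split differ by 2 * effect_size); noise_sd is the per-window replicate
    noise;
    signal_sd the marginal SD of the shared base profile (~1.5, so values
    stay mostly within [-3, 3] as in real log2 early/late profiles).
    """

    n_types: int = 4
    reps_per_type: int = 3
    n_windows: int = 1000
    window_size: int = 200_000
    domain_block: int = 6
    n_diff_blocks: int = 12
    block_len: int | tuple[int, int] = (2, 4)
    effect_size: float = 2.0
    noise_sd: float = 0.2
    signal_sd: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_types < 2 or self.reps_per_type < 1:
            raise ValueError("need >= 2 types and >= 1 replicate per type")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self._block_range()
        if self.n_diff_blocks * hi > self.n_windows / 4:
            raise ValueError(
                "planted blocks would cover more than a quarter of the genome: "
                f"{self.n_diff_blocks} x {hi} windows vs {self.n_windows} total"
            )

    def _block_range(self) -> tuple[int, int]:
        if isinstance(self.block_len, int):
            return self.block_len, self.block_len
        lo, hi = self.block_len
        return int(lo), int(hi)


@dataclass
class GroundTruth:
    """Simulator ledger: planted blocks, their per-type offsets, sample types."""

    blocks: list[dict] = field(default_factory=list)
    sample_types: dict[str, str] = field(default_factory=dict)
    seed: int | None = None

    @property
    def planted_region_ids(self) -> list[str]:
        return [rid for b in self.blocks for rid in b["region_ids"]]

    def to_json(self, path: str | pathlib.Path) -> None:
        pathlib.Path(path).write_text(
            json.dumps(
                {"blocks": self.blocks, "sample_types": self.sample_types, "seed": self.seed},
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | pathlib.Path) -> "GroundTruth":
        d = json.loads(pathlib.Path(path).read_text())
        return cls(blocks=d["blocks"], sample_types=d["sample_types"], seed=d["seed"])


def simulate_window_matrix(params: SimParams) -> tuple[WindowMatrix, GroundTruth]:
    """Generate a windowed timing matrix with planted differential blocks.

    The base profile is a moving average (length ``domain_block``) of
    i.i.d. normals scaled to ``signal_sd``.  Each planted block is a
    two-state region: every cell type replicates it either early
    (+effect_size) or late (-effect_size), with the split drawn per block
    (re-drawn if degenerate), so each block separates at least two types
    but generally only some type pairs.  Replicates add independent
    N(0, noise_sd^2) noise.  Deterministic under seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_windows
    db = params.domain_block

    # stationary autocorrelated base; MA(db) of N(0,1) has SD 1/sqrt(db)
    raw = rng.normal(size=n + db - 1)
    base = np.convolve(raw, np.ones(db) / db, mode="valid") * params.signal_sd * np.sqrt(db)

    windows = pd.DataFrame(
        {
            "region_id": [
                f"chr1:{i * params.window_size}-{(i + 1) * params.window_size}"
                for i in range(n)
            ],
            "chrom": "chr1",
            "start": np.arange(n) * params.window_size,
            "end": (np.arange(n) + 1) * params.window_size,
            "partial": False,
        }
    )
    region_ids = list(windows["region_id"])
    type_names = [f"type{t + 1}" for t in range(params.n_types)]

    # place one block per equal-length genome segment: contiguous, non-overlapping
    lo, hi = params._block_range()
    blocks: list[dict] = []
    offsets = np.zeros((params.n_types, n))
    if params.n_diff_blocks > 0:
        signs = _draw_block_splits(rng, params.n_diff_blocks, params.n_types)
        seg = n // params.n_diff_blocks
        for b in range(params.n_diff_blocks):
            blen = int(rng.integers(lo, hi + 1))
            start = b * seg + int(rng.integers(0, max(seg - blen, 1)))
            widx = list(range(start, start + blen))
            block_offsets = {}
            for t in range(params.n_types):
                offsets[t, widx] += signs[b, t] * params.effect_size
                block_offsets[type_names[t]] = signs[b, t] * params.effect_size
            blocks.append(
                {
                    "block_id": f"block{b + 1}",
                    "region_ids": [region_ids[i] for i in widx],
                    "offsets": block_offsets,
                }
            )

    values = {}
    sample_rows = []
    sample_types = {}
    for t, tname in enumerate(type_names):
        type_profile = base + offsets[t]
        for r in range(params.reps_per_type):
            sid = f"{tname}_R{r + 1}"
            values[sid] = type_profile + rng.normal(0.0, params.noise_sd, size=n)
            sample_rows.append({"sample_id": sid, "cell_type": tname, "replicate": f"R{r + 1}"})
            sample_types[sid] = tname
    labels = pd.DataFrame(sample_rows)
    matrix = WindowMatrix(
        windows=windows,
        labels=labels,
        values=pd.DataFrame(values, index=pd.Index(region_ids, name="region_id")),
    )
    truth = GroundTruth(blocks=blocks, sample_types=sample_types, seed=params.seed)
    return matrix, truth


def _draw_block_splits(
    rng: np.random.Generator, n_blocks: int, n_types: int, max_tries: int = 1000
) -> np.ndarray:
    """Per-block early/late (+1/-1) state of each type.

    Every block must separate >= 2 types, and every pair of types must be
    separated by at least a third of the blocks: distinct cell types differ
    at many regions genome-wide, and a scaled-down genome should preserve
    that distinctness rather than produce two types that are near-copies by
    lottery.
    """
    target_sep = max(1, -(-n_blocks // 3))  # ceil(n_blocks / 3)
    # relax toward 0 when few blocks make the pair floor infeasible
    for min_pair_sep in range(target_sep, -1, -1):
        for _ in range(max_tries):
            signs = rng.choice([-1.0, 1.0], size=(n_blocks, n_types))
            if any(np.all(row == row[0]) for row in signs):
                continue
            seps = [
                int((signs[:, a] != signs[:, b]).sum())
                for a in range(n_types)
                for b in range(a + 1, n_types)
            ]
            if min(seps) >= min_pair_sep:
                return signs
    raise RuntimeError(
        f"could not draw {n_blocks} block splits over {n_types} types"
    )


def simulate_probe_profile(
    windows: pd.DataFrame,
    window_values,
    sample_id: str = "sim",
    probes_per_window: tuple[int, int] = (35, 180),
    probe_noise_sd: float = 0.0,
    seed: int | None = None,
) -> ProbeProfile:
    """Expand per-window values into a probe-level profile.

    Per window, a probe count is drawn uniformly in ``probes_per_window``
    and probes are placed uniformly inside the window with value = window
    value + N(0, probe_noise_sd^2).  Feeding the result back through
    windowing recovers the input values (exactly when probe_noise_sd=0).
    """
    lo, hi = probes_per_window
    if lo < 1 or hi < lo:
        raise ValueError("probes_per_window must be a range with lo >= 1")
    rng = np.random.default_rng(seed)
    vals = np.asarray(window_values, dtype=float)
    if len(vals) != len(windows):
        raise ValueError("window_values length does not match windows table")
    rows = []
    for (_, w), v in zip(windows.iterrows(), vals):
        count = int(rng.integers(lo, hi + 1))
        starts = np.sort(rng.integers(int(w["start"]), int(w["end"]) - 1, size=count))
        noise = rng.normal(0.0, probe_noise_sd, size=count) if probe_noise_sd > 0 else 0.0
        for s, val in zip(starts, v + noise if probe_noise_sd > 0 else np.full(count, v)):
            rows.append((w["chrom"], int(s), int(s) + 1, float(val)))
    return ProbeProfile(
        sample_id=sample_id,
        records=pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]),
    )
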