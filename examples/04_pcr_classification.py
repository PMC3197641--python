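"""Classify a sample from PCR percent-early values at 20 fingerprint loci.

Emulates the bench workflow: a fingerprint is trained on array-scale
profiles; a new sample is measured by early/late nascent-strand PCR at
the fingerprint loci (plus control loci, excluded from scoring), giving
percent-early fractions on a different scale; the query is rescaled to
the array scale and classified by Euclidean-distance kNN.
"""

import numpy as np
import pandas as pd

from repfp import (
    MCParams,
    PcrSample,
    SimParams,
    classify_pcr,
    fit_classifier,
    select_fingerprint,
    simulate_window_matrix,
)

matrix, _ = simulate_window_matrix(
    SimParams(n_types=4, reps_per_type=3, n_windows=1000, n_diff_blocks=12,
              block_len=1, effect_size=2.0, noise_sd=0.2, seed=3)
)
fingerprint, _ = select_fingerprint(
    matrix, params=MCParams(n_candidates=100, n_iterations=2000, n_min=20, seed=4)
)
model = fit_classifier(matrix, None, fingerprint.regions, k=3)

# a "blind" sample: type2's mean profile, measured on the percent-early
# scale with measurement noise, in triplicate, plus a mitochondrial control
rng = np.random.default_rng(9)
truth = matrix.values.loc[model.regions,
                          [s for s in matrix.sample_ids if s.startswith("type2")]].mean(axis=1)
rows = []
for rep in ("R1", "R2", "R3"):
    pe = (truth.to_numpy() - truth.min()) / (truth.max() - truth.min()) * 0.8 + 0.1
    pe = np.clip(pe + rng.normal(0, 0.05, len(pe)), 0.01, 0.99)
    for rid, v in zip(model.regions, pe):
        rows.append((rid, rep, v, 1 - v, False))
    rows.append(("mito", rep, 0.5, 0.5, True))
sample = PcrSample("unknown_1", pd.DataFrame(
    rows, columns=["region_id", "replicate", "early_intensity", "late_intensity", "is_control"]))

summary = sample.percent_early_table()
print(summary.head(3).to_string(index=False))
print(f"... percent-early mean +/- SEM over 3 replicates at {len(model.regions)} loci")

result = classify_pcr(model, sample)
print(f"prediction: {result.predicted} "
      f"(3 nearest training profiles: {[(s, round(d, 2)) for s, d in result.neighbors[:3]]})")
print(f"{result.below_theta} training profiles within theta; "
      f"estimated pairwise error rate at the nearest distance: {result.error_estimate:.2%}")
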