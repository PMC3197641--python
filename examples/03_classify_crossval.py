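"""Open-set kNN classification with LOOCV and leave-cell-type-out folds.

LOOCV re-selects regions with one experiment held out and classifies it;
LCTO holds out every replicate of one cell type, whose correct call is
"Unseen" (a type absent from training).
"""

from repfp import MCParams, SimParams, lcto, loocv, simulate_window_matrix

params = MCParams(n_candidates=100, n_iterations=2000, n_min=20, seed=11)

matrix, _ = simulate_window_matrix(
    SimParams(n_types=4, reps_per_type=3, n_windows=1000, n_diff_blocks=12,
              block_len=1, effect_size=2.0, noise_sd=0.2, seed=7)
)
table, accuracy = loocv(matrix, None, params, runs_per_fold=10)
print(f"LOOCV: {int(table['correct'].sum())}/{len(table)} held-out experiments "
      f"assigned their true cell type (accuracy {accuracy:.0%})")

matrix5, _ = simulate_window_matrix(
    SimParams(n_types=5, reps_per_type=3, n_windows=1000, n_diff_blocks=12,
              block_len=1, effect_size=2.0, noise_sd=0.2, seed=7)
)
table = lcto(matrix5, None, params, runs_per_fold=10)
full = int((table["fraction_unseen"] == 1.0).sum())
print(f"LCTO: {full}/{len(table)} held-out cell types fully called 'Unseen' "
      f"(no training neighbor within the threshold theta)")
print(table.to_string(index=False))
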