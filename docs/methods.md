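# Methods

## Data model and windowing

A replication-timing profile is a per-probe log2(early/late) ratio along
the genome; positive values replicate early. Probes are averaged into
non-overlapping windows (default 200 kb — large enough that 35–180 array
probes fall in a window, small enough to resolve the 400–800 kb units at
which developmental timing changes occur). Decisions the data formats do
not fix, made once:

- Coordinates are 0-based half-open (BED/bedGraph convention). A probe
  belongs to the window containing its midpoint — a single unambiguous
  rule for probes straddling window edges. Three-column (chrom, position,
  value) input is stored as the 1 bp interval [position, position+1), so
  both input formats window identically.
- Windows tile each chromosome from coordinate 0; terminal windows
  truncated by the last probe are kept and flagged `partial`.
- A window with fewer than `min_probes` (default 5) probes in a sample is
  missing for that sample; all downstream stages use the complete-case
  view (rows with no missing value in any sample) — the simplest
  defensible missing-data policy. Quantile normalization requires a
  complete matrix for the same reason; z-scoring tolerates missing
  entries.
- Sample standard deviations use the n−1 convention everywhere.

LOESS smoothing (display only, never upstream of selection) is a locally
weighted polynomial regression of degree 2 with tricube weights. The span
is given in bp (default 300 kb) and converted per chromosome to a
neighborhood size k by binary search so that the median width spanned by
the k nearest probes matches the span; this keeps the smoothing scale in
genomic units on unevenly spaced probes. Duplicate-x neighborhoods fall
back to lower degree automatically.

## Distances, the distance ratio, and θ

The distance between two samples over a region set is the L1 sum of
absolute timing differences (the selection objective's metric) or the
Euclidean distance (the default for reported distance matrices and for
PCR classification); both are exposed everywhere. Unordered sample pairs
split into within-type (mean χ_S) and between-type (mean χ_D); self-pairs
are excluded as uninformative. The distance ratio dR = χ_D/χ_S is
scale-invariant and is the quantity the region search maximizes.

The classification threshold θ minimizes the error count
#{within > θ} + #{between ≤ θ} over the intervals between consecutive
pooled distance values (plus the two extremes). Error counts are constant
on each interval, so the scan is exhaustive by construction. Ties across
intervals resolve to the lowest-distance interval — the conservative
choice, pushing borderline queries toward `Unseen` — and θ is that
interval's midpoint. Pairs at distance exactly θ count as same-type.

## Annealed region selection

The candidate pool is the `n_candidates` (default 2000) complete-case
windows of highest across-sample SD, ties broken by genomic order. The
search starts from a uniformly random half of the pool and proposes one
move per iteration; proposal weights are remove 0.5 / swap 0.4 / add 0.1
above the minimum size and swap 0.8 / add 0.2 at it, so the set shrinks
toward `n_min` while the ratio climbs. A proposal with ratio change Δ is
accepted with probability min(1, exp(Δ/T)) — the standard Metropolis
rule; the temperature decays geometrically (factor 0.9995/iteration).
When no initial temperature is given it is calibrated from a 200-proposal
probe of the start state so that a median-sized worsening move is
accepted with probability ~0.5.

Numerical choices: pair distances are maintained as running per-pair sums
and recomputed exactly every 1000 iterations to cap float drift; the
returned fingerprint is the best-visited state of size exactly `n_min`
(default 20), re-scored from scratch so that re-evaluation reproduces the
recorded ratio bit-for-bit; a within-type mean distance of zero (possible
on noise-free synthetic data) is floored at 1e−6 with a warning rather
than allowed to divide by zero. For the L1 metric the ratio is a ratio of
per-region sums, so the optimum over subsets of size ≥ n_min is attained
at size n_min — returning a fixed-size set loses nothing.

Consensus over repeated seeded runs keeps regions included in ≥75% of
runs; ranking (needed for "top N" fingerprints) is by inclusion
frequency, ties by a per-region separation score (mean between-type minus
mean within-type absolute timing difference), then first-seen order.
Direction annotation labels a region `EtoL` when group A replicates it
earlier than group B (e.g. early in pluripotent cells, later after
commitment) and `LtoE` otherwise.

## Open-set kNN classification

A fitted model stores the fingerprint regions, training values, the
within/between distance distributions and θ. Only training samples at
distance ≤ θ from the query are eligible neighbors: none ⇒ `Unseen`;
otherwise the min(k, #eligible) nearest vote by majority, with ties
broken by smallest mean distance among tied types, then lexicographic
label order — every tie rule is deterministic. The per-query
`error_estimate` is the training pairwise error rate evaluated at the
nearest-neighbor distance. k defaults to 3, the smallest value that keeps
single-replicate lines classifiable through other lines of the same type.

Both crossvalidation harnesses refit everything per fold — region
selection (consensus over `runs_per_fold` seeded runs, default 10, a
scaled-down stand-in for 100 genome-scale runs), classifier and θ — so no
information from the held-out data leaks into selection or the threshold.
LOOCV scores accuracy at the cell-type level; LCTO reports, per held-out
type, the fraction of its replicates called `Unseen` and any alternative
labels. A held-out type genuinely intermediate between two training types
may be labelled as the nearest one; that ambiguity is expected behavior
for closely related types, not an error state.

## PCR pathway

Timing at a locus measured by early/late nascent-strand PCR is
percent-early = early/(early+late) after background subtraction, averaged
over replicates with its SEM. Percent-early values live on a different
scale than array log2 ratios, so the query vector is standardized and
mapped to the mean/SD of the training values over the shared regions
("equivalent root-mean-square" rescaling). Consequences, by construction:
the rescaled output matches the reference moments to float precision, and
any monotone affine distortion a·v+b (a>0) of the raw measurements yields
an identical classification. The reference statistics are those of the
fingerprint regions actually queried (the only values entering the
distance), not global array statistics. θ is refit on training distances
restricted to the shared regions, because absolute distances shrink with
fewer regions; at least 5 shared non-control regions are required.
Control loci (mitochondrial DNA, globins) are carried through reporting
but never enter the distance.

## Synthetic data generator

The generator emulates the features of genome-wide profiles the pipeline
depends on, with defaults chosen once:

- **Base profile**: a moving average (window `domain_block` = 6 windows ≈
  1.2 Mb) of i.i.d. normals, scaled to marginal SD 1.5 so values lie
  mostly within [−3, 3] as in real log2 profiles. The autocorrelation
  makes adjacent windows redundant, which is what the selector faces in
  real data; nothing downstream depends on the exact autocorrelation
  form.
- **Planted differential blocks**: contiguous runs (default 2–4 windows ≈
  400–800 kb, the scale of developmental timing changes) in which every
  cell type replicates either early (+`effect_size`) or late
  (−`effect_size`). The split is drawn per block and re-drawn if it fails
  to separate at least two types. Splits are additionally drawn subject
  to every pair of types differing at ≥ ⌈n_blocks/3⌉ blocks (relaxed
  automatically when too few blocks make that infeasible): any two
  distinct cell types differ at many regions genome-wide, and a
  scaled-down genome should preserve that distinctness rather than
  produce two types that are near-copies by lottery. Types on opposite
  sides of a split differ by 2·effect_size at that block.
- **Replicates**: independent N(0, noise_sd²) per window; default
  noise_sd 0.2 against effect_size 2.0. The within-type L1 distance per
  region has closed form 2·noise_sd/√π (mean absolute difference of two
  independent normals), which the calibration test checks to 10%.
- The ground-truth ledger (planted blocks, per-type offsets, sample
  types) is returned alongside the matrix and is the oracle for recovery
  and crossvalidation tests.

What the generator does **not** emulate: S-phase sorting artifacts,
copy-number and GC/isochore covariates, chromosome structure beyond one
synthetic chromosome, probe-level platform effects (beyond optional
i.i.d. probe noise), and biological heterogeneity within a sample.
Passing tests therefore demonstrate the correctness and statistical
behavior of the algorithms under the stated model, not performance on
any particular array platform.

## Problem sizes

Tests and the acceptance script run the pipeline at desk scale, chosen as
the package's own study conditions: 1000-window genomes with a
100-region candidate pool, 2000 annealing iterations, 10–20 runs per
consensus, and 10 runs per crossvalidation fold (the genome-scale
defaults — pool 2000, ≥20 000 iterations, 100 runs — remain the
parameter defaults). The exhaustive-search comparison uses a 12-region
universe where all 4083 subsets of size ≥2 can be enumerated. At these
sizes the full test suite and the acceptance script each complete in well
under a minute of CPU.

## Known limitations

- The annealing schedule (auto-calibrated T0, cooling 0.9995) is a
  standard choice, not tuned per dataset; any schedule satisfying the
  trace invariants is acceptable, and pathological objectives could
  require slower cooling.
- Complete-case filtering can discard many windows on sparse platforms;
  no imputation is attempted.
- The classifier is supervised: it can only name types present in
  training, and `Unseen` calls for types intermediate between training
  types are not guaranteed.
- Euclidean distances over region subsets are not separable per region,
  so the fixed-size-optimum argument above holds only for L1; selection
  under Euclidean is supported but may benefit from larger n_min.
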