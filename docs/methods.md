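# Methods

## Model

A cis-regulatory module is modelled as an unordered pair of position weight
matrices (PWM1, PWM2) with minimum normalized scores (Thr1, Thr2) and a
maximum separation D between the two occurrences. For a promoter set S with
n sequences, the module's presence C is the fraction of sequences containing
at least one instance. Given a positive set S⁺ and a negative set S⁻, the
search returns, for every PWM pair in a library (homotypic pairs included),
the configuration maximizing C⁺/C⁻ subject to C⁺ ≥ Cmin⁺ and C⁻ ≤ Cmax⁻, and
ranks pairs by that optimal ratio. The model deliberately imposes no order
or strand constraint between the two motifs: all four strand combinations
and both upstream/downstream arrangements count, the weakest structural
assumption for a candidate module.

## Scoring and coordinates

A PWM is an additive per-position weight matrix. A window's raw score is
min-max normalized with the matrix's achievable extrema, so every score
lies in [0, 1] with 1.0 attained exactly by the best word. This
normalization is a convention choice isolated in one function
(`crmscan.io.normalized_score`); thresholds everywhere in the package live
on this scale. Matrices supplied as counts (JASPAR, TRANSFAC) are converted
to log₂ odds against a uniform background with a pseudocount of 0.25 per
cell; matrices containing negative values are taken as weights verbatim.

Reverse-strand occurrences are scored by applying the forward matrix to the
reverse-complemented window, accumulating positions in forward matrix
order. This is mathematically identical to scoring with a
reverse-complemented matrix, but because floating-point addition is not
associative the chosen order has a useful consequence: reverse-complementing
every input sequence swaps the strands' scores bit for bit, so search
results are exactly strand-invariant rather than invariant only to
tolerance.

Windows containing N are skipped rather than scored. Coordinates are
0-based half-open internally and 1-based inclusive in user-facing instance
reports. The distance between two occurrences is the nearest-edge gap
(end-exclusive of the upstream occurrence to the start of the downstream
one): 0 means adjacent, overlapping occurrences are never paired, and D is
independent of motif widths. This is the single place to change if a
start-to-start convention is ever preferred.

## The monotone count grid

For one pair and one set, the grid cell (i, j, k) counts sequences with at
least one occurrence pair at (thr_values[i], thr_values[j],
dist_values[k]). Counts are monotone — non-decreasing as either threshold
falls or the distance bound rises — because relaxing a parameter can only
admit more instances. Each sequence's contribution is therefore a union of
axis-aligned boxes anchored at its (s1, s2, gap) triples; the indicator is
built by marking each triple's strictest satisfied cell and closing under
the monotone order with one cumulative-maximum pass per axis, instead of
testing every cell against every triple. Scanning uses the lowest grid
threshold as score floor and the largest grid distance as gap bound, since
nothing below either can reach any cell.

The optimizer computes the positive-feasible region first and skips the
negative set entirely for pairs where it is empty — an acceleration with no
effect on results, which the test suite enforces by comparing the entire
output (pair set, configurations, presences, ratios, order) against a
brute-force per-cell reference on randomized instances.

## Grids, ratio guard, tie-breaking

* Threshold axis: 0.50 to 1.00 in steps of 0.01 (51 values, shared by both
  axes); distance axis: 0 to 200 nt in steps of 5 (41 values). Both are
  fully configurable (`SearchGrids.from_steps`); the defaults keep a pair's
  grid near 10⁵ cells and cover the operating points relevant for promoter
  work. The threshold floor doubles as the scan floor, so lowering
  `--thr-min` widens the search at proportional cost.
* C⁻ = 0 leaves the ratio undefined; the package uses
  ratio = C⁺ / max(C⁻, ε) with ε = 1/(2n⁻) by default. This ranks modules
  absent from the negatives above any module seen in even one negative
  sequence and orders them among themselves by C⁺, deterministically.
* Ties at equal ratio are broken by larger C⁺, then larger Thr1 + Thr2,
  then smaller D, then lexicographic names, then smaller Thr1. Thresholds
  are preferred before distance deliberately: with the ε guard, a true
  implanted pair and a homotypic "strong implant plus weak background
  partner" module often tie on ratio and C⁺, and preferring small D first
  would elect the spurious, unspecific configuration. Preferring the
  highest thresholds selects the most specific, most reproducible module
  and makes the reported D track the actual spacing of the instances (the
  tightest bound covering them).

## Synthetic data

The generator emulates a controlled discrimination experiment: i.i.d.
background sequences (default uniform base composition, 500 nt, 30 + 30
sequences), with each sequence independently carrying one implanted motif
pair with probability equal to its set's implant fraction (defaults 0.9
positive / 0.0 negative). Words are drawn from the PWM's per-position base
distribution and rejection-sampled to a normalized score of at least 0.95
by default; the two words are placed in random order and orientation with a
gap uniform on [0, 50] nt, overwriting the background so lengths are
preserved. One seeded generator drives everything; identical specs produce
byte-identical FASTA/truth output. A companion fixture implants a motif
together with its exact reverse complement at equal fractions in both sets,
reproducing the correlated-PWM situation that the negative-set constraint
must suppress.

What the generator does **not** emulate: real promoter base composition and
repeats (no Markov background), motif indels, multiple modules per
sequence, and co-factor dependencies between word strengths. Passing tests
on this data demonstrate correctness of the search semantics — exact
optimality, monotonicity, invariances, recovery under the stated signal
strength — not recognition performance on biological promoters.

## Numerical and degenerate-input choices

* Scores landing exactly on a grid value count as passing that threshold
  (comparisons are ≥ / ≤ throughout), and the accelerated and brute-force
  paths accumulate scores in the same order so their comparisons agree bit
  for bit.
* Sequences shorter than a matrix yield no hits (not an error); empty
  promoter sets, empty libraries, duplicate ids and non-nucleotide
  characters are hard errors.
* Evaluation metrics with a zero denominator (e.g. PPV with no predictions)
  are reported as undefined (`None`/"undefined"), never as 0, since
  averaging conventions differ between benchmarks.
* The brute-force reference refuses instances above a configurable
  cell-count ceiling (default 2×10⁷ cell-sequence evaluations) to prevent
  accidental runaway runs.

## Problem sizes used in the shipped checks

The oracle-equivalence corpus uses 50 randomized micro-instances (5–8
sequences per set of 150–250 nt, 2–3 random PWMs of width 4–8, threshold
step 0.05, distances {0, 10, …, 50}); recovery and suppression experiments
use 20–30 sequences per set at 400–500 nt on the default grids. These sizes
were chosen to exercise every code path — non-trivial feasible regions,
homotypic pairs, empty results — while keeping the whole suite quick to run
on a laptop.

## Known limitations

* Exactly one optimal configuration is reported per pair; co-optimal cells
  are resolved by the deterministic tie-break chain, not enumerated.
* The threshold grid is shared by both axes (per-PWM grids would square the
  configuration count for no clear gain at this resolution).
* No per-position p-values or background-corrected log-likelihood scores;
  the min-max normalized score is the only motif-strength scale.
* No third motif, minimal-distance constraint, or cooperativity score; the
  search space is deliberately three-dimensional.
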