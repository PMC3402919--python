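# Methods

`fuzzytr` detects *fuzzy* tandem repeats (TRs) in protein sequences:
arrays of two or more adjacent copies of a unit that have diverged by
substitutions and indels while remaining homologous.  This note records
the model, the algorithmic choices, the defaults and why they are what
they are, and what the synthetic experiments do and do not demonstrate.

## The weighted repeat model

### From similarity scores to a distance

Amino-acid similarity matrices (BLOSUM family) score pairs of residues
by log-odds similarity `M_ij`.  The detector needs costs, not scores.
The standard metric-space construction is used:

    D_ij  = M_ii + M_jj - 2 M_ij
    C_ij  = D_ij / D_max,     D_max = max over pairs of D_ij

so `C` is symmetric, zero on the diagonal, and normalized to `[0, 1]`
with at least one pair at exactly 1.  Insertions and deletions cost a
flat `indel_cost = 1` — an indel is never cheaper than the worst
substitution.  The weighted edit distance `D(a, b)` between sequences
is the usual minimum-cost edit script under these costs (dynamic
programming; the kernels are numba-compiled).

These costs are *almost* a metric: an exhaustive scan of all 20³
residue triples (`triangle_inequality_audit`) reports the rare
triangle-inequality violations rather than repairing them; the unit-cost
model (every substitution costs 1) recovers classical edit distance
exactly and is available as `matrix="unit"`.

### Divergence budgets and E(C)

Budgets are expressed relative to what *random* sequence would show.
`E(C)` is the expected cost of one substitution:

    E(C) = sum_{i != j} p_i p_j C_ij / sum_{i != j} p_i p_j

i.e. the mean substitution cost conditional on the residues differing.
The conditional form is deliberate: it makes the unit-cost model give
`E(C) = 1` exactly, so the budget `mu * p * E(C)` degenerates to the
classical "`mu` fraction of mismatches" budget.  The background `p` is
uniform by default (reproducible and composition-agnostic); a
composition-derived background is a configuration option.  A Monte-Carlo
estimator exists purely to audit the closed form.

### The Steiner repeat definition

A span decomposed into units `x_1 .. x_t` (t >= 2) is a valid fuzzy TR
for parameters `mu` in [0, 1] and `c` in [1, 2] when

    (a)  D(x_i, x_{i+1}) <= c * mu * |x_i| * E(C)    for consecutive units
    (b)  there exists a consensus (Steiner) string xbar with
         D(xbar, x_i)    <= mu * |x_i| * E(C)        for every unit

Condition (b) bounds each copy's divergence from a common ancestor
string; condition (a) additionally forbids adjacent copies from
diverging wildly from each other (it is vacuous when `mu >= 1/c`).
Defaults are `mu = 0.3`, `c = 1.5`; `c = 2` is the natural choice for
low-divergence work because then (a) follows from (b) by the triangle
inequality.

Exact Steiner strings are intractable, so (b) is certified with an
explicit consensus built by center-star progressive alignment (center =
unit minimizing total distance to the rest, ties to the earliest) and a
column-wise vote choosing, per column, the cheapest option among every
residue (substitution costs to the column plus one indel per gap row)
and column deletion (one indel per residue row); ties prefer keeping a
residue, then the alphabetically first.  A certificate can only be
conservative: if the approximate consensus satisfies (b), a Steiner
string exists; a marginal repeat whose only valid consensus is better
than center-star may be under-reported.

## The detection pipeline

1. **Blocks.**  Sequences are processed in blocks of `block_len = 2000`
   residues overlapping by half a block, so q-gram pairs are only
   counted when close enough to belong to the same local repeat.
   Candidate extension (step 5) runs on the full parent sequence, so
   repeats longer than a block are still recovered; duplicates found in
   two overlapping blocks collapse in the final filters.  The overlap
   scheme is this package's own carry-over design.

2. **Seed scan.**  The complete gapped 3-gram family with span 2–4
   (`###`, `#-##`, `##-#`, `##--#`, `#-#-#`, `#--##`; six seeds) slides
   over the block.  Two grams are *homologous* when at least two sampled
   positions are identical and the residues at the one differing
   position are mutually within the top `z` of each other's similarity
   ranking (`z = 1` means exact; 3 and 5 progressively looser; ranking
   ties broken alphabetically, so runs are deterministic).  For every
   seed and anchor position the next `h = 5` homologous occurrences are
   recorded; each yields a candidate period `k` = distance between the
   anchors.  The optional `##` 2-gram seed (identity-only homology) is
   off by default, keeping the advertised six-seed family.  The scanner
   is a numba kernel implementing this definition directly; a pure
   Python definitional scanner backs it in the test suite.

3. **Period weighting.**  Indels between matching probes smear the
   detected period.  Anti-smear weighting counters this: each detected
   period `k_g` gains `sum over k in Q of 2^-|k_g - k|`, where `Q` holds
   the last `H = 20` detected distances in scan order (one shared queue
   across seeds; increments within one probe are evaluated against the
   pre-probe queue, making them order-independent; the queue fills to
   capacity before dequeuing starts).  Multiplicity weighting then folds
   harmonics onto the fundamental, `w1(k) = sum over m of w0(m k)`,
   because many-copy repeats also match at multiples of their period.
   The `L = 50` best periods by `w1` (ties to the smaller period)
   proceed.

4. **Positional density.**  For each top period `k`, the scan positions
   that supported `k` or a multiple of it (first probe of each hit,
   counted once) are marked, smoothed with a `k`-wide sliding window
   `F`, and thresholded at `alpha * mean(F)` with `alpha = 1` by
   default; the mean runs over all window positions, and an empty
   contributor set yields no candidates.  Candidate positions are
   thinned to the first position of each maximal run plus one anchor per
   period-length of run — validation re-derives exact boundaries, but a
   long run (one repeat array) deserves more than a single growth
   attempt.

5. **Validation.**  From candidate `(k, i)` the seed window
   `seq[i : i+k]` grows one unit at a time, rightward then leftward.
   The next unit's boundary floats: the running consensus is aligned
   against a window of width `p + delta` and the best-cost prefix
   length is taken.  A unit is accepted while within `1.2x` the
   condition-(b) budget of the running consensus; a unit over that
   budget may still be accepted through the condition-(a) pair budget
   against its neighbor (the first extension necessarily is, since only
   one unit exists; an isolated divergent unit is often covered once the
   final consensus includes it), but never twice in a row — when
   `c * mu * E(C)` approaches the maximal per-residue cost the pair
   budget stops rejecting anything, and consecutive pair-budget
   acceptances would coast through random sequence.  The consensus is
   re-derived after every acceptance.  Growth is followed by strict
   re-checking of (a) and (b) with no slack, trimming violating units
   from the nearer end, then one strict re-extension pass per round
   (growth decisions were made against an immature consensus; a unit it
   rejected may fit the final one), bounded to three rounds.  Fractional
   leading and trailing copies (up to `p - 1` residues matching a
   consensus suffix/prefix within the pro-rata budget) complete the
   span.  A repeat is reported when at least two full units survive,
   the span is at least 6 residues, and span/period >= 2.

6. **Filters.**  Repeats strictly enclosed in another's span are
   dropped; among identical spans the shortest period wins; output is
   sorted by start position.  Reported fields: 0-based inclusive span,
   period (consensus length), fractional copy number (span/period, one
   decimal in tables), total length, consensus, and mean divergence
   (unit-to-consensus distance normalized by `|x_i| * E(C)`).

Non-canonical residues: B, Z, U, O are canonicalized to D, E, C, K with
a warning; anything else becomes X, which never matches inside a
sampled gram position and substitutes at the maximal cost 1 in the
alignment (gapped seeds may legitimately straddle an X they do not
sample).

The detector is fully deterministic: identical input and configuration
give identical output.

## Statistical significance

Are the repeats found in real sequences distinguishable from what the
detector reports on random sequences of the same composition?  Each
sequence is paired with one uniform shuffle of itself (identical residue
multiset, per-pair seeds derived from a master seed by a counter), the
detector runs on both, and the longest reported repeat lengths — floored
at the 6-residue reporting limit — form a matched pair for a one-tailed
Wilcoxon signed-rank test (alternative: original longer).  Pairs where
neither run reports anything are ties and excluded; zero differences
after flooring are dropped by the standard signed-rank zero policy
(scipy's `wilcox` method, exact null for small untied samples).  The
test is run per length class; `p < 0.05` rejects the null that shuffling
does not affect the longest repeat.

## Synthetic data

`generate_planted_tr` implants a tandem array into a random background:
unit and background drawn from a residue composition (default:
Robinson–Robinson average protein frequencies), each copy independently
mutated per position — substitution with the stated rate (replacement
drawn from the composition, forced to differ) and indel with the stated
rate (insertion or deletion equally likely, inserted residues from the
composition).  The generator returns the true implanted span for
recovery scoring.

What this emulates: local repeat arrays of controlled unit length, copy
number and divergence inside composition-realistic but otherwise
unstructured backgrounds.  What it does not: positional composition
bias, low-complexity and disordered regions, correlated (domain-level)
mutations, or the BLOSUM-biased substitution spectrum of real evolution
(replacements are composition-random, which if anything makes planted
repeats *harder* to validate under a BLOSUM metric than real ones).
Passing the synthetic suites therefore demonstrates detection power and
false-positive control under the stated noise model, not corpus-level
performance on any particular proteome.

## Experiment scales and expected numbers

The bundled experiments (test suite and `scripts/acceptance.py`) use
these problem sizes, chosen as the package's standard benchmark
conditions:

- **Planted recovery**: 100 fixtures, 600-residue backgrounds, unit
  length 10–50, 4–10 copies, 10–20% substitutions, 2% indels; a fixture
  counts as recovered when one reported repeat covers >= 90% of the
  planted span (BLOSUM50, z = 3, mu = 0.3, c = 1.5).  Typical recovery
  is ~90–94/100.  The residue is informative: at the top of the
  substitution range many planted arrays are *not* valid Steiner repeats
  at the planted period — direct evaluation of the true decomposition
  shows units exceeding the strict budget — so fragmenting them is the
  definitionally correct output.
- **Shuffled controls**: 100 shuffled composition-matched sequences of
  400–1000 residues under the significance parameterization (BLOSUM50,
  z = 1, mu = 0.3, c = 1.5): mean longest reported repeat ~8, maximum
  ~19–25 depending on seed.  Every such hit re-verifies against the
  strict definition — loose budgets admit occasional short repeats in
  random sequence; this is a property of the definition, not a detector
  artifact.  Under the unit metric the mean longest stays below 20,
  consistent with the repeat-length threshold of 20 used for corpus
  summaries being well clear of chance.
- **Significance**: corpora of 30 strong planted repeats (400 residues,
  unit 15, 12 copies, 8% substitutions) reject the shuffle null at
  p < 0.05 essentially always (p ~ 1e-6 with ~25-30 informative pairs).

## Numerical and design choices

- Cost comparisons use absolute tolerance 1e-9; the triangle audit
  1e-12.  Alignment traceback ties prefer match/substitution, then
  deletion, then insertion.
- `E(C)` background: uniform by default (see above).
- Neighbor-ranking ties: alphabetical; self is always rank 0.
- Growth slack 1.2x: wide enough to survive per-unit sampling noise in
  divergence, small enough that the strict re-check rarely trims more
  than an edge unit.
- Window float `delta` for unit extension: `max(2, budget)` residues —
  an accepted unit cannot contain more indels than its cost budget.
- Block carry-over by half-block overlap is this package's design; the
  per-block confinement of the scan is what bounds memory and time on
  long sequences.
- The candidate skip (`_covered`) only suppresses candidates of a period
  *equal* to an already-accepted repeat covering the window — broader
  skipping measurably blocked rescue of truncated arrays at multiple
  periods.

## Known limitations

- The center-star consensus is an approximation; condition (b) can be
  under-certified for marginal repeats (never over-certified).
- Greedy bidirectional growth does not backtrack across alternative unit
  segmentations; arrays whose only valid decomposition has irregular
  unit boundaries may be reported fragmented.
- Period drift: the reported period is the final consensus length,
  which can differ by a residue or two from the seeded candidate period
  when indel columns survive the vote.
- Corpus-level percentages (fraction of a proteome with repeats above a
  length threshold) depend on the corpus; `scan_summary` computes them
  for whatever FASTA stream it is given, and no proteome ships with the
  package.
- BLOSUM30 and BLOSUM70 are not bundled (45/50/62/80/90 are); any
  NCBI-format matrix file can be supplied by path.
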