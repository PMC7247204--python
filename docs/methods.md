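# Methods

## Microhomology by placement equivalence

A deletion whose flanks share a k-bp identical sequence has no unique pair
of breakpoints: k+1 distinct contiguous windows of the reference produce
the identical mutant molecule. `spidel` takes this placement count as the
*definition* of junction microhomology (`mh_len = placements − 1`) rather
than comparing fixed-width flanks. The definition is oracle-checkable — the
test suite enumerates every deletion window of small references and counts
identical mutants — and it reproduces the field's range notation exactly:
a printed placement range `A–B → C–D` has span `B − A + 1 = mh_len + 1`.

The caller finds the placement set by flank extension: the window
`[start, end)` can shift left by s iff `ref[start−i] == ref[end−i]` for
i = 1..s, and right symmetrically. The canonical placement is the left-most
one (VCF left-alignment convention), and the microhomology sequence is the
k bases at the junction, which provably occur both as the prefix of the
deleted segment and as the start of the retained right flank. Consequences
worth noting:

* a 1-bp deletion inside a mononucleotide run of length L has L placements,
  so `in_run` (the replication-slippage signature) is equivalent to
  `mh_len ≥ 1` for size-1 events; the run threshold is length ≥ 2;
* a size-k deletion inside a run of length L ≥ k has L − k + 1 placements,
  not C(L, k): non-contiguous base subsets are not placements;
* ties between "left" and "right" homology readings cannot arise — the
  placement set is a single contiguous interval of shifts.

For deletions carrying a junction insertion, microhomology is computed
between the retained flanks ignoring the inserted bases, and such events
form their own spectrum class regardless of flank homology. Whether the
original observers computed their annotation the same way for these rare
rows is not documented; this convention is explicit and applied uniformly.

Recovering an event from a raw mutant sequence uses maximal common
prefix/suffix trimming. Every difference between two strings is formally
representable as one deletion plus one insertion; the recovered event is
the *minimal* (maximally trimmed) representation, then left-aligned. An
inserted base identical to the adjacent deleted base is therefore absorbed
into the flank (e.g. del GCGC + ins CC collapses to del GCG + ins C) —
the simulator avoids generating such degenerate events (see below).

## Breakpoint notation

Positions are 1-based "last retained → first retained"; deletion size is
`first_retained − last_retained − 1`, always gross of any junction
insertion (insertions are reported separately, never netted into size).
Accepted forms: `A → B`; `A–B → C–D` (equal spans required); an
`(k bp(s) ins.)` suffix; a bare deleted-region `A–B` with a printed size
and junction sequence (the union of equivalent deleted segments); short
context changes (`ttAtt→tttt`, `AAAAA→AAAA`) for 1-bp events, compared
case-insensitively with capitals marking the changed bases. Thousands
separators and all dash variants are accepted. Reversed or multi-segment
coordinates fail parsing and the record is retained as COMPLEX — counted
in totals, excluded from junction statistics.

In the bundled table, a handful of printed rows are internally inconsistent
(size vs coordinates, or placement span vs junction annotation). These rows
carry a `flag` and are not corrected: the printed size is used for
reporting, and the junction-sequence annotation is authoritative for
microhomology length wherever the two disagree, on the grounds that the
junction sequence is the primary observation while coordinate ranges are
derived. No class assignment or >1 kb call changes under either reading.

## Spectrum classes and statistics

Seven mutually exclusive classes, in report order: 1-bp deletion in run /
other; ≥2-bp deletion with microhomology / without / with junction
insertion; pure insertion; complex. The "≥ 2 bp" boundary follows the
published table structure, which groups 2- and 3-bp deletions with the
larger NHEJ-type deletions.

Junction statistics over one group's ≥2-bp deletions:

* `mh_fraction` — microhomology-bearing deletions over *all* ≥2-bp
  deletions, including junction-insertion ones (this denominator is what
  makes the published 21/35 reproducible);
* `mean_mh_len` — over microhomology-bearing deletions only, with an
  optional `exclude_mh_above` threshold (default off) for quoting a mean
  with an explicit outlier exception, as done for a 12-bp-homology record;
* `large_fraction` — deletions larger than `large_threshold` (default
  1000 bp);
* `insertion_fraction` — records carrying any inserted bases (junction
  insertions plus pure insertions) over *all* records of the group.

A group with no ≥2-bp deletions raises an explicit undefined-statistic
error instead of returning 0. Duplicate identical mutants are kept by
default (recurrent hotspot mutants are genuine observations in these
assays); `clonal_correction` collapses per-animal duplicates when asked.

## Frequencies and comparisons

Per-animal MF = confirmed mutants / rescued pfu; groups are summarized as
mean ± SD (n−1). Specific MFs multiply the *group mean* MF by the class
ratio among sequenced deletion mutations, so a group's specific MFs sum to
its total MF by construction. Fold changes in the report are quoted from
specific MFs rounded to 2 decimals (in 1e-6 units), matching how such
values are conventionally printed and combined; the full-precision ratio is
always written alongside.

Group comparisons use all-pairs Tukey HSD on raw per-animal MFs: pooled
within-group variance, Tukey–Kramer standard error
`sqrt(MSE/2 · (1/nᵢ + 1/nⱼ))` for unequal group sizes, and p-values from
the studentized range distribution (scipy's implementation, accurate to
well beyond 4 significant figures). Monte-Carlo helpers for operating
characteristics (`null_familywise_error_rate`, `pairwise_detection_rate`)
vectorize thousands of replicates and decide each pair against the single
critical value `q_crit = ppf(1−α)`, the same decision rule as the per-pair
p-value comparison. No transformation is applied to MFs before testing, and
no Poisson-regression alternative is offered; the test spans all groups of
one organ.

## Synthetic data generator

The generator exists to validate the analysis, not to model radiobiology.
Defaults mirror the emulated study's brain arm: four groups (wild-type and
DNA-PKcs-deficient, sham or 10 Gy) with 10/8/6/7 animals, group mean MFs of
1.03/5.00/0.85/2.89 × 10⁻⁶, and 3–5 × 10⁵ rescued pfu per animal; mutant
counts are Poisson (the rare-event limit of the plaque assay — binomial
would be indistinguishable at MF ~10⁻⁶).

* **Reference**: uniform i.i.d. 6-kb sequence with planted 4–6-mer
  homopolymer runs at 2 runs/kb (recorded as features), giving the
  slippage substrate.
* **Events** per mutant, with per-group probabilities (irradiated default
  0.42/0.08/0.49/0/0.01 over slippage / other-1-bp / DSB deletion / pure
  insertion / complex, mirroring the irradiated wild-type spectrum;
  unirradiated default 0.72/0.08/0.12/0.08/0):
  slippage deletes one base of a run; "other" deletes a lone base;
  DSB deletions draw a log-uniform size (2 bp–10 kb, clipped) and a
  breakpoint pair weighted by `placements^mh_bias` (default bias 2.0,
  which yields a realistic ~60% microhomology fraction; bias 0 is uniform),
  plus a junction insertion with probability 0.06 (1 + geometric(0.5)
  bases, truncated at 22, the largest insertion observed in vivo);
  pure insertions duplicate a run base.
* **Ground truth** stores the realized canonical call computed by the same
  placement-equivalence definition as the caller, so end-to-end agreement
  is exact, not approximate — a definitional consistency check, as well as
  an implementation check of parser/caller/classifier round trips.
  Inserted sequences are constrained so their first/last base differs from
  the canonical flanking deleted bases; otherwise the deletion+insertion
  decomposition of the mutant molecule would be non-unique and "exact
  agreement" ill-posed.
* **Reproducibility**: one integer seed; a `SeedSequence` spawns one
  substream for the reference and one per animal. Identical seeds give
  byte-identical output tables.

What the generator does *not* emulate: packaging/plating efficiency,
sequencing error, dose–response kinetics, chromatin context, clonal
expansion within an animal, and multi-segment rearrangements beyond an
opaque COMPLEX label. Passing recovery tests therefore validates the
analysis pipeline's correctness on NHEJ-like deletion spectra, not any
biological claim about real tissues.

## Problem sizes and numerical choices

Validation uses an exhaustive caller-vs-enumeration check over all two-letter
references up to length 12 with deletions up to 4 bp (~350k calls), 1000
simulated mutants for exact ground-truth agreement, 2000 null replicates
(4 groups × 8 animals) for the Tukey family-wise error rate, and 500
replicates for power at a 5-SD separation; these sizes give tight Monte
Carlo error (FWER SE ≈ 0.005) while keeping the whole suite in seconds.
Frequencies are held as plain floats (magnitudes ~10⁻⁶ are far from any
precision limit); percentages and MFs are rounded only at the presentation
layer. Degenerate inputs fail loudly: empty groups, zero rescued pfu,
zero-denominator fold changes and statistics all raise typed errors rather
than returning silent zeros.

## Known limitations

* The bundled mutant table transcribes printed junction observations; the
  transgene reference sequence itself is not distributed, so bundled-data
  analyses run from the notation (coordinates + junction annotation) rather
  than re-deriving microhomology from raw sequence. The two paths are
  proven equivalent on synthetic data, where both are available.
* Within-group per-animal MFs behind the bundled group means were not
  published; statistics requiring them (the Tukey p-values of the original
  comparisons) are validated on synthetic data at the published
  means/SDs instead.
* Complex rearrangements pass through as annotations; no multi-segment or
  inversion calling is attempted.
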