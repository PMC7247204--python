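# spidel

Deletion-junction microhomology analysis and mutation-spectrum statistics
for Spi⁻ selection data from transgenic rodent gene mutation assays.

## The problem

In *gpt* delta mice, ~80 tandem copies of a lambda-phage reporter (lambda
EG10, carrying the *red*/*gam* genes) are integrated into the genome.
Spi⁻ selection rescues the transgene as phage and recovers mutants in which
both *red* and *gam* are inactivated — predominantly deletions, from −1
frameshifts up to ~10 kb. Sequencing each mutant's breakpoint junction
reveals how the deletion arose: 1-bp deletions inside mononucleotide runs
are the signature of replication slippage, while larger deletions with short
junction microhomologies or small junction insertions are the signature of
non-homologous end joining (NHEJ) of double-strand breaks, e.g. after
ionizing radiation. Comparing spectra between wild-type and NHEJ-deficient
(*scid*, DNA-PKcs-mutant) animals, organs, and doses asks which repair
pathway produced the damage.

`spidel` implements the full analysis behind such a study:

* **Junction calling** — given a reference and deletion endpoints (or a raw
  mutant sequence), compute the canonical left-aligned placement, the number
  of equivalent placements, and the junction microhomology.
  Microhomology is defined by *placement equivalence*: a deletion flanked by
  a k-bp repeat can be placed in k+1 distinct ways that all yield the same
  mutant sequence, so `mh_len = placements − 1`. This is exactly what the
  field's breakpoint notation encodes: `182–184 → 187–189` (last retained →
  first retained, span 3) is a 4-bp deletion with a 2-bp microhomology.
* **Notation parsing** — the printed position/junction notation
  (`A–B → C–D`, context changes like `ttAtt→tttt`, `(k bp ins.)` suffixes,
  thousands separators) round-trips losslessly; deletion size is
  `first_retained − last_retained − 1`.
* **Spectrum classification** — every mutant goes to exactly one of seven
  classes: 1-bp deletion in run / other, ≥2-bp deletion with / without
  microhomology / with junction insertion, pure insertion, complex.
* **Frequency statistics** — per-animal mutant frequencies
  (MF = confirmed mutants / rescued pfu), group mean ± SD, class-specific
  MFs (total MF × class ratio), dose-response fold changes, and all-pairs
  Tukey HSD comparisons (Tukey–Kramer for unequal group sizes).
* **Synthetic data** — a generator that plants homopolymer runs in a random
  reference, draws slippage / DSB-deletion / insertion events with
  microhomology-biased breakpoints, and emits per-animal Poisson mutant
  counts, providing exact ground truth for every stage.

## Worked example

The package bundles the sequenced Spi⁻ deletion junctions recovered from
mouse brain in a published wild-type vs *scid* X-irradiation experiment
(four groups: WT/scid × 0/10 Gy), plus the group mean MFs.

```python
from spidel import load_brain_mutants, load_brain_group_mf
from spidel.spectrum import classify_record, group_records, junction_statistics, summarize_group
from spidel.stats import specific_mf

groups = group_records(classify_record(r) for r in load_brain_mutants())
wt10 = groups[("WT", 10.0, "brain")]

s = summarize_group(wt10)
print({c.name: n for c, n in s.counts.items()})
# {'DEL1_RUN': 30, 'DEL1_OTHER': 6, 'DELGT2_MH': 21, 'DELGT2_NOMH': 12,
#  'DELGT2_INS': 2, 'INSERTION': 0, 'COMPLEX': 1}

js = junction_statistics(wt10)
print(f"{js.mh_count}/{js.gt2bp_total} = {100*js.mh_fraction:.0f}% with microhomology, "
      f"mean {js.mean_mh_len:.1f} bp; {100*js.large_fraction:.0f}% over 1 kb")
# 21/35 = 60% with microhomology, mean 1.8 bp; 37% over 1 kb

mf = load_brain_group_mf()["mean_mf_e6"]          # 5.00e-6 for WT 10 Gy
print(f"{specific_mf(mf[('WT', 10)], 21, s.total):.2f}")
# 1.46   (specific MF of microhomology-bearing deletions, x1e-6)
```

Of the 72 deletion mutations in irradiated wild-type brain, 60% of the
≥2-bp deletions carry 1–4 bp of junction microhomology (mean 1.8 bp) — the
NHEJ signature — and their specific MF rises 20.3-fold with dose, versus
3.0-fold for slippage-type 1-bp deletions.

The same analysis runs from the shell on any reference/mutant/assay tables:

```bash
spidel all --seed 42 --out demo/            # simulate, then analyze
spidel report --mutants mutants.tsv --assays assays.tsv \
    --reference ref.fasta --out report/ --emit-vcf
```

`report/` contains per-mutant calls, the spectrum table with specific MFs,
junction statistics, MF summaries with Tukey comparisons, and fold changes,
each at full precision alongside conventionally rounded values.

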