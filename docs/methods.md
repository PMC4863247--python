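# Methods

This note documents the statistical procedures, the synthetic-data
generator, and the design decisions behind `crossomics`.

## Quantification model

Input is protein-level label-free quantification: one table per
subcellular fraction, with a peak area and a unique-peptide count per
protein per run, two groups (T24, T24M cell lines) of five replicates.
The package deliberately starts *after* spectral processing: peptide
identification, protein inference and top-peptide area aggregation are
the job of the acquisition software, and their outputs are the contract.

Processing order is: contaminant exclusion → ppm normalization →
detection filtering → missing-value handling.  Normalization divides
each sample's areas by that sample's total area (summed over all
non-contaminant quantified proteins, i.e. before detection filtering)
and scales by 10⁶, so each sample's ppm column sums to 10⁶ exactly (to
relative tolerance 1e-9).  Normalizing before filtering keeps the
denominator a property of the sample rather than of the filter settings;
contaminants are excluded first so that abundant exogenous proteins
(e.g. serum carry-over in conditioned medium) do not distort the scale.

**Detection and exclusivity.** Detected = ≥ `min_unique_peptides`
(default 2) unique peptides in that individual run.  Retained = detected
in ≥ `min_replicates` (default 3) runs of *at least one* group.  The
one-group reading is deliberate: requiring both groups would make
proteins fully absent from one cell line — the biologically loudest
changes — unreportable, yet such "only in one line" proteins are exactly
what an exclusivity call is for.  Exclusivity additionally requires zero
detections in the other group, which keeps `only_T24M` / `only_T24`
disjoint from ordinary fold changes.

**Missing values.** Undetected cells are set to ppm 0 (absence of
identification is evidence of absence at the detection limit, not
missing-at-random).  Cells flagged as identified-but-unquantified (a
quantification-software failure mode) receive the mean ppm of the same
protein over the non-flagged samples of the same group, computed after
zero replacement — the fixed order makes the imputation deterministic.
A flagged cell whose entire group is flagged is an error rather than a
guess.

## Differential expression

Fold change is the ratio of group means of imputed ppm (T24M over T24).
Means, not medians, keep the summary consistent with the mean-based
imputation rule.  Exclusive proteins carry their sentinel instead of a
number but are still *tested* on the zero-imputed vectors — an
exclusivity call with an unconvincing p (e.g. 2-of-5 vs 0-of-5 detections
would not be retained anyway) should not get a free pass.

The Mann–Whitney p-value is exact for pooled n ≤ 16: all C(n, n_x)
group-label arrangements of the pooled values are enumerated, the
U statistic (ties scored ½) is computed for each, and the two-sided p is
twice the smaller one-sided tail containing the observed value, capped
at 1.  This doubling convention matches classical statistical packages
and makes the achievable 5v5 levels the familiar 2k/252 grid (0.0079,
0.0159, …, 0.0556).  Ties are handled exactly by enumerating over the
actual tied values — important here because zero-imputation creates
heavy ties.  Above n = 16 the normal approximation with tie-corrected
variance and a 0.5 continuity correction is used.  Internally the
enumeration is vectorized over all proteins at once (an einsum over the
252 arrangement masks), so a full fraction tests in milliseconds.

Calls: direction up at FC ≥ 1.5 (down at ≤ 1/1.5) or exclusive;
significance p < 0.05 by default.  A `less_equal` p-rule is provided for
re-scoring tables whose p-values are printed at two decimals (an exact
0.0556 prints as 0.05).  BH adjustment (via statsmodels) is computed per
fraction, not pooled — fraction datasets have different variability and
pooling would let a quiet fraction subsidize a noisy one.  FDR-gated
calling is available but off by default: with n = 5 per group the exact
test's floor (0.0079) is high relative to BH at hundreds of tests, and
the cross-strategy agreement step is the intended false-positive
control.

## Integration

Features are matched across strategies by upper-cased gene symbol
(proteomics-only comparisons use accessions); accessions missing from
the id map keep a synthesized symbol and are logged.  Same-symbol
collisions within a strategy merge when their directions do not
conflict; a conflict flags the feature and contributes no direction.

The transcript slot uses CPM-normalized count means and the same FC ≥
1.5 rule, with *no* p-value: two replicates per line cannot support a
per-gene test, so the transcriptome contributes trend information only.
Externally normalized abundance tables bypass the CPM step.

Verified = ≥ 2 of the 4 strategy slots agree in direction and no slot
opposes.  Any opposing pair disqualifies regardless of support count;
such features are reported separately as conflicting.  Tiers: `all4`
(four agreeing slots) and `two_or_three`.  The proteomics-only
cross-validated set uses the same rule over the three fraction slots.

*Suggestive support* lists, for each called feature, the other fractions
whose raw fold change trends the same way but misses the thresholds.
"Trends" uses an indifference band around 1 (default 1.25-fold): a ratio
of 0.9 is noise, not a downward trend.  The band is a reporting
convention, not a statistical claim, and is configurable.

## Literature scoring and over-representation

Overlap percentages are exact rationals rounded half-up to one decimal
at reporting only.  Over-representation uses the right hypergeometric
tail (scipy) against an explicit universe; the default universe is the
union of all quantified features, and it is a logged parameter because
commercial pathway tools ship undisclosed backgrounds that materially
change p-values.  Pathways are intersected with the universe before
testing; results sort by ascending p with ties broken by larger hit
count then name.  Significance uses raw p < 0.05 (matching common
pathway-tool practice at small query sizes); a BH column is emitted
alongside for transparency.  The rank-comparison report cross-tabulates
the primary ranking's top-k pathways against other rankings, marking
absences as "not predicted" and non-significant ranks with "(n.s.)".

## The synthetic-data generator

The generator emulates the study conditions the pipeline targets, with
known ground truth.

* **Membership.** Gene membership across fractions follows a fixed Venn
  structure: totals 1359/1062/816 (CE/ER-Golgi/CM), core 498,
  fraction-exclusive regions 408/166/219; the pairwise-only regions are
  derived (376/77/22) and infeasible structures are rejected.
* **Intensities.** Baseline log areas are Normal(16, 1.8²) per gene
  (arbitrary units); replicate noise is log-normal with σ = 0.25 (~25 %
  CV, typical of label-free protein-level areas).  A planted-DE gene
  (probability 0.20) carries one true direction shared by every fraction
  containing it, with |log2 FC| ~ U(1.2, 3); an exclusive gene
  (probability 0.02) is absent from one group entirely.
* **Dropout.** Per-run detection probability falls linearly with the
  within-fraction abundance rank, from 0.99 (most abundant) to 0.55;
  detected runs occasionally (3 %) yield a single peptide, which the
  ≥ 2-peptide rule discards.  This reproduces realistic replicate-overlap
  rates (~75 % of proteins pass 3-of-5) and exercises the filter.
* **Signal peptides.** Flags are assigned per Venn region: shared-region
  rates are fixed mild defaults and the three fraction-exclusive region
  rates are solved linearly so each fraction's expected prevalence hits
  its target (0.09/0.14/0.30) exactly in expectation despite the shared
  core; with the default structure the solved rates are ≈ 0.15 / 0.55 /
  0.93 for the CE-/ER-Golgi-/CM-only regions — a biologically sensible
  gradient (CM-only members are bona fide secreted proteins).  Flags are
  independent of abundance, so retention does not bias prevalence.
* **Transcriptome.** Negative-binomial counts (dispersion 0.02, baseline
  log-normal around ~300 counts), two replicates per line.  A planted-DE
  gene's transcript is concordant (same direction, |log2 FC| ~
  U(0.9, 2.5), i.e. ≥ 1.87-fold — safely above the 1.5 verification
  threshold under counting noise) with probability q (default 0.7),
  opposite with probability 0.05, otherwise sub-threshold (≤ 1.19-fold).
  A small fraction (0.5 %) of transcripts is missing.
* **Literature and pathways.** Two reference lists of exactly 627 and
  671 symbols with exactly 179 shared are drawn without replacement from
  the data genes plus 3000 decoy symbols, weighting true-DE genes 3:1
  over background; the GMT collection holds 40 random gene sets plus one
  planted set with 80 % true-DE members.

Everything is driven by one mandatory seed through a `SeedSequence`
hierarchy; identical configurations produce bit-identical workspaces.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: peptide-level effects (shared peptides,
protein-inference ambiguity), between-replicate batch structure,
intensity-dependent variance heteroscedasticity beyond the dropout
gradient, correlated co-regulation between genes, annotation errors in
the id map, and literature lists with citation-structure biases.
Recovery results (prevalence, concordance, the verified-set validity
gain) demonstrate the *machinery* is correct under the stated model, not
that real datasets will show the same effect sizes.

## Problem sizes and numerical choices

The default simulation (per-fraction totals 1359/1062/816, five
replicates) runs a full generate-plus-pipeline cycle in about two
seconds, so the Monte-Carlo suites (20-seed sign test, 1000-instance
exact-test oracle, ~2700-protein null calibration) use full-size data.
Structural tests use a scaled configuration (~630 genes) purely for
brevity of fixtures.

Ties in the exact test are compared on the doubled-U integer scale to
avoid floating-point tie-breaking; ppm sums are validated to 1e-9
relative tolerance; Fisher p-values are checked against exact rational
summation to 1e-10 relative tolerance.  Degenerate inputs fail loudly:
zero total area names the sample, a fully flagged group is an error, an
empty retained set cannot produce an enrichment report, and an empty
universe cannot anchor an over-representation test.

## Known limitations

* The exclusivity/retention rule follows the one-group reading (see
  above); data processed under a strict both-groups rule will retain
  fewer proteins and report no exclusive calls.
* Transcript verification ignores mRNA measurement uncertainty entirely
  (by design, given n = 2); a concordant-by-chance rate of roughly the
  band mass around the threshold is unavoidable.
* The de-duplication key for multi-fraction features is the gene symbol;
  genuinely distinct proteoforms mapping to one symbol are merged if
  their directions agree, flagged otherwise.
* With five-per-group designs the exact test cannot produce p below
  0.0079; power against small fold changes is intrinsically limited, and
  the FDR-adjusted mode is conservative.
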