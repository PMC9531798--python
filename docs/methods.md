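# Methods

## Scope and model

`kdrsurv` implements the analysis chain of a target-site pyrethroid
resistance (kdr) survey in *Aedes aegypti*: per-codon diploid genotyping of
the four voltage-gated sodium channel (VGSC) substitutions S989P, V1016G,
F1534C and D1763Y from Sanger amplicon consensus sequences; phasing of the
unphased four-locus genotype into an unordered haplotype pair constrained by
a reference panel; two-group contingency statistics on zygosity classes and
combined genotypes; Abbott-corrected probit dose–response with LC99; and
classification of resistance-associated genotypes with a
proportion-vs-LC99 correlation. Codon numbering follows the house fly VGSC
reference, the field convention.

## Genotype calling

Each codon is located in its amplicon by a configured 0-based offset
(optionally overridden by an exact flanking anchor k-mer). Loci are strictly
biallelic: the wild and mutant codons differ at exactly one nucleotide for
all four substitutions (TCC>CCC, GTA>GGA, TTC>TGC, GAC>TAC). A Sanger
consensus encodes a heterozygote as the IUPAC ambiguity code at the
discriminating position; calling expands the code to its nucleotide set and
intersects the codon's resolutions with {wild, mutant}. Ambiguity at any
position where wild and mutant agree, or a codon matching neither allele,
is an *uncallable* error rather than a call — the conservative analogue of
manual chromatogram confirmation, under which a third segregating allele
would be flagged, not genotyped. Sequences are normalised to uppercase;
reverse-complemented input is supported behind a flag, since orientation is
a file dialect, not a biological property.

## Phasing against a haplotype panel

A genotype with k heterozygous loci decomposes into exactly
2^(max(k,1)−1) unordered haplotype pairs (each heterozygous locus splits
its alleles between the two haplotypes; fixing the first heterozygous
locus removes the order double-count). The phasing rule is purely
combinatorial, in order of precedence:

1. **panel_unique** — exactly one candidate pair lies fully within the
   reference panel; it is assigned.
2. **forced_novel** — no candidate is fully in-panel but the decomposition
   is combinatorially unique (k ≤ 1); the unique pair is assigned and its
   out-of-panel members flagged as novel. A forced call is only ever made
   when no inference is involved.
3. **ambiguous** — two or more candidates are fully in-panel; nothing is
   assigned. Ambiguous specimens are excluded from combined-genotype
   statistics but retained in per-locus statistics, which are phase-free.
4. **unresolved** — otherwise (k ≥ 2 and no fully-in-panel candidate);
   reported in per-locus notation such as `SP/VG/FC/DY`. The package never
   guesses a phase from population frequencies; statistical phasing (EM,
   Clark parsimony) is an explicit non-goal.

The default panel is the six haplotypes reported to segregate in Taiwanese
*Ae. aegypti* — SVFD (wild), SVCD, PGFD, SGFY, SGFD, PVFD. The panel is
configuration data, not code: substituting a different panel changes phasing
outcomes, and the monotonicity property (enlarging the panel never turns a
unique assignment into unresolved) is tested. One genuine consequence of the
rule is worth noting: the double heterozygote S/P + V/G (with 1534 and 1763
wild) decomposes as (SVFD, PGFD) or (SGFD, PVFD), both fully in the default
panel, and is therefore *ambiguous* — surveys that report it as SVFD/PGFD
are implicitly using haplotype-frequency information the rule deliberately
refuses.

## Contingency statistics

Every non-reference category (het or mutant-hom zygosity class; non-wild
combined genotype) is compared against the wild-type reference between two
groups in a 2×2 table. The test is Pearson's chi-square (df = 1, no
continuity correction) when every expected cell count is ≥ 5, else a
one-sided Fisher exact test whose alternative is enrichment of the tested
category in the second group (the later round, or the survivors). This
selection rule reproduces, at four printed decimals, 17 of the 19
non-floor p-values in the published tables the package ships as its worked
example; the two exceptions (printed 0.1701 and 0.1496) are non-significant
under every candidate rule we tried (uncorrected and Yates chi-square, one-
and two-sided Fisher, mid-p) and do not affect any significance call.
The Fisher tail is computed from the hypergeometric survival function; the
test suite checks it against an independent exact-rational enumeration of
all tables with the observed margins. p-values are displayed to 4 decimals
("0.0000" meaning p < 0.00005) with full precision retained internally.
No multiple-testing correction is applied by default, matching surveillance
practice for these tables; Bonferroni/BH can be layered on by the caller.

Mutant allele frequency is (het + 2·hom) / 2N, reported to 2 decimals by
default. The unpaired equal-variance t-test compares per-district allele
frequencies between rounds — the district is the unit of replication, the
only level at which multiple observations per round exist.

## Bioassay and LC99

Observed mortality is corrected with Abbott's formula
(obs − ctrl)/(100 − ctrl)·100, clamped to [0, 100]; control mortality of
100% is undefined and ≥ 20% invalidates the assay (WHO-style threshold,
configurable). The dose–response is a binomial probit regression on log10
concentration fitted by IRLS (exact maximum likelihood), the Finney
convention for insecticide bioassays; a logit link would change LC99
slightly but the probit is the standard reported alongside LC values.
LC_p = 10^((Φ⁻¹(p) − α)/β). A fit requires ≥ 2 distinct concentrations and
non-degenerate corrected mortality; a non-positive slope is flagged invalid
rather than silently extrapolated.

A genotype is classified resistance-associated when its dead-vs-alive test
against the wild type has p < 0.05 *and* its survival rate exceeds the wild
type's, with a stricter p < 0.01 tier reported separately. The proportion
of resistance-associated genotypes per population unit is correlated with
that unit's LC99 by the Pearson product-moment coefficient (R² = r²).

## Synthetic data

Specimens are drawn by random union of haplotypes from a frequency vector
(Hardy–Weinberg at the haplotype level; the VGSC and sex-determination loci
are on different chromosomes, so no sex linkage). The default March-like
and October-like vectors are the haplotype counts implied by the worked
example's combined-genotype tables (296 and 340 chromosomes; the two
October specimens whose phase is unresolvable are excluded). Amplicon
templates are neutral random 400-nt sequences with the wild codons placed at
the configured offsets (both domain II codons on one amplicon, 81 nt apart,
in frame); heterozygotes are emitted with the IUPAC code at the
discriminating position. Identical seed and configuration give
byte-identical FASTA and outcome tables.

Bioassay simulation assigns specimens round-robin to a dose ladder
(default 0.01–0.2 % w/w, the cypermethrin label range, 25 per cage plus an
unexposed control at baseline mortality 0) and kills each with probability
Φ(α_g + β_g·log10 d) using three genotype tiers on slope β = 3:
susceptible (LC99 ≈ 0.0095, just below the lowest dose — mirroring the
> 99% kill expected of a susceptible laboratory strain), intermediate
(LC50 ≈ 0.06, mid-ladder) and resistant (LC50 ≈ 0.6, above the ladder).
The tiers mirror the survival classes of the worked example's bioassay
table: genotypes combining two mutant haplotypes (e.g. SVCD/PGFD,
SGFY/PGFD) and the 1534 homozygote are resistant; single-mutant-haplotype
heterozygotes are intermediate or susceptible.

What the generator does *not* emulate: sequencing noise and base-calling
error (every emitted codon is clean), linkage to untyped VGSC variants,
inbreeding or population structure, generation-to-generation dynamics, and
cage effects in the bioassay (fates are independent Bernoulli draws).
Passing round-trip tests therefore demonstrate the pipeline's correctness
on clean data, not robustness to dirty chromatograms — uncallable-locus
handling is tested separately with deliberately corrupted codons.

## Numerical and design choices

* **Probit recovery experiment.** The recovery benchmark simulates 200
  assays per slope configuration β ∈ {1, 2, 4} at 250 mosquitoes per dose
  and five doses, and checks the median relative LC99 error pooled over the
  600 assays is below 10%. Doses are placed at the 10/40/70/90/95%
  mortality quantiles of the generating curve: estimating a high quantile
  (LC99) calls for a design weighted toward high kill — the c-optimal
  design concentrates near 92% mortality. A Fisher-information calculation
  shows the β = 1 configuration *alone* cannot reach 10% at this sample
  size under any five-point design (the optimal design yields a median
  relative error ≈ 13%, since the error in log10 LC99 scales as 1/β), which
  is why the criterion is pooled; per-configuration medians are ≈ 17%, 8.5%
  and 4%.
* **Problem sizes.** Round-trip and end-to-end checks use 180 specimens per
  simulated round (comparable to the 148/172 of the worked example);
  exhaustive checks cover all 81 zygosity combinations and all 136
  unordered haplotype pairs, so nothing is sampled where enumeration is
  feasible.
* **Tie-breaks and ordering.** Combined-genotype labels order the two
  haplotypes alphabetically; per-locus notation puts the wild letter first;
  candidate lists are sorted — all outputs are byte-stable across runs.
* **Degenerate inputs.** Empty groups, zero marginals, all-dead/all-alive
  dose ladders, 100% control mortality and zero-variance correlations raise
  errors rather than returning NaNs; a genotype class absent from both
  groups is skipped with a notice.

## Known limitations

* The two-group contingency scheme treats specimens as independent; spatial
  clustering by district is ignored except in the t-test's unit choice.
* The test-selection rule was reverse-engineered from printed values; the
  original analysis software may differ on non-significant borderline
  tables (see the two unmatched p-values above).
* LC99 extrapolates the probit line far beyond the top dose for shallow
  slopes; its sampling error is correspondingly large (see the recovery
  analysis), and reported LC99s should always be read with the slope.
* The correlation step requires per-unit LC99 values and ≥ 3 units; with
  the bundled example counts alone (no per-district dose data) it can only
  be exercised on synthetic assays.
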