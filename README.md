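# kdrsurv

Four-locus VGSC (*kdr*) genotyping and insecticide-resistance surveillance
statistics for *Aedes aegypti*.

Pyrethroid spraying is the front-line intervention against dengue vectors,
and repeated use selects for knockdown resistance (*kdr*): amino-acid
substitutions in the voltage-gated sodium channel (VGSC) that weaken
pyrethroid binding. In Taiwanese *Ae. aegypti* four substitutions circulate
— S989P, V1016G, F1534C and D1763Y (house fly codon numbering) — arranged
on a small set of haplotypes, written as 4-letter codes over the loci
(989, 1016, 1534, 1763): SVFD is the wild type, PGFD carries S989P+V1016G,
and so on. `kdrsurv` is for vector-control and medical-entomology teams who
genotype field mosquitoes by direct Sanger sequencing and need the full
chain from consensus sequence to surveillance report:

1. **Genotype calling** — extract the diploid call at each codon from the
   amplicon consensus, reading IUPAC ambiguity codes (Y, K, ...) as
   heterozygotes;
2. **Panel-constrained phasing** — resolve the unphased four-locus genotype
   into an unordered haplotype pair. A genotype with k heterozygous loci
   has 2^(max(k,1)−1) possible pairs; a pair is assigned only when it is
   the unique candidate fully inside the reference panel, or when the
   decomposition is combinatorially forced (k ≤ 1). Everything else is
   reported ambiguous/unresolved — never guessed;
3. **Comparison statistics** — mutant allele frequencies
   ((het + 2·hom)/2N), and for each zygosity class or combined genotype a
   2×2 comparison against the wild type between groups (survey rounds, or
   dead vs alive after a bioassay): Pearson chi-square without continuity
   correction when all expected counts are ≥ 5, otherwise a one-sided
   Fisher exact test;
4. **Bioassay analysis** — Abbott correction
   ((obs − ctrl)/(100 − ctrl)·100), maximum-likelihood probit regression
   Φ⁻¹(p) = α + β·log₁₀(dose), LC99 = 10^((Φ⁻¹(0.99) − α)/β), and
   classification of resistance-associated genotypes (significant vs wild
   type *and* higher survival), correlated with LC99 across districts;
5. **Synthetic data** — seeded populations drawn by random union of
   haplotypes, emitted as IUPAC-coded FASTA plus genotype-specific probit
   bioassay outcomes, so the whole pipeline is testable without mosquitoes.

## Worked example

The package bundles the genotype counts of a published 2016 two-round field
survey of nine districts in southern Taiwan (320 field males genotyped in
March and October; 115 G1 females genotyped after a cypermethrin bioassay)
and recomputes its statistics:

```sh
kdrsurv reproduce-tables --outdir report/
```

`report/field_locus_tests.tsv` then contains, per locus and mutant
zygosity class, the between-round test — for example the 1534 heterozygote
row (F/C: 36 specimens in March, 59 in October, against F/F wild 103 vs 96)
is a chi-square with statistic 4.96 and `p = 0.0260`, while the rare 1763
homozygote (Y/Y: 0 vs 4) falls below the expected-count cutoff and gets the
one-sided Fisher test, `p = 0.0629`. `report/field_allele_freqs.tsv` holds
the mutant allele frequencies (March 0.09/0.16/0.18/0.03 vs October
0.29/0.40/0.27/0.11 at 989/1016/1534/1763 — every locus rising over the
spray season), and `report/bioassay_survival.tsv` the per-genotype survival
rates, from 0% (wild SVFD/SVFD, 45 dead / 0 alive) through 7.7%
(SVCD/SVFD) to 100% for the double-mutant-haplotype genotypes such as
PGFD/SVCD (0 dead / 14 alive).

The same machinery is available as a library:

```python
>>> from kdrsurv import run_test, phase, genotypes_from_csv
>>> run_test([[103, 96], [36, 59]]).p_display   # F/C vs F/F, March/October
'0.0260'
>>> g = genotypes_from_csv(open("genotypes.csv"))[0]   # S/P,G/G,F/F,D/D
>>> p = phase(g)
>>> p.status.value, p.label
('panel_unique', 'PGFD/SGFD')
```

A full synthetic round trip from sequences to report:

```sh
kdrsurv simulate --preset october --n 150 --seed 7 --outdir sim/
kdrsurv call sim/specimens.fasta --out sim/called.csv
kdrsurv phase sim/called.csv --out sim/phased.csv
kdrsurv bioassay sim/genotypes.csv --bioassay-csv sim/bioassay.csv --outdir sim/report/
```

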