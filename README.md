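# kaspqc

F₁ hybridity verification and marker QA/QC for diploid crops from
low-density KASP SNP genotype data.

## The problem

Breeding programs make bi-parental crosses and must confirm — before
advancing material — that each putative F₁ really is a hybrid of the two
stated parents rather than an accidental self or a seed mixture. Low-density
KASP SNP panels are the routine tool for this: in a diploid, an offspring
receives one allele from each parent, so at any SNP where the parents are
homozygous for *different* alleles (a polymorphic, "informative" marker) a
genuine hybrid must be heterozygous for exactly those two alleles. `kaspqc`
automates the manual spreadsheet curation this check otherwise requires:
it reads a whole genotyping run (many crosses in one file), finds each
cross's informative markers, scores every putative F₁, flags impure
(heterozygous) parents and non-parental alleles, and reports how useful
each marker in the panel was.

## The statistics

With `Tm` markers in the panel, for each parent pair let `Pm` be the number
of informative markers and `Mc` the relevant missing-call count. Per
offspring, `Lhet` counts informative loci at which it is the expected
heterozygote and `Lnpa` loci carrying an allele seen in neither parent:

* parental polymorphism = 100 · Pm / (Tm − Mc)  — pair level
* hybridity = 100 · Lhet / (Pm − Mc)            — per offspring
* parental heterozygosity = 100 · Phet / (Tm − Mc) — per parent
* non-parental alleles = 100 · Lnpa / Pm        — per offspring
* marker efficiency = 100 · fm / Tc             — per marker, where `fm`
  is the number of parental pairs the marker distinguishes out of `Tc`
  pairs in the file

Each offspring receives one status: `TRUE CROSS` (hybridity ≥ 50% by
default), `SELF`, or one of three undetermined verdicts
(`Undetermine: Parent Heterozygous`, `Undetermine: Parent not polymorphic`,
`Undetermine: missing data`), evaluated in that precedence order against
the four thresholds (parent heterozygosity ≤ 20%, polymorphism ≥ 20%,
missing data ≤ 20%, hybridity ≥ 50%; all configurable).

## Input format

A grid with header columns `Sample ID`, `Sample Name`, `Type` followed by
one column per SNP marker (XLSX, CSV or TSV). Cells hold diploid calls
(`A:G`, `T/T`, `AG`, or a single letter for a homozygote) or the missing
codes `?` / `Uncallable` / blank. Rows are positional: each cross appears
as its two parent rows (Type `Parent`) immediately followed by its
putative F₁ rows (Type `F1`); several crosses may be stacked in one file.

## Worked example

A cross of the cowpea variety IT97K-573-1-1 with the landrace Danila,
genotyped at three SNPs; offspring 1–3 are heterozygous at every locus,
offspring 4 matches parent 1:

```bash
kaspqc run --input cross.csv --out report.xlsx
```

prints

```
families: 1  offspring: 4  markers: 3
  TRUE CROSS: 3
  SELF: 1
wrote hybridity_png: report.hybridity.png
wrote efficiency_png: report.efficiency.png
wrote workbook: report.xlsx
wrote summary_tsv: report.summary.tsv
```

Three offspring are verified hybrids (hybridity 100% over 3 informative
loci) and the fourth is an accidental self (hybridity 0%). `report.xlsx`
holds the genotype grid with color classes (green = polymorphic parental
locus, red = monomorphic, blue = heterozygous parent, orange = offspring
heterozygous at an informative locus, purple = non-parental allele), the
eleven summary columns per sample, a pie chart of status proportions and a
bar chart of marker efficiency; `report.summary.tsv` is a plain-text mirror
of the summary table.

Synthetic fixtures with known ground truth (true class of every offspring,
intended informative markers per family):

```bash
kaspqc simulate --out fixture.csv --seed 7 --n-families 103 \
    --offspring 5-34 --n-markers 22
```

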