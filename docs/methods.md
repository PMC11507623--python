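# Methods

## Model and assumptions

`kaspqc` scores putative F₁ offspring of bi-parental crosses in diploid
species genotyped with co-dominant SNP markers (KASP-style biallelic
calls). The genetic model is Mendelian transmission at unlinked autosomal
loci: a true F₁ carries one allele from each parent at every locus, so at
a marker where the parents are distinct homozygotes the offspring must be
heterozygous for those two alleles. Everything downstream follows from
per-locus classification; no linkage, allele-frequency or pedigree-depth
modeling is attempted, and markers are treated as independent (linkage
equilibrium). Polyploid calls and sex-linked markers are out of scope.

## Locus classification

For each parent pair and marker:

| class | condition | consequence |
|---|---|---|
| POLYMORPHIC | both parents homozygous, different alleles | informative |
| MONOMORPHIC | both homozygous, same allele | uninformative |
| PARENT_HET | ≥1 parent call heterozygous | uninformative |
| MISSING | ≥1 parent call missing | excluded from the polymorphism denominator |

A locus with one heterozygous parent (e.g. A:A × A:G) is classed
PARENT_HET and excluded from the informative set: the expected offspring
genotype is ambiguous there, so it contributes evidence to parental
impurity, not to hybridity. PARENT_HET loci remain in the polymorphism
denominator (they were genotyped; they simply are not informative).

For each offspring, only the family's informative loci are scored:
HET_TRUE (exactly the two parental alleles), HOM_PARENTAL (parental
alleles but not the heterozygote — the self signature), NON_PARENTAL
(≥1 allele absent from both parents — outcrossing, seed mixture or a
genotyping error), or MISSING. Non-parental loci count in the hybridity
denominator but never toward `Lhet`; they are reported in their own
columns.

## Statistics

* Parental polymorphism = 100·Pm/(Tm−Mc), with Mc = loci where either
  parent call is missing.
* Parental heterozygosity is computed per parent as 100·Phet/(Tm−Mc_self)
  with that parent's own missing count; the pair-level gate uses the
  worse (max) of the two parents.
* Hybridity = 100·Lhet/(Pm−Mc), with Mc = the offspring's missing calls
  at informative loci only — only informative loci enter the denominator.
* Non-parental alleles = 100·Lnpa/Pm with no missing-call correction.
* Marker efficiency = 100·fm/Tc across the whole file; Tc counts every
  parental pair, including pairs missing or heterozygous at the marker
  (the marker had its chance to distinguish them and did not).
* The reported and thresholded %missing is panel-wide: the offspring's
  missing calls over all Tm markers. Ratios with a zero denominator are
  undefined and rendered `NA`.

## Status machine

Statuses are assigned in strict precedence: (1) either parent's
heterozygosity above `max_parent_het_pct` → `Undetermine: Parent
Heterozygous`; (2) polymorphism undefined or below `min_polymorphism_pct`
→ `Undetermine: Parent not polymorphic`; (3) %missing above
`max_missing_pct` or hybridity undefined → `Undetermine: missing data`;
(4) otherwise `TRUE CROSS` iff hybridity ≥ `min_hybridity_pct`, else
`SELF`. Whenever an undetermined status is returned, %hybridity is
reported as `NA` rather than a number.

Defaults (all percentages, all configurable, validated to [0,100]):
minimum polymorphism 20, maximum missing 20, minimum hybridity 50,
maximum parent heterozygosity 20. Boundary semantics: an offspring at
exactly 50% hybridity is kept as `TRUE CROSS` (the threshold is a
minimum); the undetermined gates trigger only on strict violation
(polymorphism < 20, missing > 20, parent het > 20). Percentages are kept
at full float precision internally and rounded to one decimal only in
the report.

## Input dialect decisions

Calls accept the spellings `X:Y`, `X/Y`, `XY` and single-letter
homozygote shorthand, case-insensitively; anything else (three alleles,
non-nucleotide letters) is rejected with row/column coordinates rather
than guessed. Missing codes are `?`, `Uncallable` and blank,
case-insensitively, configurable per dialect. Family grouping is purely
positional (each run of exactly two consecutive Parent rows opens a
family); a consequence is that a family with zero offspring cannot be
followed by another family in a written file, since the two parent runs
would merge — zero-offspring families are accepted in memory but the
writer's round-trip guarantee holds only for families with ≥1 offspring.
CSV/TSV are supported alongside XLSX with the identical header contract.

## Synthetic data generator

`kaspqc.synthetic` emulates a QC genotyping campaign: per family, each
marker is polymorphic with probability `polymorphism_prob` (parents fixed
for different alleles) or monomorphic; parent calls are then made
heterozygous at rate `parent_het_rate`; each offspring is a SELF
(duplicate of parent 1) with probability `selfing_rate`, else a
CONTAMINANT with probability `contamination_rate` (a hybrid given a
foreign allele at about half of the informative loci, at least one), else
a true HYBRID sampling one allele from each parent per locus; per-cell
missingness is applied last at `missing_rate`. Truth records (class per
offspring, intended informative set per family) describe the data before
missingness.

Defaults mirror a realistic cowpea QC campaign shape: 103 families,
22-SNP panel, 5–34 offspring per family. The rates — polymorphism 0.5,
selfing 0.2, missing 0.02, parent het 0.02, contamination 0.01 — are
chosen as typical of breeding QC data in which most markers of a curated
panel are informative for a random pair, a noticeable minority of crosses
fail, and call rates are high.

What the generator does *not* emulate: allele-frequency structure among
parents (alleles are uniform), linkage between markers, plate- or
marker-specific missingness, systematic genotyping error modes, or
related parents sharing alleles across families. Tests passing on this
generator therefore demonstrate correctness of the classification
arithmetic and decision logic under the stated model, not robustness to
every artifact of real assay data.

Randomness is a single seeded NumPy generator with per-family substreams
derived from `(seed, family_index)`, so enlarging a simulation never
reshuffles earlier families, and identical configurations produce
byte-identical files.

## Numerical and design notes

* The QC pipeline is fully deterministic; no randomness outside the
  simulator, no ties to break (counts are exact integers).
* Undefined ratios propagate as `None` internally and `NA` in reports;
  they are never silently coerced to 0.
* Parent rows in the report carry the pair polymorphism columns, their
  own heterozygosity and missing-call columns, and `NA` elsewhere;
  offspring rows repeat the pair polymorphism values and carry the full
  offspring statistics.
* Cell colors are semantic classes mapped to standard office-palette RGB
  fills (configurable): green #00B050 polymorphic, red #FF0000
  monomorphic, blue #00B0F0 heterozygous parent, orange #FFC000
  offspring heterozygote, purple #7030A0 non-parental.
* Problem sizes in the test suite: the enumeration-oracle cross-check
  runs on 1,000 random families of ≤8 markers and ≤5 offspring; selfing
  recovery uses 1,000 offspring per rate; the large-panel smoke run uses
  202 markers over 103 families × 47 offspring (≈4,800 F₁s), the largest
  panel-by-sample shape the tool is expected to see in routine use.

## Known limitations

* Hybridity logic assumes the informative set comes from homozygous
  parents; half-informative loci (one heterozygous parent) are excluded
  rather than partially scored.
* The positional family grammar cannot express interleaved crosses or
  explicit cross identifiers.
* VCF or other genotyping-platform formats are not ingested; convert to
  the grid dialect first.
* Genetic purity/identity/reference profiling beyond F₁ verification is
  out of scope.
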