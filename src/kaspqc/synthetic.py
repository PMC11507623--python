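"""Synthetic Intertek-dialect genotype tables with known ground truth.

The generator emulates the data a breeding program's QC lab produces:
multiple bi-parental crosses stacked in one grid, parents mostly
homozygous, offspring that are either genuine F1 hybrids, accidental
selfs of parent 1, or contaminants carrying non-parental alleles, with
uniform per-cell missingness applied last.  Because the true class of
every offspring and the intended polymorphic marker set of every family
are recorded before noise is applied, every downstream statistic can be
checked against truth.

Genetic model: markers are unlinked and biallelic per family.  For a
marker flagged polymorphic for a pair, the two parents are fixed for
different alleles; otherwise both carry the same allele.  A hybrid
offspring receives one allele from each parent at every locus; a self
duplicates parent 1's genotype; a contaminant is a hybrid that received
a foreign allele at a random half of the family's informative loci.

Defaults mirror a realistic cowpea QC campaign: 103 crosses genotyped
with a 22-SNP QA/QC panel and 5-34 putative F1s per cross.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype_io import (
    DEFAULT_DIALECT,
    CrossFamily,
    Dialect,
    GenotypeCall,
    GenotypeTable,
    MISSING_CALL,
    Role,
    SampleRecord,
    group_families,
    write_table,
)

__all__ = ["SimConfig", "TrueClass", "TruthRecord", "FamilyTruth",
           "simulate", "write_fixture"]

ALLELES = ("A", "C", "G", "T")


class TrueClass(enum.Enum):
    HYBRID = "HYBRID"
    SELF = "SELF"
    CONTAMINANT = "CONTAMINANT"


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    offspring_per_family may be a fixed count or an inclusive (lo, hi)
    range sampled per family.  selfing_rate and contamination_rate are
    per-offspring class probabilities (selfing takes precedence);
    missing_rate is per cell; parent_het_rate is per parent per locus.
    """

    n_families: int = 103
    offspring_per_family: int | tuple[int, int] = (5, 34)
    n_markers: int = 22
    polymorphism_prob: float = 0.5
    selfing_rate: float = 0.2
    missing_rate: float = 0.02
    parent_het_rate: float = 0.02
    contamination_rate: float = 0.01
    contaminated_locus_fraction: float = 0.5
    self_parent: int = 1  # which parent a self duplicates (1 or 2)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("polymorphism_prob", "selfing_rate", "missing_rate",
                     "parent_het_rate", "contamination_rate",
                     "contaminated_locus_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_families < 1 or self.n_markers < 1:
            raise ValueError("need at least one family and one marker")
        if self.self_parent not in (1, 2):
            raise ValueError("self_parent must be 1 or 2")
        lo, hi = self._offspring_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid offspring_per_family")

    @property
    def _offspring_range(self) -> tuple[int, int]:
        o = self.offspring_per_family
        return (o, o) if isinstance(o, int) else o


@dataclass
class TruthRecord:
    sample_id: str
    family_index: int
    true_class: TrueClass


@dataclass
class FamilyTruth:
    family_index: int
    polymorphic_markers: list[str]
    offspring: list[TruthRecord] = field(default_factory=list)


def _family_rng(seed: int, family_index: int) -> np.random.Generator:
    # Independent substream per family: adding families never reshuffles
    # the genotypes of earlier ones.
    return np.random.default_rng(np.random.SeedSequence([seed, family_index]))


def _hybrid_call(rng: np.random.Generator, p1: GenotypeCall,
                 p2: GenotypeCall) -> GenotypeCall:
    a = p1.alleles[int(rng.integers(2))]
    b = p2.alleles[int(rng.integers(2))]
    return GenotypeCall((a, b))


def simulate(config: SimConfig) -> tuple[GenotypeTable, list[FamilyTruth]]:
    """Generate a genotype table and the matching truth records.

    Deterministic for a given config (including seed).  Truth classes and
    intended polymorphic marker sets describe the genotypes *before*
    missingness is applied.
    """
    marker_ids = [f"snpQC{i + 1:05d}" for i in range(config.n_markers)]
    families: list[CrossFamily] = []
    truths: list[FamilyTruth] = []
    lo, hi = config._offspring_range

    for fi in range(1, config.n_families + 1):
        rng = _family_rng(config.seed, fi)
        n_off = int(rng.integers(lo, hi + 1))

        poly_mask = rng.random(config.n_markers) < config.polymorphism_prob
        p1_calls: dict[str, GenotypeCall] = {}
        p2_calls: dict[str, GenotypeCall] = {}
        locus_alleles: dict[str, tuple[str, str]] = {}
        for m, is_poly in zip(marker_ids, poly_mask):
            a, b = rng.choice(4, size=2, replace=False)
            a1, a2 = ALLELES[a], ALLELES[b]
            locus_alleles[m] = (a1, a2)
            p1_calls[m] = GenotypeCall((a1, a1))
            p2_calls[m] = GenotypeCall((a2, a2)) if is_poly \
                else GenotypeCall((a1, a1))
        # Impure-parent noise: replace a homozygous call with the het for
        # the locus allele pair.
        for calls in (p1_calls, p2_calls):
            het_mask = rng.random(config.n_markers) < config.parent_het_rate
            for m, is_het in zip(marker_ids, het_mask):
                if is_het:
                    calls[m] = GenotypeCall(tuple(sorted(locus_alleles[m])))

        informative = [m for m in marker_ids
                       if p1_calls[m].is_hom and p2_calls[m].is_hom
                       and p1_calls[m] != p2_calls[m]]
        truth = FamilyTruth(family_index=fi, polymorphic_markers=informative)

        parent1 = SampleRecord(f"P{fi:04d}-1", f"ParentA_{fi}", Role.PARENT,
                               p1_calls)
        parent2 = SampleRecord(f"P{fi:04d}-2", f"ParentB_{fi}", Role.PARENT,
                               p2_calls)
        offspring: list[SampleRecord] = []
        self_calls = p1_calls if config.self_parent == 1 else p2_calls
        for oi in range(1, n_off + 1):
            u = rng.random()
            if u < config.selfing_rate:
                cls = TrueClass.SELF
                calls = dict(self_calls)
            else:
                calls = {m: _hybrid_call(rng, p1_calls[m], p2_calls[m])
                         for m in marker_ids}
                if u < config.selfing_rate + config.contamination_rate \
                        and informative:
                    cls = TrueClass.CONTAMINANT
                    hit = [m for m in informative
                           if rng.random() < config.contaminated_locus_fraction]
                    if not hit:  # a contaminant must carry >=1 foreign allele
                        hit = [informative[int(rng.integers(len(informative)))]]
                    for m in hit:
                        parental = p1_calls[m].allele_set | p2_calls[m].allele_set
                        foreign = [x for x in ALLELES if x not in parental]
                        fa = foreign[int(rng.integers(len(foreign)))]
                        keep = calls[m].alleles[int(rng.integers(2))]
                        calls[m] = GenotypeCall(tuple(sorted((keep, fa))))
                else:
                    cls = TrueClass.HYBRID
            sid = f"F{fi:04d}-{oi:03d}"
            offspring.append(SampleRecord(sid, f"Cross_{fi}_F1_{oi}", Role.F1,
                                          calls))
            truth.offspring.append(TruthRecord(sid, fi, cls))

        # Missingness last, uniformly over every cell of the family block.
        if config.missing_rate > 0:
            for rec in (parent1, parent2, *offspring):
                drop = rng.random(config.n_markers) < config.missing_rate
                for m, d in zip(marker_ids, drop):
                    if d:
                        rec.calls[m] = MISSING_CALL
        families.append(CrossFamily(parent1, parent2, offspring, fi))
        truths.append(truth)

    # group_families on the flattened rows re-derives the same structure;
    # building directly keeps the invariant by construction.
    table = GenotypeTable(marker_ids=marker_ids, families=families)
    return table, truths


def write_fixture(config: SimConfig, out_path: str | Path,
                  dialect: Dialect = DEFAULT_DIALECT,
                  fmt: str | None = None) -> tuple[Path, Path]:
    """Simulate and write the genotype file plus a truth TSV next to it.

    Returns (genotype path, truth path).  The truth TSV has columns
    sample_id, family_index, true_class; family-level intended polymorphic
    markers are appended as FAMILY rows.
    """
    out_path = Path(out_path)
    table, truths = simulate(config)
    write_table(table, out_path, dialect=dialect, fmt=fmt)
    truth_path = out_path.with_suffix(".truth.tsv")
    lines = ["sample_id\tfamily_index\ttrue_class"]
    for fam in truths:
        for rec in fam.offspring:
            lines.append(f"{rec.sample_id}\t{rec.family_index}\t"
                         f"{rec.true_class.value}")
    for fam in truths:
        lines.append(f"FAMILY\t{fam.family_index}\t"
                     f"{','.join(fam.polymorphic_markers)}")
    truth_path.write_text("\n".join(lines) + "\n")
    return out_path, truth_path
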