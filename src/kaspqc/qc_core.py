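"""Core QC statistics and the hybridity status machine.

The science in brief: in a diploid cross, a true F1 receives one allele
from each parent, so at any SNP where the two parents are homozygous for
*different* alleles (a polymorphic, "informative" marker) a genuine hybrid
must be heterozygous for exactly those two alleles.  An offspring that is
homozygous at the informative loci is an accidental self; an allele seen
in neither parent points to outcrossing, seed mixture or a genotyping
error.  Parents that are themselves heterozygous at many loci are impure
and make hybridity undecidable.

Five per-family / per-sample statistics drive the report:

* parental polymorphism  = 100 * Pm / (Tm - Mc)      (pair level)
* hybridity              = 100 * Lhet / (Pm - Mc)    (per offspring)
* parental heterozygosity = 100 * Phet / (Tm - Mc)   (per parent)
* non-parental alleles   = 100 * Lnpa / Pm           (per offspring)
* marker efficiency      = 100 * fm / Tc             (per marker)

where Tm is the marker panel size, Pm the number of informative markers
for the pair, Mc the relevant missing-call count, Lhet the informative
loci at which the offspring is the expected heterozygote, Lnpa the loci
carrying non-parental alleles, fm the number of parental pairs a marker
distinguishes and Tc the total number of pairs in the file.

Everything here is a pure, deterministic function of the input table and
the thresholds; no randomness anywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .genotype_io import CrossFamily, GenotypeCall, GenotypeTable

__all__ = [
    "Thresholds",
    "LocusClass",
    "OffspringLocusClass",
    "ParentStats",
    "ParentPairProfile",
    "OffspringQC",
    "MarkerEfficiency",
    "QCRunResult",
    "FamilyResult",
    "classify_parent_locus",
    "classify_offspring_locus",
    "parental_polymorphism_pct",
    "parental_heterozygosity_pct",
    "hybridity_pct",
    "non_parental_pct",
    "assign_status",
    "profile_parent_pair",
    "score_offspring",
    "marker_efficiency",
    "run_qc",
    "STATUS_TRUE_CROSS",
    "STATUS_SELF",
    "STATUS_UNDET_MISSING",
    "STATUS_UNDET_POLY",
    "STATUS_UNDET_HET",
    "ALL_STATUSES",
]

# Status strings emitted in the report, verbatim.
STATUS_TRUE_CROSS = "TRUE CROSS"
STATUS_SELF = "SELF"
STATUS_UNDET_MISSING = "Undetermine: missing data"
STATUS_UNDET_POLY = "Undetermine: Parent not polymorphic"
STATUS_UNDET_HET = "Undetermine: Parent Heterozygous"
ALL_STATUSES = (STATUS_TRUE_CROSS, STATUS_SELF, STATUS_UNDET_MISSING,
                STATUS_UNDET_POLY, STATUS_UNDET_HET)


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds, all percentages in [0, 100].

    Defaults: hybridity is assessed only when parental polymorphism is
    at least 20% and offspring missing data at most 20%; an offspring is
    a true cross when hybridity is at least 50%; a parent pair with more
    than 20% heterozygous loci in either parent is considered impure.
    """

    min_polymorphism_pct: float = 20.0
    max_missing_pct: float = 20.0
    min_hybridity_pct: float = 50.0
    max_parent_het_pct: float = 20.0

    def __post_init__(self) -> None:
        for name in ("min_polymorphism_pct", "max_missing_pct",
                     "min_hybridity_pct", "max_parent_het_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")


class LocusClass(enum.Enum):
    """Per-marker classification of a parent pair."""

    POLYMORPHIC = "POLYMORPHIC"    # distinct homozygotes: informative
    MONOMORPHIC = "MONOMORPHIC"    # identical homozygotes: uninformative
    PARENT_HET = "PARENT_HET"      # >=1 parent heterozygous: uninformative
    MISSING = "MISSING"            # >=1 parent call missing


class OffspringLocusClass(enum.Enum):
    """Per-informative-marker classification of an offspring call."""

    HET_TRUE = "HET_TRUE"          # exactly {parent1 allele, parent2 allele}
    HOM_PARENTAL = "HOM_PARENTAL"  # parental alleles only, but not the het
    NON_PARENTAL = "NON_PARENTAL"  # carries an allele seen in neither parent
    MISSING = "MISSING"


def classify_parent_locus(p1: GenotypeCall, p2: GenotypeCall) -> LocusClass:
    """Classify one marker for a parent pair (total function)."""
    if p1.missing or p2.missing:
        return LocusClass.MISSING
    if p1.is_het or p2.is_het:
        return LocusClass.PARENT_HET
    if p1.alleles != p2.alleles:
        return LocusClass.POLYMORPHIC
    return LocusClass.MONOMORPHIC


def classify_offspring_locus(p1: GenotypeCall, p2: GenotypeCall,
                             f1: GenotypeCall) -> OffspringLocusClass:
    """Classify an offspring call at an informative locus.

    Must only be called where :func:`classify_parent_locus` returned
    POLYMORPHIC; raises ``ValueError`` otherwise.
    """
    if classify_parent_locus(p1, p2) is not LocusClass.POLYMORPHIC:
        raise ValueError("offspring classification requires a polymorphic "
                         "(informative) parental locus")
    if f1.missing:
        return OffspringLocusClass.MISSING
    parental = p1.allele_set | p2.allele_set  # two distinct alleles
    if not f1.allele_set <= parental:
        return OffspringLocusClass.NON_PARENTAL
    if f1.allele_set == parental:
        return OffspringLocusClass.HET_TRUE
    return OffspringLocusClass.HOM_PARENTAL


def _ratio_pct(numer: int, denom: int) -> float | None:
    return None if denom == 0 else 100.0 * numer / denom


def parental_polymorphism_pct(pm: int, tm: int, mc: int) -> float | None:
    """Percent informative markers for a pair: 100*Pm/(Tm-Mc); None if the
    denominator is zero (all parental calls missing)."""
    if not (0 <= mc <= tm and 0 <= pm <= tm - mc):
        raise ValueError(f"inconsistent counts Pm={pm}, Tm={tm}, Mc={mc}")
    return _ratio_pct(pm, tm - mc)


def parental_heterozygosity_pct(phet: int, tm: int, mc: int) -> float | None:
    """Percent heterozygous loci for one parent: 100*Phet/(Tm-Mc)."""
    if not (0 <= mc <= tm and 0 <= phet <= tm - mc):
        raise ValueError(f"inconsistent counts Phet={phet}, Tm={tm}, Mc={mc}")
    return _ratio_pct(phet, tm - mc)


def hybridity_pct(lhet: int, pm: int, mc: int) -> float | None:
    """Percent informative loci scoring the offspring heterozygous:
    100*Lhet/(Pm-Mc), with Mc the offspring's missing calls at informative
    loci; None when no informative locus was called."""
    if not (0 <= mc <= pm and 0 <= lhet <= pm - mc):
        raise ValueError(f"inconsistent counts Lhet={lhet}, Pm={pm}, Mc={mc}")
    return _ratio_pct(lhet, pm - mc)


def non_parental_pct(lnpa: int, pm: int) -> float | None:
    """Percent informative loci carrying non-parental alleles: 100*Lnpa/Pm.
    No missing-call correction is applied to this quantity."""
    if not 0 <= lnpa <= max(pm, 0):
        raise ValueError(f"inconsistent counts Lnpa={lnpa}, Pm={pm}")
    return _ratio_pct(lnpa, pm)


@dataclass
class ParentStats:
    """One parent's heterozygosity profile."""

    phet: int
    mc_self: int
    het_pct: float | None


@dataclass
class ParentPairProfile:
    """Per-marker classification and pair-level statistics for one cross."""

    locus_classes: dict[str, LocusClass]
    pm: int
    tm: int
    mc_parents: int
    polymorphism_pct: float | None
    parent1: ParentStats
    parent2: ParentStats

    @property
    def informative_markers(self) -> list[str]:
        return [m for m, c in self.locus_classes.items()
                if c is LocusClass.POLYMORPHIC]

    @property
    def max_parent_het_pct(self) -> float | None:
        vals = [s.het_pct for s in (self.parent1, self.parent2)
                if s.het_pct is not None]
        return max(vals) if vals else None


@dataclass
class OffspringQC:
    """Per-offspring QC: locus classes at informative markers + statistics."""

    locus_classes: dict[str, OffspringLocusClass]
    lhet: int
    lnpa: int
    mc_f1_inf: int     # missing calls at informative loci
    mc_f1_all: int     # missing calls across the whole panel
    hybridity: float | None
    non_parental: float | None
    missing_pct: float | None
    status: str = ""


@dataclass(frozen=True)
class MarkerEfficiency:
    """How often one marker distinguishes the parental pairs in a file."""

    marker_id: str
    fm: int
    tc: int
    efficiency_pct: float | None


def profile_parent_pair(family: CrossFamily,
                        marker_ids: list[str]) -> ParentPairProfile:
    """Classify every marker for the family's parent pair and compute the
    pair-level polymorphism and per-parent heterozygosity statistics."""
    p1, p2 = family.parent1, family.parent2
    classes = {m: classify_parent_locus(p1.calls[m], p2.calls[m])
               for m in marker_ids}
    tm = len(marker_ids)
    pm = sum(c is LocusClass.POLYMORPHIC for c in classes.values())
    mc = sum(c is LocusClass.MISSING for c in classes.values())

    def parent_stats(rec) -> ParentStats:
        phet = sum(rec.calls[m].is_het for m in marker_ids)
        mc_self = sum(rec.calls[m].missing for m in marker_ids)
        return ParentStats(phet, mc_self,
                           parental_heterozygosity_pct(phet, tm, mc_self))

    return ParentPairProfile(
        locus_classes=classes,
        pm=pm,
        tm=tm,
        mc_parents=mc,
        polymorphism_pct=parental_polymorphism_pct(pm, tm, mc),
        parent1=parent_stats(p1),
        parent2=parent_stats(p2),
    )


def score_offspring(family: CrossFamily, profile: ParentPairProfile,
                    offspring_index: int, marker_ids: list[str]) -> OffspringQC:
    """Score one putative F1 against its family's informative markers."""
    rec = family.offspring[offspring_index]
    p1, p2 = family.parent1, family.parent2
    classes: dict[str, OffspringLocusClass] = {}
    for m in profile.informative_markers:
        classes[m] = classify_offspring_locus(p1.calls[m], p2.calls[m],
                                              rec.calls[m])
    lhet = sum(c is OffspringLocusClass.HET_TRUE for c in classes.values())
    lnpa = sum(c is OffspringLocusClass.NON_PARENTAL for c in classes.values())
    mc_inf = sum(c is OffspringLocusClass.MISSING for c in classes.values())
    mc_all = sum(rec.calls[m].missing for m in marker_ids)
    return OffspringQC(
        locus_classes=classes,
        lhet=lhet,
        lnpa=lnpa,
        mc_f1_inf=mc_inf,
        mc_f1_all=mc_all,
        hybridity=hybridity_pct(lhet, profile.pm, mc_inf),
        non_parental=non_parental_pct(lnpa, profile.pm),
        missing_pct=_ratio_pct(mc_all, profile.tm),
    )


def assign_status(pair: ParentPairProfile, off: OffspringQC,
                  thr: Thresholds) -> str:
    """Resolve one offspring's status string, in strict precedence order:
    impure parents, then insufficient polymorphism, then excessive missing
    data, then the hybridity verdict."""
    het = pair.max_parent_het_pct
    if het is not None and het > thr.max_parent_het_pct:
        return STATUS_UNDET_HET
    poly = pair.polymorphism_pct
    if poly is None or poly < thr.min_polymorphism_pct:
        return STATUS_UNDET_POLY
    if (off.missing_pct is not None and off.missing_pct > thr.max_missing_pct) \
            or off.hybridity is None:
        return STATUS_UNDET_MISSING
    if off.hybridity >= thr.min_hybridity_pct:
        return STATUS_TRUE_CROSS
    return STATUS_SELF


def marker_efficiency(profiles: list[ParentPairProfile],
                      marker_id: str) -> MarkerEfficiency:
    """Fraction of parental pairs a marker distinguishes.  Pairs whose call
    at the marker is missing or heterozygous still count in the total."""
    if not profiles:
        raise ValueError("marker efficiency requires at least one family")
    fm = sum(p.locus_classes[marker_id] is LocusClass.POLYMORPHIC
             for p in profiles)
    tc = len(profiles)
    return MarkerEfficiency(marker_id, fm, tc, _ratio_pct(fm, tc))


@dataclass
class FamilyResult:
    """QC output for one cross family."""

    family: CrossFamily
    profile: ParentPairProfile
    offspring: list[OffspringQC] = field(default_factory=list)


@dataclass
class QCRunResult:
    """Full QC output for a genotype table."""

    table: GenotypeTable
    thresholds: Thresholds
    families: list[FamilyResult]
    marker_efficiencies: dict[str, MarkerEfficiency]

    def status_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in ALL_STATUSES}
        for fam in self.families:
            for off in fam.offspring:
                counts[off.status] += 1
        return counts


def run_qc(table: GenotypeTable,
           thr: Thresholds | None = None) -> QCRunResult:
    """Run the whole QC pipeline on a parsed genotype table.

    Deterministic: classifies every parental locus, scores each offspring
    against its family's informative markers, assigns exactly one status
    per offspring and computes panel-wide marker efficiency.
    """
    thr = thr or Thresholds()
    results: list[FamilyResult] = []
    for fam in table.families:
        profile = profile_parent_pair(fam, table.marker_ids)
        fr = FamilyResult(family=fam, profile=profile)
        for i in range(len(fam.offspring)):
            off = score_offspring(fam, profile, i, table.marker_ids)
            off.status = assign_status(profile, off, thr)
            fr.offspring.append(off)
        results.append(fr)
    profiles = [fr.profile for fr in results]
    eff = {m: marker_efficiency(profiles, m) for m in table.marker_ids}
    return QCRunResult(table=table, thresholds=thr, families=results,
                       marker_efficiencies=eff)
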