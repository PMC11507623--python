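"""Locus classification, the five QC statistics and the status machine."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kaspqc.genotype_io import (
    CrossFamily,
    GenotypeCall,
    GenotypeTable,
    MISSING_CALL,
    Role,
    SampleRecord,
)
from kaspqc.qc_core import (
    LocusClass,
    OffspringLocusClass,
    STATUS_SELF,
    STATUS_TRUE_CROSS,
    STATUS_UNDET_HET,
    STATUS_UNDET_MISSING,
    STATUS_UNDET_POLY,
    Thresholds,
    classify_offspring_locus,
    classify_parent_locus,
    hybridity_pct,
    marker_efficiency,
    non_parental_pct,
    parental_heterozygosity_pct,
    parental_polymorphism_pct,
    run_qc,
)

from conftest import random_family, random_table
from _oracle import oracle_family, oracle_marker_efficiency

AA = GenotypeCall(("A", "A"))
GG = GenotypeCall(("G", "G"))
TT = GenotypeCall(("T", "T"))
AG = GenotypeCall(("A", "G"))
AT = GenotypeCall(("A", "T"))


class TestClassifyParentLocus:
    @pytest.mark.parametrize("p1, p2, expected", [
        (AA, GG, LocusClass.POLYMORPHIC),       # distinct homozygotes
        (AA, AA, LocusClass.MONOMORPHIC),       # identical homozygotes
        (AG, TT, LocusClass.PARENT_HET),        # one parent heterozygous
        (AG, AG, LocusClass.PARENT_HET),
        (MISSING_CALL, GG, LocusClass.MISSING),
        (AA, MISSING_CALL, LocusClass.MISSING),
        (MISSING_CALL, MISSING_CALL, LocusClass.MISSING),
    ])
    def test_classification(self, p1, p2, expected):
        assert classify_parent_locus(p1, p2) is expected

    def test_symmetric_in_parents(self):
        for p1, p2 in [(AA, GG), (AG, TT), (MISSING_CALL, AA)]:
            assert classify_parent_locus(p1, p2) is classify_parent_locus(p2, p1)


class TestClassifyOffspringLocus:
    @pytest.mark.parametrize("f1, expected", [
        (AG, OffspringLocusClass.HET_TRUE),        # one allele from each parent
        (AA, OffspringLocusClass.HOM_PARENTAL),    # matches parent 1 (a self)
        (GG, OffspringLocusClass.HOM_PARENTAL),
        (AT, OffspringLocusClass.NON_PARENTAL),    # T in neither parent
        (GenotypeCall(("T", "T")), OffspringLocusClass.NON_PARENTAL),
        (MISSING_CALL, OffspringLocusClass.MISSING),
    ])
    def test_classification_at_informative_locus(self, f1, expected):
        assert classify_offspring_locus(AA, GG, f1) is expected

    def test_requires_polymorphic_parents(self):
        with pytest.raises(ValueError):
            classify_offspring_locus(AA, AA, AG)
        with pytest.raises(ValueError):
            classify_offspring_locus(AG, TT, AG)


class TestStatisticFormulas:
    @pytest.mark.parametrize("pm, tm, mc, expected", [
        (11, 22, 0, 50.0),
        (5, 22, 2, 25.0),
        (0, 22, 22, None),   # all parental calls missing
    ])
    def test_parental_polymorphism(self, pm, tm, mc, expected):
        assert parental_polymorphism_pct(pm, tm, mc) == expected

    @pytest.mark.parametrize("phet, tm, mc, expected", [
        (0, 22, 0, 0.0),
        (11, 22, 0, 50.0),
        (2, 22, 2, 10.0),
    ])
    def test_parental_heterozygosity(self, phet, tm, mc, expected):
        assert parental_heterozygosity_pct(phet, tm, mc) == expected

    @pytest.mark.parametrize("lhet, pm, mc, expected", [
        (10, 10, 0, 100.0),
        (3, 8, 2, 50.0),
        (0, 4, 4, None),     # every informative call missing
    ])
    def test_hybridity(self, lhet, pm, mc, expected):
        assert hybridity_pct(lhet, pm, mc) == expected

    @pytest.mark.parametrize("lnpa, pm, expected", [
        (0, 10, 0.0),
        (2, 10, 20.0),
        (0, 0, None),        # no informative markers at all
    ])
    def test_non_parental(self, lnpa, pm, expected):
        assert non_parental_pct(lnpa, pm) == expected

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            parental_polymorphism_pct(5, 4, 0)
        with pytest.raises(ValueError):
            hybridity_pct(3, 4, 2)


def _family(p1_calls, p2_calls, offspring_calls, markers):
    p1 = SampleRecord("P1", "P1", Role.PARENT, dict(zip(markers, p1_calls)))
    p2 = SampleRecord("P2", "P2", Role.PARENT, dict(zip(markers, p2_calls)))
    offs = [SampleRecord(f"F{i}", f"F{i}", Role.F1, dict(zip(markers, calls)))
            for i, calls in enumerate(offspring_calls)]
    return CrossFamily(p1, p2, offs, 1)


def _table(family, markers):
    return GenotypeTable(marker_ids=list(markers), families=[family])


class TestStatusMachine:
    MARKERS = ["M1", "M2", "M3", "M4", "M5"]

    def _run(self, p1, p2, f1, thr=None):
        fam = _family(p1, p2, [f1], self.MARKERS)
        return run_qc(_table(fam, self.MARKERS), thr).families[0].offspring[0]

    def test_true_cross_at_full_hybridity(self):
        off = self._run([AA] * 5, [GG] * 5, [AG] * 5)
        assert off.status == STATUS_TRUE_CROSS
        assert off.hybridity == 100.0

    def test_self_at_zero_hybridity(self):
        off = self._run([AA] * 5, [GG] * 5, [AA] * 5)
        assert off.status == STATUS_SELF
        assert off.hybridity == 0.0

    def test_exact_threshold_hybridity_is_true_cross(self):
        # 50% hybridity lands exactly on the default minimum: kept a hybrid.
        calls = [AG, AG, AA, AA, MISSING_CALL]
        off = self._run([AA] * 5, [GG] * 5, calls)
        assert off.hybridity == 50.0
        assert off.status == STATUS_TRUE_CROSS

    def test_low_polymorphism_undetermined(self):
        # 1 informative locus out of 5 => 20% is not below the default 20.
        p2 = [GG, AA, AA, AA, AA]
        off = self._run([AA] * 5, p2, [AG] * 5)
        assert off.status == STATUS_TRUE_CROSS
        # 0 informative loci => polymorphism 0% < 20 => undetermined.
        off = self._run([AA] * 5, [AA] * 5, [AG] * 5)
        assert off.status == STATUS_UNDET_POLY

    def test_excess_missing_undetermined(self):
        calls = [AG, AG, MISSING_CALL, MISSING_CALL, AG]
        off = self._run([AA] * 5, [GG] * 5, calls)
        assert off.missing_pct == 40.0
        assert off.status == STATUS_UNDET_MISSING

    def test_heterozygous_parent_takes_precedence(self):
        # Parent 1 heterozygous at 2/5 loci (40% > 20%) while the pair is
        # also poorly polymorphic: the parent-het verdict wins.
        p1 = [AG, AG, AA, AA, AA]
        off = self._run(p1, [AA] * 5, [AA] * 5)
        assert off.status == STATUS_UNDET_HET

    def test_all_informative_calls_missing_undetermined(self):
        calls = [MISSING_CALL] * 5
        off = self._run([AA] * 5, [GG] * 5, calls)
        assert off.hybridity is None
        assert off.status == STATUS_UNDET_MISSING

    def test_custom_thresholds_change_verdict(self):
        calls = [AG, AG, AG, AA, AA]  # 60% hybridity
        off = self._run([AA] * 5, [GG] * 5, calls,
                        Thresholds(min_hybridity_pct=90.0))
        assert off.status == STATUS_SELF

    def test_threshold_monotonicity(self):
        """Raising the hybridity threshold can only turn TRUE CROSS into
        SELF, never the reverse."""
        rng = np.random.default_rng(5)
        fam = random_family(rng, n_markers=6, n_offspring=4)
        tab = GenotypeTable(marker_ids=[f"M{i}" for i in range(1, 7)],
                            families=[fam])
        lo = run_qc(tab, Thresholds(min_hybridity_pct=30.0))
        hi = run_qc(tab, Thresholds(min_hybridity_pct=70.0))
        for off_lo, off_hi in zip(lo.families[0].offspring,
                                  hi.families[0].offspring):
            if off_lo.status == STATUS_SELF:
                assert off_hi.status == STATUS_SELF
            if off_hi.status == STATUS_TRUE_CROSS:
                assert off_lo.status == STATUS_TRUE_CROSS


class TestMarkerEfficiency:
    def test_counts_all_pairs_in_denominator(self):
        markers = ["M1"]
        fams = [
            _family([AA], [GG], [], markers),            # polymorphic
            _family([AA], [AA], [], markers),            # monomorphic
            _family([AG], [GG], [], markers),            # parent het
            _family([MISSING_CALL], [GG], [], markers),  # missing
        ]
        table = GenotypeTable(marker_ids=markers, families=[
            CrossFamily(f.parent1, f.parent2, f.offspring, i + 1)
            for i, f in enumerate(fams)])
        result = run_qc(table)
        eff = result.marker_efficiencies["M1"]
        assert (eff.fm, eff.tc) == (1, 4)
        assert eff.efficiency_pct == 25.0

    def test_single_polymorphic_family_is_100(self):
        markers = ["M1"]
        table = _table(_family([AA], [GG], [], markers), markers)
        eff = run_qc(table).marker_efficiencies["M1"]
        assert eff.efficiency_pct == 100.0

    def test_requires_at_least_one_family(self):
        with pytest.raises(ValueError):
            marker_efficiency([], "M1")


class TestRunQC:
    def test_worked_three_snp_cross(self, fig_cross_table):
        result = run_qc(fig_cross_table)
        statuses = [o.status for o in result.families[0].offspring]
        assert statuses == [STATUS_TRUE_CROSS] * 3 + [STATUS_SELF]
        profile = result.families[0].profile
        assert profile.pm == 3 and profile.polymorphism_pct == 100.0

    def test_partition_invariants(self):
        rng = np.random.default_rng(23)
        table = random_table(rng, n_families=8)
        result = run_qc(table)
        for fr in result.families:
            p = fr.profile
            counts = {}
            for c in p.locus_classes.values():
                counts[c] = counts.get(c, 0) + 1
            assert sum(counts.values()) == p.tm
            assert counts.get(LocusClass.POLYMORPHIC, 0) == p.pm
            assert counts.get(LocusClass.MISSING, 0) == p.mc_parents
            for off in fr.offspring:
                assert len(off.locus_classes) == p.pm
                ocounts = {}
                for c in off.locus_classes.values():
                    ocounts[c] = ocounts.get(c, 0) + 1
                hom = ocounts.get(OffspringLocusClass.HOM_PARENTAL, 0)
                assert off.lhet + off.lnpa + off.mc_f1_inf + hom == p.pm

    def test_marker_permutation_invariance(self):
        rng = np.random.default_rng(31)
        table = random_table(rng, n_families=5, max_markers=6)
        result = run_qc(table)
        perm = list(table.marker_ids)[::-1]
        permuted = GenotypeTable(marker_ids=perm, families=table.families)
        result2 = run_qc(permuted)
        for fr1, fr2 in zip(result.families, result2.families):
            assert fr1.profile.pm == fr2.profile.pm
            assert fr1.profile.polymorphism_pct == fr2.profile.polymorphism_pct
            for o1, o2 in zip(fr1.offspring, fr2.offspring):
                assert (o1.status, o1.hybridity, o1.lnpa) == \
                       (o2.status, o2.hybridity, o2.lnpa)

    def test_appending_monomorphic_locus_keeps_hybridity(self):
        markers = ["M1", "M2", "M3"]
        fam = _family([AA, AA, TT], [GG, GG, TT], [[AG, AA, TT]], markers)
        base = run_qc(_table(fam, markers)).families[0].offspring[0]
        markers2 = markers + ["M4"]
        fam2 = _family([AA, AA, TT, AA], [GG, GG, TT, AA],
                       [[AG, AA, TT, AA]], markers2)
        ext = run_qc(_table(fam2, markers2)).families[0].offspring[0]
        assert ext.hybridity == base.hybridity

    def test_appending_het_true_locus_never_decreases_hybridity(self):
        markers = ["M1", "M2"]
        fam = _family([AA, AA], [GG, GG], [[AG, AA]], markers)
        base = run_qc(_table(fam, markers)).families[0].offspring[0]
        markers2 = markers + ["M3"]
        fam2 = _family([AA, AA, TT], [GG, GG, AA], [[AG, AA, AT]], markers2)
        ext = run_qc(_table(fam2, markers2)).families[0].offspring[0]
        assert ext.hybridity >= base.hybridity

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_matches_bruteforce_oracle(self, seed):
        """run_qc agrees exactly with a per-locus enumeration oracle on
        random families covering every locus class."""
        rng = np.random.default_rng(seed)
        thr = Thresholds()
        table = random_table(rng, n_families=3)
        result = run_qc(table, thr)
        for fr in result.families:
            expect = oracle_family(fr.family, table.marker_ids, thr)
            assert fr.profile.pm == expect["pm"]
            assert fr.profile.polymorphism_pct == expect["polymorphism"]
            assert fr.profile.parent1.het_pct == expect["het1"]
            assert fr.profile.parent2.het_pct == expect["het2"]
            for off, exp in zip(fr.offspring, expect["offspring"]):
                assert off.status == exp["status"]
                assert off.hybridity == exp["hybridity"]
                assert off.non_parental == exp["non_parental"]
        eff = oracle_marker_efficiency(table.families, table.marker_ids)
        for m, (fm, tc, pct) in eff.items():
            got = result.marker_efficiencies[m]
            assert (got.fm, got.tc, got.efficiency_pct) == (fm, tc, pct)
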