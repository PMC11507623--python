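"""Shared fixtures: the illustrative three-SNP cross and random families."""

from __future__ import annotations

import numpy as np
import pytest

from kaspqc.genotype_io import (
    CrossFamily,
    GenotypeCall,
    GenotypeTable,
    MISSING_CALL,
    Role,
    SampleRecord,
)

# The worked example: two fully homozygous parents that differ at all
# three SNPs; offspring 1-3 heterozygous everywhere (true hybrids),
# offspring 4 identical to parent 1 (a self).
FIG_CROSS_CSV = """\
Sample ID,Sample Name,Type,SNP1,SNP2,SNP3
P1,IT97K-573-1-1,Parent,A:A,T:T,G:G
P2,Danila,Parent,G:G,C:C,T:T
F1-1,IT97K-573-1-1/Danila,F1,A:G,C:T,G:T
F1-2,IT97K-573-1-1/Danila,F1,A:G,C:T,G:T
F1-3,IT97K-573-1-1/Danila,F1,A:G,C:T,G:T
F1-4,IT97K-573-1-1/Danila,F1,A:A,T:T,G:G
"""


@pytest.fixture
def fig_cross_path(tmp_path):
    path = tmp_path / "fig_cross.csv"
    path.write_text(FIG_CROSS_CSV)
    return path


@pytest.fixture
def fig_cross_table(fig_cross_path):
    from kaspqc.genotype_io import read_table

    return read_table(fig_cross_path)


def random_call(rng: np.random.Generator, alleles="ACGT",
                p_missing=0.1) -> GenotypeCall:
    if rng.random() < p_missing:
        return MISSING_CALL
    pair = rng.choice(list(alleles), size=2, replace=True)
    return GenotypeCall(tuple(sorted(pair)))


def random_family(rng: np.random.Generator, n_markers: int, n_offspring: int,
                  index: int = 1) -> CrossFamily:
    """A fully randomized family exercising every locus class: parents may
    be missing, heterozygous, identical or distinct; offspring calls are a
    mix of the expected heterozygote, copies of a parent, random pairs and
    missing calls."""
    markers = [f"M{i}" for i in range(1, n_markers + 1)]

    def parent(tag: str) -> SampleRecord:
        calls = {}
        for m in markers:
            u = rng.random()
            if u < 0.10:
                calls[m] = MISSING_CALL
            elif u < 0.25:  # heterozygous parent call
                pair = rng.choice(list("ACGT"), size=2, replace=False)
                calls[m] = GenotypeCall(tuple(sorted(pair)))
            else:
                a = rng.choice(list("ACGT"))
                calls[m] = GenotypeCall((a, a))
        return SampleRecord(f"P{index}-{tag}", f"parent-{tag}", Role.PARENT,
                            calls)

    p1, p2 = parent("1"), parent("2")
    offspring = []
    for oi in range(n_offspring):
        calls = {}
        for m in markers:
            u = rng.random()
            a1, a2 = p1.calls[m], p2.calls[m]
            if u < 0.10 or a1.missing or a2.missing:
                calls[m] = random_call(rng)
            elif u < 0.45:  # one allele from each parent
                x = a1.alleles[int(rng.integers(2))]
                y = a2.alleles[int(rng.integers(2))]
                calls[m] = GenotypeCall(tuple(sorted((x, y))))
            elif u < 0.70:  # copy parent 1
                calls[m] = a1
            else:
                calls[m] = random_call(rng, p_missing=0.2)
        offspring.append(SampleRecord(f"F{index}-{oi}", f"off-{oi}", Role.F1,
                                      calls))
    return CrossFamily(p1, p2, offspring, index)


def random_table(rng: np.random.Generator, n_families: int,
                 max_markers: int = 8, max_offspring: int = 5,
                 min_offspring: int = 0) -> GenotypeTable:
    # min_offspring=1 keeps the table writable: in the positional grid
    # dialect a zero-offspring family followed by another family would
    # merge into one four-parent run on re-reading.
    n_markers = int(rng.integers(1, max_markers + 1))
    fams = [random_family(rng, n_markers,
                          int(rng.integers(min_offspring, max_offspring + 1)),
                          index=i + 1)
            for i in range(n_families)]
    return GenotypeTable(marker_ids=[f"M{i}" for i in range(1, n_markers + 1)],
                         families=fams)
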