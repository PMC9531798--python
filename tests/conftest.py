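"""Shared fixtures: genotype builders and exhaustive genotype enumeration."""

from __future__ import annotations

from itertools import product

import pytest

from kdrsurv.genotypes import LOCI, DiploidGenotype, LocusGenotype, Zygosity
from kdrsurv.phasing import LOCUS_ALPHABETS, HaplotypePanel


def make_genotype(zygosities: tuple[str, str, str, str],
                  specimen_id: str = "t1", **metadata) -> DiploidGenotype:
    """Build a genotype from per-locus zygosity words ('wild'|'het'|'hom')."""
    calls = {}
    for locus, z in zip(LOCI, zygosities):
        wild, mutant = LOCUS_ALPHABETS[locus]
        if z == "wild":
            calls[locus] = LocusGenotype(locus, (wild, wild), Zygosity.WILD_HOM)
        elif z == "hom":
            calls[locus] = LocusGenotype(locus, (mutant, mutant),
                                         Zygosity.MUTANT_HOM)
        elif z == "het":
            calls[locus] = LocusGenotype(locus, (wild, mutant), Zygosity.HET)
        else:
            raise ValueError(z)
    return DiploidGenotype(specimen_id=specimen_id, locus_calls=calls,
                           **metadata)


def genotype_from_labels(labels: dict[int, str], **kw) -> DiploidGenotype:
    """Build a genotype from per-locus labels like {989: 'S/P', ...}."""
    words = []
    for locus in LOCI:
        wild, mutant = LOCUS_ALPHABETS[locus]
        pair = set(labels[locus].split("/"))
        words.append("wild" if pair == {wild}
                     else "hom" if pair == {mutant} else "het")
    return make_genotype(tuple(words), **kw)


def all_81_genotypes() -> list[DiploidGenotype]:
    """Every zygosity combination across the four loci."""
    return [make_genotype(z, specimen_id="-".join(z))
            for z in product(("wild", "het", "hom"), repeat=4)]


@pytest.fixture
def default_panel() -> HaplotypePanel:
    return HaplotypePanel()


@pytest.fixture
def genotype81() -> list[DiploidGenotype]:
    return all_81_genotypes()
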