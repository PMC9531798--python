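"""Panel-constrained phasing of four-locus kdr genotypes.

A diploid specimen carries two VGSC haplotypes, written as 4-letter codes
over the loci (989, 1016, 1534, 1763) with per-locus alphabets
{S,P} x {V,G} x {F,C} x {D,Y}; SVFD is the wild type.  Direct Sanger
sequencing yields only the unphased locus-wise genotype, so a genotype with
k heterozygous loci is compatible with 2^(max(k,1)-1) unordered haplotype
pairs.  Field studies resolve this ambiguity against a reference panel of
haplotypes known to segregate in the population: a genotype is assigned a
pair when exactly one compatible pair lies fully within the panel
(``panel_unique``), or when the decomposition is combinatorially unique
(k <= 1) even though it requires a haplotype outside the panel
(``forced_novel``).  Genotypes with several fully-in-panel pairs are
``ambiguous``; genotypes with none and k >= 2 are ``unresolved`` and are
reported in per-locus notation (e.g. ``SP/VG/FC/DY``) — phasing never
guesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Iterable, Sequence

import pandas as pd

from .genotypes import LOCI, DiploidGenotype, Zygosity

__all__ = [
    "LOCUS_ALPHABETS",
    "WILD_HAPLOTYPE",
    "DEFAULT_PANEL_MEMBERS",
    "HaplotypePanel",
    "PhaseStatus",
    "PhasedGenotype",
    "validate_haplotype",
    "all_haplotypes",
    "haplotype_union",
    "pair_label",
    "per_locus_notation",
    "enumerate_decompositions",
    "phase",
    "tabulate_genotypes",
]

#: Wild/mutant amino-acid letters per locus, in locus order.
LOCUS_ALPHABETS: dict[int, tuple[str, str]] = {
    989: ("S", "P"), 1016: ("V", "G"), 1534: ("F", "C"), 1763: ("D", "Y"),
}

WILD_HAPLOTYPE = "SVFD"

#: Default reference panel: the six haplotypes reported to segregate in
#: Taiwanese *Ae. aegypti*.  Config-overridable; the panel is data, not code.
DEFAULT_PANEL_MEMBERS: frozenset[str] = frozenset(
    {"SVFD", "SVCD", "PGFD", "SGFY", "SGFD", "PVFD"}
)


def validate_haplotype(code: str) -> str:
    code = code.strip().upper()
    if len(code) != len(LOCI):
        raise ValueError(f"haplotype {code!r} must have {len(LOCI)} letters")
    for letter, locus in zip(code, LOCI):
        if letter not in LOCUS_ALPHABETS[locus]:
            raise ValueError(
                f"haplotype {code!r}: letter {letter!r} invalid at locus {locus}")
    return code


def all_haplotypes() -> list[str]:
    """All 16 possible four-locus haplotypes, lexicographic in locus order."""
    return ["".join(p) for p in product(*(LOCUS_ALPHABETS[l] for l in LOCI))]


@dataclass(frozen=True)
class HaplotypePanel:
    """Reference set of haplotypes used to constrain phasing."""

    members: frozenset[str] = DEFAULT_PANEL_MEMBERS
    name: str = "taiwan-six"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "members", frozenset(validate_haplotype(h) for h in self.members))
        if WILD_HAPLOTYPE not in self.members:
            raise ValueError(f"panel must contain the wild type {WILD_HAPLOTYPE}")

    def __contains__(self, haplotype: str) -> bool:
        return haplotype in self.members


class PhaseStatus(str, Enum):
    PANEL_UNIQUE = "panel_unique"
    FORCED_NOVEL = "forced_novel"
    AMBIGUOUS = "ambiguous"
    UNRESOLVED = "unresolved"


def haplotype_union(h1: str, h2: str) -> dict[int, frozenset[str]]:
    """Locus-wise allele sets of the genotype formed by a haplotype pair."""
    return {
        locus: frozenset({a, b})
        for locus, a, b in zip(LOCI, validate_haplotype(h1), validate_haplotype(h2))
    }


def pair_label(pair: Sequence[str]) -> str:
    """Stable genotype label with alphabetically ordered members."""
    return "/".join(sorted(pair))


def per_locus_notation(g: DiploidGenotype) -> str:
    """Per-locus fallback notation for unresolved genotypes, wild letter first.

    E.g. the quadruple heterozygote is written ``SP/VG/FC/DY``.
    """
    parts = []
    for locus in LOCI:
        wild, mutant = LOCUS_ALPHABETS[locus]
        z = g.locus_calls[locus].zygosity
        if z is Zygosity.WILD_HOM:
            parts.append(wild + wild)
        elif z is Zygosity.MUTANT_HOM:
            parts.append(mutant + mutant)
        else:
            parts.append(wild + mutant)
    return "/".join(parts)


@dataclass
class PhasedGenotype:
    """Outcome of panel-constrained phasing for one specimen."""

    specimen_id: str
    status: PhaseStatus
    candidates: list[tuple[str, str]]
    assigned_pair: tuple[str, str] | None = None
    novel_members: tuple[str, ...] = ()
    locus_notation: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        """Genotype label: assigned pair if any, else per-locus notation."""
        if self.assigned_pair is not None:
            return pair_label(self.assigned_pair)
        return self.locus_notation


def enumerate_decompositions(g: DiploidGenotype) -> list[tuple[str, str]]:
    """All unordered haplotype pairs consistent with an unphased genotype.

    Homozygous loci contribute their single allele to both haplotypes; each
    heterozygous locus splits its two alleles between them.  Fixing the first
    heterozygous locus's assignment removes the pair-order double count, so a
    genotype with k heterozygous loci yields exactly 2^(max(k,1)-1) unordered
    pairs, returned sorted by label.
    """
    het = [l for l in LOCI if g.locus_calls[l].zygosity is Zygosity.HET]
    first = {}
    for locus in LOCI:
        call = g.locus_calls[locus]
        first[locus] = call.allele_pair[0]
    pairs: set[tuple[str, str]] = set()
    k = len(het)
    # bit i chooses which haplotype receives the first-listed allele of het[i];
    # het[0] (if any) is pinned to haplotype 1 to avoid counting (h1,h2) twice
    for bits in range(2 ** max(k - 1, 0)):
        h1, h2 = [], []
        flips = {het[0]: 0} if het else {}
        for i, locus in enumerate(het[1:], start=1):
            flips[locus] = (bits >> (i - 1)) & 1
        for locus in LOCI:
            a, b = g.locus_calls[locus].allele_pair
            if locus in flips and flips[locus]:
                a, b = b, a
            h1.append(a)
            h2.append(b)
        pairs.add(tuple(sorted(("".join(h1), "".join(h2)))))
    return sorted(pairs)


def phase(g: DiploidGenotype, panel: HaplotypePanel | Iterable[str] = None
          ) -> PhasedGenotype:
    """Resolve an unphased genotype against a reference haplotype panel.

    Assignment rule (in order):

    1. exactly one candidate pair fully in the panel -> ``panel_unique``;
    2. no fully-in-panel candidate but a combinatorially unique decomposition
       (k <= 1 heterozygous loci) -> ``forced_novel``, flagging out-of-panel
       members;
    3. two or more fully-in-panel candidates -> ``ambiguous``, no assignment;
    4. otherwise -> ``unresolved``, reported in per-locus notation.
    """
    if panel is None:
        panel = HaplotypePanel()
    elif not isinstance(panel, HaplotypePanel):
        panel = HaplotypePanel(frozenset(panel), name="custom")
    candidates = enumerate_decompositions(g)
    in_panel = [p for p in candidates if p[0] in panel and p[1] in panel]
    meta = {"population_unit": g.population_unit,
            "survey_round": g.survey_round, "outcome": g.outcome}
    common = dict(specimen_id=g.specimen_id, candidates=candidates,
                  locus_notation=per_locus_notation(g), metadata=meta)
    if len(in_panel) == 1:
        pair = in_panel[0]
        return PhasedGenotype(status=PhaseStatus.PANEL_UNIQUE,
                              assigned_pair=pair, **common)
    if len(in_panel) == 0 and len(candidates) == 1:
        pair = candidates[0]
        novel = tuple(sorted({h for h in pair if h not in panel}))
        return PhasedGenotype(status=PhaseStatus.FORCED_NOVEL,
                              assigned_pair=pair, novel_members=novel, **common)
    if len(in_panel) >= 2:
        return PhasedGenotype(status=PhaseStatus.AMBIGUOUS, **common)
    return PhasedGenotype(status=PhaseStatus.UNRESOLVED, **common)


def tabulate_genotypes(phased: Iterable[PhasedGenotype],
                       group_by: str | None = None) -> pd.DataFrame:
    """Count combined genotypes, with within-group percentage shares.

    ``group_by`` names a metadata key (e.g. ``"survey_round"`` or
    ``"outcome"``); unresolved genotypes are tabulated under their per-locus
    notation, ambiguous ones under ``"ambiguous:" + notation`` so they remain
    visible but cannot be confused with an assigned pair.  Percentages within
    each group sum to 100 up to rounding.
    """
    rows = []
    for p in phased:
        if p.status is PhaseStatus.AMBIGUOUS:
            label = "ambiguous:" + p.locus_notation
        else:
            label = p.label
        rows.append({
            "genotype": label,
            "status": p.status.value,
            "group": p.metadata.get(group_by, "all") if group_by else "all",
        })
    if not rows:
        return pd.DataFrame(columns=["genotype", "group", "count", "percent"])
    df = pd.DataFrame(rows)
    counts = (df.groupby(["group", "genotype"], sort=False).size()
                .rename("count").reset_index())
    totals = counts.groupby("group")["count"].transform("sum")
    counts["percent"] = (counts["count"] / totals * 100).round(1)
    return counts.sort_values(["group", "count"],
                              ascending=[True, False]).reset_index(drop=True)
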