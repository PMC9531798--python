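"""Per-locus diploid genotype calling at the four VGSC kdr codons.

Knockdown resistance (kdr) in *Aedes aegypti* is conferred by amino-acid
substitutions in the voltage-gated sodium channel (VGSC).  This module calls
diploid genotypes at the four resistance codons surveyed in Taiwanese
populations — S989P (TCC>CCC) and V1016G (GTA>GGA) in domain II, F1534C
(TTC>TGC) in domain III and D1763Y (GAC>TAC) in domain IV — from Sanger
amplicon consensus sequences in which heterozygous positions appear as IUPAC
ambiguity codes (Y = C/T, K = G/T, ...), or from pre-called genotype tables.

Codon numbering follows the house fly VGSC reference, the field convention.
Each locus is modelled as strictly biallelic (wild vs mutant codon); any
other codon state is an error rather than a call, mirroring manual
chromatogram confirmation of direct-sequencing traces.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "IUPAC_NUCLEOTIDES",
    "CodonSpec",
    "Zygosity",
    "LocusGenotype",
    "DiploidGenotype",
    "UncallableLocusError",
    "IncompleteSpecimenError",
    "DEFAULT_CODON_SPECS",
    "LOCI",
    "call_codon",
    "call_specimen",
    "read_fasta_specimens",
    "genotypes_from_fasta",
    "genotypes_to_csv",
    "genotypes_from_csv",
]

#: IUPAC nucleotide ambiguity codes mapped to the nucleotide sets they denote.
IUPAC_NUCLEOTIDES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: The four surveyed VGSC codons, in genomic order.
LOCI: tuple[int, ...] = (989, 1016, 1534, 1763)


class Zygosity(str, Enum):
    WILD_HOM = "wild_hom"
    HET = "het"
    MUTANT_HOM = "mutant_hom"


class UncallableLocusError(ValueError):
    """The observed codon cannot be resolved to the wild/mutant allele pair."""

    def __init__(self, locus_name: int, observed_codon: str, reason: str):
        self.locus_name = locus_name
        self.observed_codon = observed_codon
        super().__init__(
            f"uncallable locus {locus_name}: codon {observed_codon!r} ({reason})"
        )


class IncompleteSpecimenError(ValueError):
    """A specimen is missing one or more amplicons required for calling."""

    def __init__(self, specimen_id: str, missing_loci: Sequence[int]):
        self.specimen_id = specimen_id
        self.missing_loci = tuple(missing_loci)
        super().__init__(
            f"incomplete specimen {specimen_id!r}: missing loci {self.missing_loci}"
        )


@dataclass(frozen=True)
class CodonSpec:
    """Location and allele definition of one kdr codon within its amplicon.

    ``offset`` is the 0-based position of the codon's first nucleotide in the
    amplicon consensus.  ``anchor`` is an optional exact flanking k-mer ending
    immediately before the codon; when set and found uniquely in the sequence
    it overrides ``offset``, making calling robust to small indel-free shifts
    in how the consensus was trimmed.
    """

    locus_name: int
    amplicon_id: str
    offset: int
    wild_codon: str
    mutant_codon: str
    wild_aa: str
    mutant_aa: str
    anchor: str | None = None

    def __post_init__(self) -> None:
        if self.locus_name not in LOCI:
            raise ValueError(f"unknown locus {self.locus_name}")
        if len(self.wild_codon) != 3 or len(self.mutant_codon) != 3:
            raise ValueError("codons must be 3 nt")
        if self.wild_codon == self.mutant_codon:
            raise ValueError("wild and mutant codons must differ")
        diffs = [i for i in range(3) if self.wild_codon[i] != self.mutant_codon[i]]
        if len(diffs) != 1:
            raise ValueError(
                "wild and mutant codons must differ at exactly one position"
            )
        if self.wild_aa == self.mutant_aa:
            raise ValueError("wild and mutant amino acids must differ")

    @property
    def discriminating_position(self) -> int:
        """Index (0-2) of the single nucleotide separating wild from mutant."""
        return next(
            i for i in range(3) if self.wild_codon[i] != self.mutant_codon[i]
        )


#: Default codon specifications.  The domain II amplicon carries both 989 and
#: 1016 (27 codons = 81 nt apart, in frame); offsets refer to the synthetic
#: 400-nt template amplicons used throughout this package and are config
#: overridable for real trimmed consensus sequences.
DEFAULT_CODON_SPECS: tuple[CodonSpec, ...] = (
    CodonSpec(989, "II", 150, "TCC", "CCC", "S", "P"),
    CodonSpec(1016, "II", 231, "GTA", "GGA", "V", "G"),
    CodonSpec(1534, "III", 180, "TTC", "TGC", "F", "C"),
    CodonSpec(1763, "IV", 165, "GAC", "TAC", "D", "Y"),
)


@dataclass(frozen=True)
class LocusGenotype:
    """Unordered diploid allele pair at one codon, e.g. S/P at 989."""

    locus_name: int
    allele_pair: tuple[str, str]  # wild letter first for heterozygotes
    zygosity: Zygosity

    @property
    def label(self) -> str:
        return "/".join(self.allele_pair)

    def alleles(self) -> tuple[str, str]:
        return self.allele_pair


@dataclass
class DiploidGenotype:
    """Unphased four-locus genotype of one specimen plus survey metadata."""

    specimen_id: str
    locus_calls: dict[int, LocusGenotype]
    population_unit: str = ""
    survey_round: str = ""
    sex: str = ""
    generation: str = ""
    outcome: str = "untested"  # dead | alive | untested
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.locus_calls) != set(LOCI):
            raise ValueError(
                f"genotype must cover loci {LOCI}, got {sorted(self.locus_calls)}"
            )
        if self.outcome not in {"dead", "alive", "untested"}:
            raise ValueError(f"invalid outcome {self.outcome!r}")

    def zygosity(self, locus: int) -> Zygosity:
        return self.locus_calls[locus].zygosity

    def het_loci(self) -> tuple[int, ...]:
        return tuple(
            l for l in LOCI if self.locus_calls[l].zygosity is Zygosity.HET
        )

    def locus_labels(self) -> dict[int, str]:
        return {l: self.locus_calls[l].label for l in LOCI}


def _make_locus_genotype(spec: CodonSpec, alleles: frozenset[str]) -> LocusGenotype:
    if alleles == {spec.wild_aa}:
        return LocusGenotype(spec.locus_name, (spec.wild_aa, spec.wild_aa),
                             Zygosity.WILD_HOM)
    if alleles == {spec.mutant_aa}:
        return LocusGenotype(spec.locus_name, (spec.mutant_aa, spec.mutant_aa),
                             Zygosity.MUTANT_HOM)
    return LocusGenotype(spec.locus_name, (spec.wild_aa, spec.mutant_aa),
                         Zygosity.HET)


def locus_genotype_from_label(spec: CodonSpec, label: str) -> LocusGenotype:
    """Parse a table entry like ``"S/P"`` into a :class:`LocusGenotype`."""
    parts = label.strip().upper().split("/")
    valid = {spec.wild_aa, spec.mutant_aa}
    if len(parts) != 2 or not set(parts) <= valid:
        raise UncallableLocusError(spec.locus_name, label,
                                   f"alleles must be in {sorted(valid)}")
    return _make_locus_genotype(spec, frozenset(parts))


def call_codon(sequence: str, spec: CodonSpec, *, reverse_complement: bool = False
               ) -> LocusGenotype:
    """Call the diploid genotype at one codon of an amplicon consensus.

    The codon is read at ``spec.offset`` (or after ``spec.anchor`` when
    configured and found).  IUPAC ambiguity codes are expanded to nucleotide
    sets, the codon's possible resolutions are intersected with
    {wild_codon, mutant_codon}, and zygosity follows from which alleles
    survive the intersection.  Only the single discriminating position may be
    ambiguous: an ambiguity code where the wild and mutant codons agree
    signals sequencing noise and raises :class:`UncallableLocusError`.
    """
    seq = sequence.strip().upper()
    if reverse_complement:
        seq = str(Seq(seq).reverse_complement())
    offset = spec.offset
    if spec.anchor:
        anchor = spec.anchor.upper()
        hit = seq.find(anchor)
        if hit >= 0 and seq.find(anchor, hit + 1) < 0:
            offset = hit + len(anchor)
    if len(seq) < offset + 3:
        raise UncallableLocusError(
            spec.locus_name, seq[offset:offset + 3],
            f"sequence shorter than offset+3 ({len(seq)} < {offset + 3})")
    codon = seq[offset:offset + 3]

    disc = spec.discriminating_position
    alleles: set[str] = set()
    for i, base in enumerate(codon):
        nts = IUPAC_NUCLEOTIDES.get(base)
        if nts is None:
            raise UncallableLocusError(spec.locus_name, codon,
                                       f"invalid nucleotide {base!r}")
        if i != disc:
            if len(nts) > 1:
                raise UncallableLocusError(
                    spec.locus_name, codon,
                    "ambiguity at a position where wild and mutant agree")
            if codon[i] != spec.wild_codon[i]:
                raise UncallableLocusError(
                    spec.locus_name, codon,
                    "matches neither wild nor mutant codon")
        else:
            if spec.wild_codon[i] in nts:
                alleles.add(spec.wild_aa)
            if spec.mutant_codon[i] in nts:
                alleles.add(spec.mutant_aa)
    if not alleles:
        raise UncallableLocusError(spec.locus_name, codon,
                                   "matches neither wild nor mutant codon")
    return _make_locus_genotype(spec, frozenset(alleles))


def call_specimen(amplicons: Mapping[str, str], specs: Iterable[CodonSpec],
                  *, specimen_id: str = "", reverse_complement: bool = False,
                  **metadata) -> DiploidGenotype:
    """Call all four loci of one specimen from its amplicon consensus map.

    ``amplicons`` maps amplicon id (e.g. ``"II"``) to its consensus sequence.
    Raises :class:`IncompleteSpecimenError` listing the loci whose amplicon is
    absent, or :class:`UncallableLocusError` from the first failing codon.
    """
    specs = tuple(specs)
    missing = [s.locus_name for s in specs if s.amplicon_id not in amplicons]
    if missing:
        raise IncompleteSpecimenError(specimen_id, missing)
    calls = {
        s.locus_name: call_codon(amplicons[s.amplicon_id], s,
                                 reverse_complement=reverse_complement)
        for s in specs
    }
    return DiploidGenotype(specimen_id=specimen_id, locus_calls=calls, **metadata)


def read_fasta_specimens(handle: TextIO | str | Path
                         ) -> dict[str, dict[str, str]]:
    """Group FASTA records ``<specimen_id>|<amplicon_id>`` by specimen.

    Returns ``{specimen_id: {amplicon_id: sequence}}`` preserving input order.
    """
    specimens: dict[str, dict[str, str]] = {}
    for record in SeqIO.parse(handle, "fasta"):
        if "|" not in record.id:
            raise ValueError(
                f"FASTA id {record.id!r} does not follow '<specimen>|<amplicon>'")
        specimen_id, amplicon_id = record.id.split("|", 1)
        specimens.setdefault(specimen_id, {})[amplicon_id] = str(record.seq)
    return specimens


def genotypes_from_fasta(handle: TextIO | str | Path,
                         specs: Iterable[CodonSpec] = DEFAULT_CODON_SPECS,
                         *, reverse_complement: bool = False,
                         metadata: Mapping[str, Mapping[str, str]] | None = None,
                         ) -> tuple[list[DiploidGenotype], list[tuple[str, str]]]:
    """Call every specimen in a FASTA file.

    ``metadata`` optionally maps specimen id to metadata fields (district,
    round, outcome ...).  Returns ``(genotypes, failures)`` where failures are
    ``(specimen_id, reason)`` pairs for uncallable/incomplete specimens; the
    caller decides whether to treat failures as fatal.
    """
    specs = tuple(specs)
    genotypes: list[DiploidGenotype] = []
    failures: list[tuple[str, str]] = []
    for specimen_id, amplicons in read_fasta_specimens(handle).items():
        meta = dict((metadata or {}).get(specimen_id, {}))
        try:
            genotypes.append(call_specimen(
                amplicons, specs, specimen_id=specimen_id,
                reverse_complement=reverse_complement, **meta))
        except (UncallableLocusError, IncompleteSpecimenError) as exc:
            failures.append((specimen_id, str(exc)))
    return genotypes, failures


_CSV_COLUMNS = ["specimen_id", "district", "round", "outcome",
                "g989", "g1016", "g1534", "g1763"]


def genotypes_to_csv(genotypes: Iterable[DiploidGenotype],
                     handle: TextIO | str | Path) -> None:
    """Write a genotype table CSV with per-locus labels like ``S/P``."""
    rows = [
        {"specimen_id": g.specimen_id, "district": g.population_unit,
         "round": g.survey_round, "outcome": g.outcome,
         **{f"g{l}": g.locus_calls[l].label for l in LOCI}}
        for g in genotypes
    ]
    close = False
    if isinstance(handle, (str, Path)):
        handle = open(handle, "w", newline="")
        close = True
    try:
        writer = csv.DictWriter(handle, fieldnames=_CSV_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    finally:
        if close:
            handle.close()


def genotypes_from_csv(handle: TextIO | str | Path,
                       specs: Iterable[CodonSpec] = DEFAULT_CODON_SPECS,
                       ) -> list[DiploidGenotype]:
    """Read a genotype table CSV produced by :func:`genotypes_to_csv`."""
    by_locus = {s.locus_name: s for s in specs}
    close = False
    if isinstance(handle, (str, Path)):
        handle = open(handle, newline="")
        close = True
    try:
        out = []
        for row in csv.DictReader(handle):
            calls = {
                l: locus_genotype_from_label(by_locus[l], row[f"g{l}"])
                for l in LOCI
            }
            out.append(DiploidGenotype(
                specimen_id=row["specimen_id"], locus_calls=calls,
                population_unit=row.get("district", ""),
                survey_round=row.get("round", ""),
                outcome=row.get("outcome", "untested") or "untested"))
        return out
    finally:
        if close:
            handle.close()
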