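"""Synthetic specimens, consensus sequences and bioassay outcomes.

The generator emulates the data a field kdr survey produces, so every
pipeline stage is testable without specimens: diploid mosquitoes are drawn
by random union of haplotypes from a frequency vector (Hardy–Weinberg at the
haplotype level — the VGSC locus and the sex-determining locus sit on
different chromosomes, so no sex linkage is modelled), their amplicon
consensus sequences are emitted as FASTA with IUPAC ambiguity codes at
heterozygous positions, and bioassay fates are drawn from genotype-specific
probit dose–response curves.

The true haplotype pair of every simulated specimen is retained as hidden
ground truth for round-trip and recovery tests.  Identical seed and
configuration give byte-identical output.

The default March-like and October-like haplotype-frequency vectors are the
maximum-likelihood estimates from the published two-round 2016 field survey
of southern Taiwan that this package's worked example reproduces (haplotype
counts over resolved specimens; see the reference tables module).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .bioassay import BioassayRecord
from .genotypes import (DEFAULT_CODON_SPECS, LOCI, CodonSpec, DiploidGenotype,
                        LocusGenotype, Zygosity)
from .phasing import LOCUS_ALPHABETS, haplotype_union, pair_label, validate_haplotype

__all__ = [
    "MARCH_HAPLOTYPE_FREQS",
    "OCTOBER_HAPLOTYPE_FREQS",
    "DEFAULT_DOSE_LADDER",
    "DEFAULT_GENOTYPE_PARAMS",
    "SimulationConfig",
    "SimulatedSpecimen",
    "sample_population",
    "emit_fasta",
    "make_templates",
    "simulate_bioassay",
]

#: Haplotype frequencies estimated from the March round of the 2016 survey
#: (296 chromosomes over 148 resolved male specimens).
MARCH_HAPLOTYPE_FREQS: dict[str, float] = {
    "SVFD": 195 / 296, "SVCD": 54 / 296, "PGFD": 26 / 296,
    "SGFD": 11 / 296, "SGFY": 9 / 296, "PVFD": 1 / 296,
}

#: October round (340 chromosomes over 170 resolved specimens; the two
#: quadruple-heterozygote specimens whose phase cannot be resolved are
#: excluded from the estimate).
OCTOBER_HAPLOTYPE_FREQS: dict[str, float] = {
    "SVFD": 112 / 340, "SVCD": 91 / 340, "PGFD": 95 / 340,
    "SGFY": 35 / 340, "SGFD": 5 / 340, "PGFY": 2 / 340,
}

#: WHO-style cypermethrin ladder within the 0.01-0.2 % w/w label range.
DEFAULT_DOSE_LADDER: tuple[float, ...] = (0.01, 0.02, 0.04, 0.08, 0.2)

# Probit (alpha, beta) tiers on log10 % w/w, slope 3 throughout:
# susceptible LC99 ~= 0.0095, just under the lowest ladder dose (>=99% dead
# across the ladder, matching the susceptible lab-strain expectation),
# intermediate LC50 ~= 0.06 (mid-ladder), resistant LC50 ~= 0.6 (above the
# ladder, survival ~100%).
_SUSCEPTIBLE = (8.4, 3.0)
_INTERMEDIATE = (3.66, 3.0)  # LC50 ~= 0.06
_RESISTANT = (0.66, 3.0)

#: Genotype-specific dose-response defaults, keyed by combined-genotype
#: label.  The tiers mirror the survival classes observed in the bioassay
#: reference table: double-mutant-haplotype genotypes and the 1534
#: homozygote are resistant, single-mutant-haplotype heterozygotes are
#: intermediate-to-susceptible.  Unlisted genotypes fall back to the wild
#: type's parameters.
DEFAULT_GENOTYPE_PARAMS: dict[str, tuple[float, float]] = {
    "SVFD/SVFD": _SUSCEPTIBLE,
    "SVCD/SVFD": _SUSCEPTIBLE,
    "SGFY/SVFD": _SUSCEPTIBLE,
    "SVFD/SVFY": _SUSCEPTIBLE,
    "SGFD/SVFD": _INTERMEDIATE,
    "SVCD/SVCD": _INTERMEDIATE,
    "PGFD/SVFD": _INTERMEDIATE,
    "PGFD/SVCD": _RESISTANT,
    "SGFY/SVCD": _RESISTANT,
    "PGFD/SGFY": _RESISTANT,
    "SGFY/SGFY": _RESISTANT,
    "PGFD/PGFD": _RESISTANT,
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated survey round and its bioassay."""

    haplotype_freqs: Mapping[str, float]
    n_specimens: int
    group_label: str = "simulated"
    seed: int = 0
    genotype_dose_response: Mapping[str, tuple[float, float]] = dc_field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_PARAMS))
    dose_ladder: Sequence[float] = DEFAULT_DOSE_LADDER
    n_per_dose: int = 25
    include_control: bool = True
    control_mortality: float = 0.0  # probability of death in the control cage
    fallback_to_wild_params: bool = True
    template_length: int = 400

    def __post_init__(self) -> None:
        total = float(sum(self.haplotype_freqs.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        for h in self.haplotype_freqs:
            validate_haplotype(h)
        for g, (_, beta) in self.genotype_dose_response.items():
            if beta <= 0:
                raise ValueError(f"non-positive slope for {g}")


@dataclass
class SimulatedSpecimen:
    """A generated mosquito: observed genotype plus hidden true phase."""

    genotype: DiploidGenotype
    true_pair: tuple[str, str]


def _union_genotype(specimen_id: str, pair: tuple[str, str],
                    **metadata) -> DiploidGenotype:
    calls = {}
    for locus, alleles in haplotype_union(*pair).items():
        wild, mutant = LOCUS_ALPHABETS[locus]
        if alleles == {wild}:
            calls[locus] = LocusGenotype(locus, (wild, wild), Zygosity.WILD_HOM)
        elif alleles == {mutant}:
            calls[locus] = LocusGenotype(locus, (mutant, mutant),
                                         Zygosity.MUTANT_HOM)
        else:
            calls[locus] = LocusGenotype(locus, (wild, mutant), Zygosity.HET)
    return DiploidGenotype(specimen_id=specimen_id, locus_calls=calls, **metadata)


def sample_population(cfg: SimulationConfig) -> list[SimulatedSpecimen]:
    """Draw diploid specimens by random union of haplotypes.

    Each specimen's two haplotypes are independent draws from
    ``cfg.haplotype_freqs`` (Hardy–Weinberg proportions at the haplotype
    level); the observed genotype is their locus-wise union and the ordered
    draw is kept as ground truth (stored unordered).
    """
    rng = np.random.default_rng(cfg.seed)
    haplotypes = sorted(cfg.haplotype_freqs)
    probs = np.array([cfg.haplotype_freqs[h] for h in haplotypes])
    draws = rng.choice(len(haplotypes), size=(cfg.n_specimens, 2), p=probs)
    out = []
    for i, (a, b) in enumerate(draws):
        pair = tuple(sorted((haplotypes[a], haplotypes[b])))
        sid = f"{cfg.group_label}-{i + 1:04d}"
        out.append(SimulatedSpecimen(
            genotype=_union_genotype(sid, pair, survey_round=cfg.group_label,
                                     population_unit=cfg.group_label),
            true_pair=pair))
    return out


def make_templates(specs: Sequence[CodonSpec] = DEFAULT_CODON_SPECS,
                   length: int = 400, seed: int = 20160301
                   ) -> dict[str, str]:
    """Neutral random amplicon templates with wild codons at spec offsets.

    The template seed is fixed independently of the population seed so the
    same amplicon background is reused across simulations; real amplicon
    sequences can be substituted via configuration.
    """
    rng = np.random.default_rng(seed)
    templates: dict[str, list[str]] = {}
    for spec in specs:
        if spec.amplicon_id not in templates:
            templates[spec.amplicon_id] = list(
                rng.choice(list("ACGT"), size=length))
        tpl = templates[spec.amplicon_id]
        if spec.offset + 3 > length:
            raise ValueError(
                f"template length {length} too short for {spec.locus_name}")
        tpl[spec.offset:spec.offset + 3] = spec.wild_codon
    return {amp: "".join(tpl) for amp, tpl in templates.items()}


_IUPAC_FOR_PAIR = {frozenset("AG"): "R", frozenset("CT"): "Y",
                   frozenset("CG"): "S", frozenset("AT"): "W",
                   frozenset("GT"): "K", frozenset("AC"): "M"}


def emit_fasta(specimens: Sequence[SimulatedSpecimen],
               specs: Sequence[CodonSpec] = DEFAULT_CODON_SPECS,
               templates: Mapping[str, str] | None = None) -> str:
    """Render per-specimen amplicon consensus sequences as FASTA text.

    Record ids follow ``<specimen_id>|<amplicon_id>``.  Homozygous loci get
    the plain wild or mutant codon; heterozygous loci carry the IUPAC
    ambiguity code at the single discriminating position, as a Sanger
    consensus would.
    """
    if templates is None:
        templates = make_templates(specs)
    for spec in specs:
        tpl = templates.get(spec.amplicon_id)
        if tpl is None or len(tpl) < spec.offset + 3:
            raise ValueError(
                f"template for amplicon {spec.amplicon_id!r} missing or too "
                f"short for locus {spec.locus_name}")
    lines = []
    for sp in specimens:
        per_amplicon: dict[str, list[str]] = {
            a: list(t) for a, t in templates.items()}
        for spec in specs:
            call = sp.genotype.locus_calls[spec.locus_name]
            disc = spec.discriminating_position
            if call.zygosity is Zygosity.WILD_HOM:
                codon = spec.wild_codon
            elif call.zygosity is Zygosity.MUTANT_HOM:
                codon = spec.mutant_codon
            else:
                pair = frozenset({spec.wild_codon[disc], spec.mutant_codon[disc]})
                codon = (spec.wild_codon[:disc] + _IUPAC_FOR_PAIR[pair]
                         + spec.wild_codon[disc + 1:])
            seq = per_amplicon[spec.amplicon_id]
            seq[spec.offset:spec.offset + 3] = codon
        for amplicon_id in sorted(per_amplicon):
            lines.append(f">{sp.genotype.specimen_id}|{amplicon_id}")
            lines.append("".join(per_amplicon[amplicon_id]))
    return "\n".join(lines) + "\n"


def simulate_bioassay(specimens: Sequence[SimulatedSpecimen],
                      cfg: SimulationConfig
                      ) -> tuple[list[BioassayRecord], list[SimulatedSpecimen]]:
    """Expose simulated specimens to the dose ladder and record fates.

    Specimens are assigned to dose cages round-robin after a seeded shuffle
    (``cfg.n_per_dose`` per cage where numbers allow).  A specimen in the
    cage at dose d dies with probability Phi(alpha_g + beta_g * log10 d)
    where (alpha_g, beta_g) are its combined genotype's parameters
    (falling back to the wild type's when enabled).  Returns the aggregate
    cage records (plus an optional control cage drawn at the configured
    baseline mortality) and the specimens with their ``outcome`` metadata
    set to dead/alive for the dead-vs-alive genotype analysis.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    params = dict(cfg.genotype_dose_response)
    wild_label = pair_label(("SVFD", "SVFD"))
    doses = list(cfg.dose_ladder)
    order = rng.permutation(len(specimens))
    records: list[BioassayRecord] = []
    exposed: list[SimulatedSpecimen] = []
    assignments: dict[float, list[SimulatedSpecimen]] = {d: [] for d in doses}
    for rank, idx in enumerate(order):
        assignments[doses[rank % len(doses)]].append(specimens[idx])
    for dose in doses:
        cage = assignments[dose]
        n_dead = 0
        for sp in cage:
            label = pair_label(sp.true_pair)
            if label not in params:
                if not cfg.fallback_to_wild_params:
                    raise ValueError(f"no dose-response parameters for {label}")
                alpha, beta = params.get(wild_label, _SUSCEPTIBLE)
            else:
                alpha, beta = params[label]
            p_die = float(sps.norm.cdf(alpha + beta * np.log10(dose)))
            dead = bool(rng.random() < p_die)
            n_dead += dead
            sp.genotype.outcome = "dead" if dead else "alive"
            exposed.append(sp)
        if cage:
            records.append(BioassayRecord(
                population_unit=cfg.group_label, concentration=dose,
                n_exposed=len(cage), n_dead=n_dead))
    if cfg.include_control:
        n_ctrl = cfg.n_per_dose
        ctrl_dead = int(rng.binomial(n_ctrl, cfg.control_mortality))
        records.append(BioassayRecord(
            population_unit=cfg.group_label, concentration=0.0,
            n_exposed=n_ctrl, n_dead=ctrl_dead, is_control=True))
    return records, exposed
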