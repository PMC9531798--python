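"""The two surveillance workflows, as library functions behind the CLI.

``run_surveillance`` turns two rounds of genotypes into the standard field
report: per-locus zygosity distributions with between-round tests, combined
genotype distributions with between-round tests, and mutant allele
frequencies.  ``run_bioassay_analysis`` turns outcome-annotated genotypes
and cage records into the genotype–phenotype report: dead-vs-alive tests,
survival rates, resistance classification, per-unit LC99 and the
class-proportion vs LC99 correlation.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from . import stats as kstats
from .bioassay import (BioassayRecord, classify_genotypes,
                       correlate_class_proportion, probit_fit)
from .config import PipelineConfig
from .genotypes import LOCI, DiploidGenotype
from .phasing import (PhaseStatus, PhasedGenotype, phase, tabulate_genotypes)

logger = logging.getLogger("kdrsurv")

__all__ = ["run_surveillance", "run_bioassay_analysis",
           "locus_comparison", "genotype_comparison"]

WILD_LABEL = "SVFD/SVFD"


def locus_comparison(genotypes: Sequence[DiploidGenotype], group_by: str,
                     groups: Sequence[str], cfg: PipelineConfig
                     ) -> pd.DataFrame:
    """Per-locus zygosity counts with mutant-class vs wild-class tests."""
    counts = kstats.zygosity_counts(genotypes, group_by)
    rows = []
    for locus in LOCI:
        sub = counts[counts["locus"] == locus].set_index("group")
        sub = sub.reindex(groups, fill_value=0)
        wild = sub["wild_hom"].to_numpy(dtype=float)
        for zclass, column in (("het", "het"), ("hom", "mutant_hom")):
            cat = sub[column].to_numpy(dtype=float)
            row = {"locus": locus, "class": zclass,
                   f"n_{groups[0]}": int(cat[0]), f"n_{groups[1]}": int(cat[1])}
            if cat.sum() == 0:
                row.update(test="", p_value=float("nan"), p="n/a")
            else:
                res = kstats.run_test([[wild[0], wild[1]], [cat[0], cat[1]]],
                                      category=f"{locus}:{zclass}",
                                      cutoff=cfg.expected_count_cutoff)
                row.update(test=res.test_used, p_value=res.p_value,
                           p=res.p_display)
            rows.append(row)
    return pd.DataFrame(rows)


def genotype_comparison(phased: Iterable[PhasedGenotype], group_by: str,
                        groups: Sequence[str], cfg: PipelineConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combined-genotype distribution and between-group tests.

    Ambiguous phasings are excluded from combined-genotype statistics (their
    per-locus calls still count in the locus-level comparison); unresolved
    genotypes are tabulated in per-locus notation.  Returns
    ``(distribution, tests)`` frames.
    """
    usable = [p for p in phased if p.status is not PhaseStatus.AMBIGUOUS]
    # tabulate_genotypes reads metadata; inject the grouping key
    for p in usable:
        p.metadata["__group"] = p.metadata.get(group_by, "all")
    dist = tabulate_genotypes(usable, group_by="__group")
    tidy = dist.rename(columns={"genotype": "category"})
    tests = kstats.compare_categories(
        tidy[["category", "group", "count"]], reference=WILD_LABEL,
        group_order=list(groups), cutoff=cfg.expected_count_cutoff)
    test_frame = pd.DataFrame([
        {"category": r.category, "test": r.test_used, "p_value": r.p_value,
         "p": r.p_display, "share_change": r.share_change}
        for r in tests])
    return dist, test_frame


def run_surveillance(genotypes: Sequence[DiploidGenotype],
                     cfg: PipelineConfig | None = None,
                     group_by: str = "survey_round",
                     groups: Sequence[str] | None = None) -> dict:
    """Field surveillance workflow over two survey rounds.

    Returns a dict of DataFrames: ``allele_frequencies``, ``locus_tests``,
    ``genotype_distribution``, ``genotype_tests`` and a ``phasing_summary``.
    With fewer than two groups the tests are skipped with a notice.
    """
    cfg = cfg or PipelineConfig()
    if not genotypes:
        raise ValueError("no genotypes supplied")
    if groups is None:
        seen = []
        for g in genotypes:
            key = getattr(g, group_by)
            if key not in seen:
                seen.append(key)
        groups = seen
    freqs = kstats.allele_frequencies(genotypes, group_by,
                                      decimals=cfg.freq_decimals)
    phased = [phase(g, cfg.panel) for g in genotypes]
    for p, g in zip(phased, genotypes):
        p.metadata[group_by] = getattr(g, group_by)
    summary = pd.Series([p.status.value for p in phased]).value_counts()
    out = {"allele_frequencies": freqs,
           "phasing_summary": summary.rename_axis("status").reset_index(name="count")}
    if len(groups) != 2:
        logger.warning("need exactly two groups for between-round tests, "
                       "got %s: tests skipped", list(groups))
        usable = [p for p in phased if p.status is not PhaseStatus.AMBIGUOUS]
        for p in usable:
            p.metadata["__group"] = p.metadata.get(group_by, "all")
        out["genotype_distribution"] = tabulate_genotypes(usable, "__group")
        return out
    out["locus_tests"] = locus_comparison(genotypes, group_by, groups, cfg)
    dist, tests = genotype_comparison(phased, group_by, groups, cfg)
    out["genotype_distribution"] = dist
    out["genotype_tests"] = tests
    return out


def run_bioassay_analysis(genotypes: Sequence[DiploidGenotype],
                          records: Sequence[BioassayRecord] = (),
                          cfg: PipelineConfig | None = None) -> dict:
    """Genotype–phenotype workflow on bioassay-exposed specimens.

    ``genotypes`` must carry dead/alive outcomes.  Returns dict with
    ``locus_tests``, ``genotype_tests``, ``survival``, ``classification``
    and, when cage records for >= 1 unit are supplied, ``lc99`` per unit
    plus ``correlation`` when >= 3 units allow it.
    """
    cfg = cfg or PipelineConfig()
    tested = [g for g in genotypes if g.outcome in ("dead", "alive")]
    if not tested:
        raise ValueError("no specimens with dead/alive outcomes")
    groups = ("dead", "alive")
    out: dict = {}
    out["locus_tests"] = locus_comparison(tested, "outcome", groups, cfg)
    phased = [phase(g, cfg.panel) for g in tested]
    for p, g in zip(phased, tested):
        p.metadata["outcome"] = g.outcome
    dist, tests = genotype_comparison(phased, "outcome", groups, cfg)
    out["genotype_distribution"] = dist
    out["genotype_tests"] = tests

    usable = [p for p in phased if p.status is not PhaseStatus.AMBIGUOUS]
    counts: dict[str, dict[str, int]] = {}
    for p in usable:
        entry = counts.setdefault(p.label, {"dead": 0, "alive": 0})
        entry[p.metadata["outcome"]] += 1
    surv_in = pd.DataFrame([
        {"category": k, "dead": v["dead"], "alive": v["alive"]}
        for k, v in counts.items()])
    survival = kstats.survival_rates(surv_in, decimals=cfg.percent_decimals)
    out["survival"] = survival

    surv_map = dict(zip(survival["category"], survival["survival_pct"]))
    wild_surv = surv_map.get(WILD_LABEL, 0.0)
    results = list(_results_from_frame(tests))
    labels = classify_genotypes(
        results, {k: v for k, v in surv_map.items() if k != WILD_LABEL},
        wild_survival_pct=wild_surv, alpha=cfg.alpha,
        strong_alpha=cfg.strong_alpha)
    out["classification"] = pd.DataFrame([
        {"genotype": l.genotype, "class": l.label, "p_value": l.p_value,
         "survival_pct": l.survival_pct, "strong": l.strong}
        for l in labels])

    by_unit: dict[str, list[BioassayRecord]] = {}
    for r in records:
        by_unit.setdefault(r.population_unit, []).append(r)
    if by_unit:
        fits = []
        for unit, recs in by_unit.items():
            try:
                fit = probit_fit(recs)
                fits.append({"unit": unit, "lc50": fit.lc50, "lc99": fit.lc99,
                             "slope": fit.slope, "intercept": fit.intercept,
                             "valid": fit.valid})
            except ValueError as exc:
                logger.warning("unit %s: %s", unit, exc)
        if fits:
            out["lc99"] = pd.DataFrame(fits)
    return out


def _results_from_frame(tests: pd.DataFrame):
    """Rehydrate lightweight ContingencyResult views from the test frame."""
    from .stats import ContingencyResult
    import numpy as np

    for _, row in tests.iterrows():
        yield ContingencyResult(category=row["category"],
                                table=np.zeros((2, 2)),
                                test_used=row["test"],
                                p_value=float(row["p_value"]))
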