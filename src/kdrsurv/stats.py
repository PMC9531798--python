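"""Population comparison statistics for kdr surveillance.

Implements the contingency-analysis scheme used in field resistance
surveillance: every non-reference category (a heterozygous or
mutant-homozygous zygosity class, or a non-wild combined genotype) is
compared against the wild-type reference between two groups (survey rounds,
or dead vs alive after a bioassay) in a 2x2 table.  Pearson's chi-square
without continuity correction is used when every expected cell count is at
least 5; otherwise a one-sided Fisher exact test, with the one-sided
direction testing enrichment of the tested category in the second group.
Mutant allele frequencies, per-genotype survival rates and the equal-variance
unpaired t-test on per-district frequencies round out the surveillance
toolkit.

p-values are presented with a 4-decimal convention ("0.0000" meaning
p < 0.00005); stored values keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import LOCI, DiploidGenotype, Zygosity
from .phasing import LOCUS_ALPHABETS

__all__ = [
    "ContingencyResult",
    "expected_counts",
    "select_test",
    "pearson_chi2",
    "fisher_one_sided",
    "run_test",
    "allele_frequency",
    "allele_frequencies",
    "zygosity_counts",
    "compare_categories",
    "survival_rates",
    "unpaired_t",
    "format_p",
]

EXPECTED_COUNT_CUTOFF = 5.0


@dataclass
class ContingencyResult:
    """A 2x2 comparison of one category against the wild-type reference.

    ``table`` rows are (reference, category); columns are (group1, group2).
    ``statistic`` is the chi-square value (None for Fisher).
    """

    category: str
    table: np.ndarray
    test_used: str  # "chi_square" | "fisher_one_sided"
    p_value: float
    statistic: float | None = None
    direction: str = "category enriched in group 2"
    share_change: float | None = None  # percentage-point change, group2 - group1

    @property
    def p_display(self) -> str:
        return format_p(self.p_value)


def format_p(p: float, decimals: int = 4) -> str:
    """4-decimal presentation; values below half a unit print as 0.0000."""
    return f"{p:.{decimals}f}"


def expected_counts(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0 or (rows == 0).any() or (cols == 0).any():
        raise ValueError("table has a zero marginal")
    return rows * cols / total


def select_test(table: np.ndarray,
                cutoff: float = EXPECTED_COUNT_CUTOFF) -> str:
    """Choose Fisher when any expected cell count falls below ``cutoff``."""
    try:
        expected = expected_counts(table)
    except ValueError:
        return "fisher_one_sided"  # zero marginal: chi-square undefined
    if (expected < cutoff).any():
        return "fisher_one_sided"
    return "chi_square"


def pearson_chi2(table: np.ndarray, category: str = "") -> ContingencyResult:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    table = np.asarray(table, dtype=float)
    expected = expected_counts(table)  # validates marginals
    statistic = float(((table - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(statistic, df=1))
    return ContingencyResult(category=category, table=table,
                             test_used="chi_square", p_value=p,
                             statistic=statistic)


def fisher_one_sided(table: np.ndarray, category: str = "") -> ContingencyResult:
    """One-sided Fisher exact test on a 2x2 table.

    With rows (reference, category) and columns (group1, group2), the
    alternative is enrichment of the category in group 2: the p-value is the
    hypergeometric tail P(X >= c2) where X is the count in the
    (category, group2) cell at the observed margins, accumulated in log space.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    c2 = table[1, 1]
    total = table.sum()
    category_total = table[1, :].sum()
    group2_total = table[:, 1].sum()
    p = float(sps.hypergeom.sf(c2 - 1, int(round(total)),
                               int(round(category_total)),
                               int(round(group2_total))))
    return ContingencyResult(category=category, table=table,
                             test_used="fisher_one_sided",
                             p_value=min(p, 1.0))


def run_test(table: np.ndarray, category: str = "",
             cutoff: float = EXPECTED_COUNT_CUTOFF) -> ContingencyResult:
    """Apply the expected-count selection rule and run the chosen test."""
    if select_test(table, cutoff) == "chi_square":
        return pearson_chi2(table, category)
    return fisher_one_sided(table, category)


def allele_frequency(wild_hom: int, het: int, mutant_hom: int) -> float:
    """Mutant allele frequency from zygosity counts: (het + 2*hom) / 2N."""
    n = wild_hom + het + mutant_hom
    if n == 0:
        raise ValueError("no callable specimens")
    return (het + 2 * mutant_hom) / (2 * n)


def zygosity_counts(genotypes: Iterable[DiploidGenotype],
                    group_by: str | None = None) -> pd.DataFrame:
    """Per-group, per-locus zygosity counts (wild_hom, het, mutant_hom)."""
    rows = []
    for g in genotypes:
        group = getattr(g, group_by) if group_by else "all"
        for locus in LOCI:
            rows.append({"group": group, "locus": locus,
                         "zygosity": g.locus_calls[locus].zygosity.value})
    if not rows:
        raise ValueError("empty group: no genotypes supplied")
    df = pd.DataFrame(rows)
    counts = (df.groupby(["group", "locus", "zygosity"]).size()
                .unstack(fill_value=0))
    for col in ("wild_hom", "het", "mutant_hom"):
        if col not in counts:
            counts[col] = 0
    return counts[["wild_hom", "het", "mutant_hom"]].reset_index()


def allele_frequencies(genotypes: Iterable[DiploidGenotype],
                       group_by: str | None = None,
                       decimals: int | None = 2) -> pd.DataFrame:
    """Per-group mutant allele frequency at each locus.

    ``decimals`` applies the surveillance reporting convention (2 decimals by
    default); pass None to keep full precision.
    """
    counts = zygosity_counts(genotypes, group_by)
    freq = counts.apply(
        lambda r: allele_frequency(r["wild_hom"], r["het"], r["mutant_hom"]),
        axis=1)
    counts = counts.assign(mutant_allele_freq=freq)
    if decimals is not None:
        counts["mutant_allele_freq"] = counts["mutant_allele_freq"].round(decimals)
    return counts


def compare_categories(counts: pd.DataFrame, reference: str,
                       group_order: Sequence[str] | None = None,
                       cutoff: float = EXPECTED_COUNT_CUTOFF
                       ) -> list[ContingencyResult]:
    """Compare every non-reference category against the reference across
    two groups.

    ``counts`` is a tidy frame with columns ``category``, ``group`` and
    ``count`` covering exactly two groups.  For each category a 2x2 table
    [[ref_g1, ref_g2], [cat_g1, cat_g2]] is built and the selection rule
    applied.  Categories absent from both groups are skipped.  The result
    also carries the between-group change in percentage share
    (``share_change``), the surveillance trend statistic.
    """
    wide = (counts.pivot_table(index="category", columns="group",
                               values="count", aggfunc="sum", fill_value=0))
    groups = list(wide.columns) if group_order is None else list(group_order)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    wide = wide.reindex(columns=groups, fill_value=0)
    if reference not in wide.index:
        raise ValueError(f"reference category {reference!r} absent")
    ref = wide.loc[reference].to_numpy(dtype=float)
    totals = wide.sum(axis=0).to_numpy(dtype=float)
    results = []
    for category, row in wide.iterrows():
        if category == reference:
            continue
        cat = row.to_numpy(dtype=float)
        if cat.sum() == 0:
            continue
        table = np.array([ref, cat])
        res = run_test(table, category=str(category), cutoff=cutoff)
        share = cat / totals * 100
        res.direction = f"{category} enriched in {groups[1]}"
        res.share_change = round(float(share[1] - share[0]), 1)
        results.append(res)
    return results


def survival_rates(counts: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Per-genotype survival percentage from dead/alive counts.

    ``counts`` has columns ``category``, ``dead``, ``alive``; survival is
    alive / (alive + dead) * 100.
    """
    df = counts.copy()
    total = df["dead"] + df["alive"]
    if (total == 0).any():
        raise ValueError("genotype with no dead or alive specimens")
    df["survival_pct"] = (df["alive"] / total * 100).round(decimals)
    return df


def unpaired_t(freqs_a: Sequence[float], freqs_b: Sequence[float]
               ) -> tuple[float, float]:
    """Classical equal-variance unpaired t-test; returns (t, two-sided p).

    Used on per-district allele frequencies between survey rounds.  With
    degenerate (zero pooled variance) input and identical means the test is
    vacuous and p = 1 is returned.
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two units per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(b.mean() - a.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
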