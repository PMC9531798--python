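"""Abbott correction, probit dose–response and LC99, and genotype–phenotype
association for cypermethrin bioassays.

Adult mosquitoes are exposed to a ladder of cypermethrin concentrations
(% w/w active ingredient) with an unexposed control cage, and 24-hour
mortality is recorded.  Observed mortality is corrected for control
mortality with Abbott's formula, a binomial probit regression on log10
concentration is fitted by maximum likelihood (the Finney convention for
insecticide bioassays), and the lethal concentration LC99 is read off the
fitted line: LC99 = 10^((Phi^-1(0.99) - alpha) / beta).

Genotypes are classified as resistance-associated when their dead-vs-alive
contingency test against the wild type is significant and their survival
rate exceeds the wild type's; the proportion of resistance-associated
genotypes in a population unit is then correlated with that unit's LC99.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .stats import ContingencyResult

__all__ = [
    "BioassayRecord",
    "DoseResponseFit",
    "GenotypeClassLabel",
    "DOSE_RANGE_GUIDELINE",
    "CONTROL_MORTALITY_LIMIT",
    "abbott_correct",
    "probit_fit",
    "lethal_concentration",
    "classify_genotypes",
    "correlate_class_proportion",
    "read_bioassay_csv",
]

#: Label-recommended cypermethrin range (% w/w); outside it a warning is
#: attached to the record set, never an error.
DOSE_RANGE_GUIDELINE = (0.01, 0.2)

#: Control mortality above this percentage invalidates an assay (WHO-style).
CONTROL_MORTALITY_LIMIT = 20.0

_Z99 = float(sps.norm.ppf(0.99))


@dataclass(frozen=True)
class BioassayRecord:
    """One cage: a concentration, exposure count and 24 h deaths."""

    population_unit: str
    concentration: float  # % w/w active ingredient; 0 only for control
    n_exposed: int
    n_dead: int
    is_control: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.n_dead <= self.n_exposed):
            raise ValueError("need 0 <= n_dead <= n_exposed")
        if self.concentration < 0:
            raise ValueError("negative concentration")
        if self.concentration == 0 and not self.is_control:
            raise ValueError("zero concentration allowed only for control")

    @property
    def mortality_pct(self) -> float:
        return self.n_dead / self.n_exposed * 100


@dataclass
class DoseResponseFit:
    """Probit model Phi^-1(p) = alpha + beta * log10(concentration)."""

    intercept: float
    slope: float
    lc50: float
    lc99: float
    se_intercept: float
    se_slope: float
    deviance: float
    n_doses: int
    converged: bool
    valid: bool  # False when slope <= 0 or assay invalid
    control_mortality_pct: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class GenotypeClassLabel:
    """Resistance classification of one combined genotype with its evidence."""

    genotype: str
    label: str  # resistance_associated | not_associated | indeterminate
    p_value: float | None = None
    survival_pct: float | None = None
    strong: bool = False  # significant at the stricter tier (default 0.01)


def abbott_correct(observed_pct: float, control_pct: float) -> float:
    """Abbott's formula: (obs - ctrl) / (100 - ctrl) * 100, clamped to [0,100].

    Undefined (raises) at 100% control mortality.
    """
    if not (0 <= observed_pct <= 100 and 0 <= control_pct <= 100):
        raise ValueError("mortalities must be percentages in [0, 100]")
    if control_pct >= 100:
        raise ValueError("Abbott correction undefined at 100% control mortality")
    corrected = (observed_pct - control_pct) / (100 - control_pct) * 100
    return min(max(corrected, 0.0), 100.0)


def _aggregate(records: Sequence[BioassayRecord]
               ) -> tuple[pd.DataFrame, float, list[str]]:
    """Pool cages per concentration; return (dose table, control %, warnings)."""
    warnings: list[str] = []
    controls = [r for r in records if r.is_control]
    doses = [r for r in records if not r.is_control]
    if not doses:
        raise ValueError("no experimental records")
    control_pct = 0.0
    if controls:
        dead = sum(r.n_dead for r in controls)
        exposed = sum(r.n_exposed for r in controls)
        control_pct = dead / exposed * 100
        if control_pct >= CONTROL_MORTALITY_LIMIT:
            warnings.append(
                f"control mortality {control_pct:.1f}% >= "
                f"{CONTROL_MORTALITY_LIMIT:.0f}%: assay invalid")
    lo, hi = DOSE_RANGE_GUIDELINE
    if any(not lo <= r.concentration <= hi for r in doses):
        warnings.append(
            f"concentration outside the {lo}-{hi} % w/w label guideline")
    table = (pd.DataFrame([{"concentration": r.concentration,
                            "n_exposed": r.n_exposed, "n_dead": r.n_dead}
                           for r in doses])
             .groupby("concentration", as_index=False).sum())
    return table, control_pct, warnings


def probit_fit(records: Sequence[BioassayRecord]) -> DoseResponseFit:
    """Fit the probit dose–response for one population unit.

    Cage counts are pooled per concentration, mortality is Abbott-corrected
    against the pooled control, and a binomial GLM with probit link on log10
    concentration is fitted by iteratively reweighted least squares (exact
    MLE).  Requires >= 2 distinct non-control concentrations and
    non-degenerate mortality; an all-0% or all-100% corrected response is
    non-identifiable and raises.  A non-positive fitted slope marks the fit
    invalid rather than raising.
    """
    table, control_pct, warnings = _aggregate(records)
    if len(table) < 2:
        raise ValueError("need >= 2 distinct non-control concentrations")
    corrected = np.array([
        abbott_correct(d / n * 100, control_pct)
        for d, n in zip(table["n_dead"], table["n_exposed"])]) / 100
    if (corrected == 0).all() or (corrected == 1).all():
        raise ValueError(
            "degenerate mortality (all 0% or all 100% after correction): "
            "dose-response non-identifiable")
    logd = np.log10(table["concentration"].to_numpy())
    X = sm.add_constant(logd)
    model = sm.GLM(corrected, X,
                   family=sm.families.Binomial(sm.families.links.Probit()),
                   var_weights=table["n_exposed"].to_numpy(dtype=float))
    res = model.fit()
    alpha, beta = (float(v) for v in res.params)
    se_a, se_b = (float(v) for v in res.bse)
    valid = beta > 0 and not any("invalid" in w for w in warnings)
    if beta <= 0:
        warnings.append(f"non-positive slope {beta:.3f}: fit invalid")
        lc50 = lc99 = float("nan")
    else:
        lc50 = 10 ** (-alpha / beta)
        lc99 = 10 ** ((_Z99 - alpha) / beta)
    return DoseResponseFit(
        intercept=alpha, slope=beta, lc50=lc50, lc99=lc99,
        se_intercept=se_a, se_slope=se_b, deviance=float(res.deviance),
        n_doses=len(table), converged=bool(res.converged), valid=valid,
        control_mortality_pct=control_pct, warnings=warnings)


def lethal_concentration(fit: DoseResponseFit, p: float = 0.99) -> float:
    """LC at an arbitrary kill fraction from a fitted probit line."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if fit.slope <= 0:
        raise ValueError("invalid fit: non-positive slope")
    return 10 ** ((float(sps.norm.ppf(p)) - fit.intercept) / fit.slope)


def classify_genotypes(results: Iterable[ContingencyResult],
                       survival: Mapping[str, float],
                       wild_survival_pct: float = 0.0,
                       alpha: float = 0.05,
                       strong_alpha: float = 0.01,
                       ) -> list[GenotypeClassLabel]:
    """Label genotypes as resistance-associated from dead/alive evidence.

    A genotype is ``resistance_associated`` when its contingency test against
    the wild type gives p < ``alpha`` AND its survival rate exceeds the wild
    type's; tested non-significant genotypes are ``not_associated``.
    Genotypes with survival data but no testable contingency table are
    ``indeterminate``.  ``strong`` marks the stricter ``strong_alpha`` tier.
    """
    tested = {r.category: r for r in results}
    labels = []
    for genotype, surv in survival.items():
        res = tested.get(genotype)
        if res is None:
            labels.append(GenotypeClassLabel(genotype, "indeterminate",
                                             survival_pct=surv))
            continue
        if res.p_value < alpha and surv > wild_survival_pct:
            labels.append(GenotypeClassLabel(
                genotype, "resistance_associated", p_value=res.p_value,
                survival_pct=surv, strong=res.p_value < strong_alpha))
        else:
            labels.append(GenotypeClassLabel(
                genotype, "not_associated", p_value=res.p_value,
                survival_pct=surv))
    return labels


def correlate_class_proportion(proportions: Sequence[float],
                               lc99s: Sequence[float]
                               ) -> tuple[float, float, float]:
    """Pearson correlation of genotype-class proportion vs LC99 across units.

    Returns ``(r, r_squared, two_sided_p)``.  Requires >= 3 units and
    non-degenerate variance in both variables.
    """
    x = np.asarray(proportions, dtype=float)
    y = np.asarray(lc99s, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired units")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(r) ** 2, float(p)


def read_bioassay_csv(handle: TextIO | str | Path) -> list[BioassayRecord]:
    """Read bioassay records from CSV with columns
    unit, concentration_pct, n_exposed, n_dead, is_control."""
    close = False
    if isinstance(handle, (str, Path)):
        handle = open(handle, newline="")
        close = True
    try:
        records = []
        for row in csv.DictReader(handle):
            records.append(BioassayRecord(
                population_unit=row["unit"],
                concentration=float(row["concentration_pct"]),
                n_exposed=int(row["n_exposed"]),
                n_dead=int(row["n_dead"]),
                is_control=str(row.get("is_control", "")).strip().lower()
                in {"1", "true", "yes"}))
        return records
    finally:
        if close:
            handle.close()
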