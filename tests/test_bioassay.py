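"""Abbott correction, probit LC99, classification and correlation."""

import io

import numpy as np
import pytest
from scipy import stats as sps

from kdrsurv import reference_data as ref
from kdrsurv.bioassay import (BioassayRecord, abbott_correct,
                              classify_genotypes, correlate_class_proportion,
                              lethal_concentration, probit_fit,
                              read_bioassay_csv)
from kdrsurv.stats import compare_categories, survival_rates


@pytest.mark.parametrize("observed, control, expected", [
    (95, 0, 95), (50, 20, 37.5), (10, 10, 0), (100, 50, 100), (5, 10, 0)])
def test_abbott_formula(observed, control, expected):
    assert abbott_correct(observed, control) == pytest.approx(expected)


def test_abbott_is_identity_at_zero_control_and_monotone():
    grid = np.linspace(0, 100, 21)
    assert all(abbott_correct(x, 0) == pytest.approx(x) for x in grid)
    for ctrl in (0, 5, 15):
        corrected = [abbott_correct(x, ctrl) for x in grid]
        assert all(b >= a for a, b in zip(corrected, corrected[1:]))


def test_abbott_undefined_at_total_control_mortality():
    with pytest.raises(ValueError):
        abbott_correct(90, 100)


def make_records(alpha, beta, doses, n, rng, unit="u", control=True):
    records = []
    for d in doses:
        p = sps.norm.cdf(alpha + beta * np.log10(d))
        records.append(BioassayRecord(unit, d, n, int(rng.binomial(n, p))))
    if control:
        records.append(BioassayRecord(unit, 0.0, n, 0, is_control=True))
    return records


class TestProbitFit:
    DOSES = (0.01, 0.02, 0.04, 0.08, 0.2)

    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(7)
        alpha, beta = 3.0, 2.0
        fit = probit_fit(make_records(alpha, beta, self.DOSES, 500, rng))
        true_lc99 = 10 ** ((sps.norm.ppf(0.99) - alpha) / beta)
        assert fit.valid and fit.converged
        assert fit.lc99 == pytest.approx(true_lc99, rel=0.10)
        assert fit.slope == pytest.approx(beta, rel=0.2)

    def test_two_point_design_matches_closed_form(self):
        # exact probit-consistent mortalities at two doses determine the
        # line algebraically: beta = (z2-z1)/(log d2 - log d1)
        d1, d2 = 0.02, 0.1
        p1, p2 = 0.3, 0.8
        records = [BioassayRecord("u", d1, 1000, 300),
                   BioassayRecord("u", d2, 1000, 800)]
        fit = probit_fit(records)
        z1, z2 = sps.norm.ppf(p1), sps.norm.ppf(p2)
        beta = (z2 - z1) / (np.log10(d2) - np.log10(d1))
        alpha = z1 - beta * np.log10(d1)
        assert fit.slope == pytest.approx(beta, rel=1e-4)
        assert fit.intercept == pytest.approx(alpha, rel=1e-4)
        assert fit.lc99 == pytest.approx(
            10 ** ((sps.norm.ppf(0.99) - alpha) / beta), rel=1e-3)

    def test_lc_ratio_equivariant_under_unit_rescaling(self):
        rng = np.random.default_rng(11)
        records = make_records(3.0, 2.0, self.DOSES, 400, rng)
        scaled = [BioassayRecord(r.population_unit, r.concentration * 1000,
                                 r.n_exposed, r.n_dead, r.is_control)
                  for r in records]
        fit = probit_fit(records)
        fit_scaled = probit_fit(scaled)
        assert fit_scaled.slope == pytest.approx(fit.slope, rel=1e-6)
        assert fit_scaled.lc99 / fit_scaled.lc50 == pytest.approx(
            fit.lc99 / fit.lc50, rel=1e-6)
        assert fit_scaled.lc99 == pytest.approx(fit.lc99 * 1000, rel=1e-6)

    def test_degenerate_mortality_is_non_identifiable(self):
        all_dead = [BioassayRecord("u", d, 100, 100) for d in self.DOSES]
        with pytest.raises(ValueError):
            probit_fit(all_dead)
        none_dead = [BioassayRecord("u", d, 100, 0) for d in self.DOSES]
        with pytest.raises(ValueError):
            probit_fit(none_dead)

    def test_single_dose_raises(self):
        with pytest.raises(ValueError):
            probit_fit([BioassayRecord("u", 0.05, 100, 50)])

    def test_high_control_mortality_invalidates_assay(self):
        rng = np.random.default_rng(3)
        records = make_records(3.0, 2.0, self.DOSES, 200, rng, control=False)
        records.append(BioassayRecord("u", 0.0, 100, 30, is_control=True))
        fit = probit_fit(records)
        assert not fit.valid
        assert any("invalid" in w for w in fit.warnings)

    def test_lethal_concentration_at_half_kill_is_lc50(self):
        rng = np.random.default_rng(5)
        fit = probit_fit(make_records(3.0, 2.0, self.DOSES, 400, rng))
        assert lethal_concentration(fit, 0.5) == pytest.approx(fit.lc50)


def test_classification_reproduces_published_partition():
    tidy = ref.genotype_counts_frame(ref.BIOASSAY_GENOTYPE_COUNTS,
                                     ref.BIOASSAY_GROUPS)
    results = compare_categories(tidy, ref.WILD_GENOTYPE,
                                 group_order=list(ref.BIOASSAY_GROUPS))
    import pandas as pd
    surv = survival_rates(pd.DataFrame([
        {"category": k, "dead": d, "alive": a}
        for k, (d, a) in ref.BIOASSAY_GENOTYPE_COUNTS.items()]))
    surv_map = dict(zip(surv["category"], surv["survival_pct"]))
    labels = classify_genotypes(
        results, {k: v for k, v in surv_map.items() if k != ref.WILD_GENOTYPE},
        wild_survival_pct=surv_map[ref.WILD_GENOTYPE])
    associated = {l.genotype for l in labels
                  if l.label == "resistance_associated"}
    strong = {l.genotype for l in labels if l.strong}
    assert strong == {"SVCD/SVCD", "PGFD/SVFD", "PGFD/SVCD", "SGFY/SVCD",
                      "PGFD/SGFY", "SGFY/SGFY", "PGFD/PGFD"}
    assert associated == strong | {"SGFD/SVFD"}
    # a genotype seen only among dead specimens can never be associated
    dead_only = next(l for l in labels if l.genotype == "SGFY/SVFD")
    assert dead_only.label == "not_associated"


def test_correlation_limits_and_errors():
    r, r2, p = correlate_class_proportion([0.1, 0.2, 0.4, 0.5],
                                          [1.0, 2.0, 4.0, 5.0])
    assert r2 == pytest.approx(1.0)
    with pytest.raises(ValueError):
        correlate_class_proportion([0.1, 0.1, 0.1], [1, 2, 3])
    with pytest.raises(ValueError):
        correlate_class_proportion([0.1, 0.2], [1, 2])


def test_correlation_recovers_generated_r2():
    rng = np.random.default_rng(9)
    props = rng.uniform(0, 1, size=400)
    lc = 2.0 + 3.0 * props + rng.normal(0, 1.0, size=400)
    # analytic R^2 = var(signal)/var(total) with slope 3, uniform(0,1) x
    expected = (9 / 12) / (9 / 12 + 1.0)
    _, r2, p = correlate_class_proportion(props, lc)
    assert r2 == pytest.approx(expected, abs=0.08)
    assert p < 1e-6


def test_bioassay_csv_reader():
    csv_text = ("unit,concentration_pct,n_exposed,n_dead,is_control\n"
                "tainan,0.05,25,20,0\n"
                "tainan,0,25,1,1\n")
    records = read_bioassay_csv(io.StringIO(csv_text))
    assert records[0].mortality_pct == 80.0
    assert records[1].is_control
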