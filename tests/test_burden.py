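"""Cohort summaries, rate estimation, burden tests, diagnostic yield."""
import numpy as np
import pytest

from triodnm.burden import (
    CohortSummary,
    ControlCohort,
    DNMBurdenModel,
    NullRates,
    diagnostic_yield,
    dnm_rate,
    lof_excess_test,
    per_trio_histogram,
    rate_burden_test,
    summarize_cohort,
)
from triodnm.consequence import ConsequenceClass as C
from triodnm.datasets import load_control_cohorts, load_study_summary
from triodnm.filters import DNMRecord
from triodnm.types import Genotype, GeneTier, SampleCall, VariantSite


def _record(trio_id, cls, gene="G1", tier=GeneTier.UNKNOWN, damaging=False, pos=100):
    return DNMRecord(
        trio_id=trio_id,
        site=VariantSite("chr1", pos, "A", "G"),
        proband_call=SampleCall(Genotype.HET, 30, 15, 15),
        consequence=cls,
        gene=gene,
        gene_tier=tier,
        predicted_damaging=damaging,
    )


def test_study_summary_arithmetic():
    s = load_study_summary()
    assert s.total_dnms == 81
    assert s.coding_snvs == 66
    assert s.lof_snvs == 7
    assert s.avg_dnm_per_trio == pytest.approx(81 / 41)
    assert round(s.avg_dnm_per_trio, 2) == 1.98
    assert round(s.avg_ccds_snv_per_trio, 2) == 1.56  # 64 callable coding SNVs
    assert round(100 * s.missense_fraction) == 73
    assert round(100 * s.lof_snv_fraction) == 11


def test_control_summary_arithmetic():
    controls = {c.name: c.summary for c in load_control_cohorts()}
    trio = controls["trio_controls"]
    assert trio.total_dnms == 40
    assert trio.coding_snvs == 39
    assert trio.lof_snvs == 1
    assert round(trio.avg_dnm_per_trio, 2) == 0.74
    asd = controls["asd_siblings"]
    assert asd.coding_snvs == 441 and asd.lof_snvs == 19
    assert round(asd.avg_dnm_per_trio, 2) == 0.74


def test_summarize_cohort_counts_and_zero_trios():
    records = [
        _record("t1", C.MISSENSE),
        _record("t1", C.NONSENSE),
        _record("t2", C.SYNONYMOUS),
    ]
    s = summarize_cohort(records, n_trios=4, callable_bases=1000)
    assert s.total_dnms == 3
    assert s.class_counts[C.MISSENSE] == 1
    assert sorted(s.per_trio_counts) == [0, 0, 1, 2]
    empty = summarize_cohort([], n_trios=3)
    assert empty.total_dnms == 0 and empty.per_trio_counts == (0, 0, 0)
    with pytest.raises(ValueError):
        summarize_cohort([_record("t1", None)], 1)


def test_dnm_rate():
    assert float(f"{dnm_rate(64, 2_477_702_175):.3g}") == 2.58e-8
    assert dnm_rate(0, 10**8) == 0.0
    assert dnm_rate(1, 10**8) == 1e-8
    with pytest.raises(ValueError):
        dnm_rate(5, 0)


def test_rate_test_at_expectation_is_insignificant():
    n, p0 = 10**6, 5e-5
    s = CohortSummary(
        "x", 10, {C.MISSENSE: int(n * p0)}, callable_bases=n
    )
    res = rate_burden_test(s, NullRates(expected_population_rate=p0))
    assert res.p_value >= 0.5


def test_lof_excess_constructions():
    case = load_study_summary()
    trio_ctrl = next(c for c in load_control_cohorts() if c.name == "trio_controls")
    by_coding = lof_excess_test(case, trio_ctrl)
    assert by_coding.p0 == pytest.approx(1 / 39)
    by_total = lof_excess_test(case, trio_ctrl, denominator="total_dnms")
    assert by_total.p0 == pytest.approx(1 / 40)
    assert by_total.p_value < by_coding.p_value  # smaller null proportion


def test_lof_excess_zero_lof_control_uses_continuity():
    ctrl = ControlCohort("clean", 10, {C.MISSENSE: 20, C.SYNONYMOUS: 10})
    case = load_study_summary()
    res = lof_excess_test(case, ctrl)
    assert res.p0 == pytest.approx(0.5 / 31)
    zero_case = CohortSummary("z", 5, {C.MISSENSE: 10})
    assert lof_excess_test(zero_case, ctrl).p_value == 1.0  # k = 0 under greater


def test_diagnostic_yield_counts_distinct_trios():
    records = [
        _record("t1", C.NONSENSE, gene="A", tier=GeneTier.KNOWN_ID, damaging=True),
        _record("t1", C.MISSENSE, gene="B", tier=GeneTier.KNOWN_ID, damaging=True),
        _record("t2", C.MISSENSE, gene="C", tier=GeneTier.CANDIDATE_ID, damaging=True),
        _record("t3", C.MISSENSE, gene="A", tier=GeneTier.KNOWN_ID, damaging=False),
    ]
    assert diagnostic_yield(records, 10) == pytest.approx(0.1)  # only t1
    assert diagnostic_yield([], 10) == 0.0


def test_per_trio_histogram():
    s = CohortSummary("h", 3, {C.MISSENSE: 4}, per_trio_counts=(1, 1, 2))
    assert per_trio_histogram(s) == {0: 0, 1: 2, 2: 1}
    z = CohortSummary("z", 2, {}, per_trio_counts=(0, 0))
    assert per_trio_histogram(z) == {0: 2}
    many = CohortSummary(
        "m", 41, {C.MISSENSE: 60}, per_trio_counts=tuple([0] * 3 + [2] * 30 + [0] * 8)
    )
    assert per_trio_histogram(many)[0] == 11


def test_model_results_roundtrip():
    model = DNMBurdenModel(load_study_summary(), NullRates(
        control_cohorts=load_control_cohorts()
    ))
    res = model.fit()
    assert res.rate == pytest.approx(64 / 2_477_702_175)
    d = res.as_dict()
    assert d["total_dnms"] == 81
    assert len(d["tests"]) == len(res.rate_tests) + len(res.lof_tests)
    text = res.summary()
    assert "coding SNVs" in text and "LoF excess" in text
    lo, hi = res.rate_confint()
    assert lo < res.rate < hi


def test_type_one_error_near_nominal():
    """Rejection rate of the rate test at alpha=0.05 under the null is ~5%."""
    rng = np.random.default_rng(2026)
    n_callable = 60_400_000 * 41
    p0 = 1.65e-8
    reps = 2500
    ks = rng.binomial(n_callable, p0, size=reps)
    cache: dict[int, float] = {}
    nulls = NullRates(expected_population_rate=p0)
    rejected = 0
    for k in ks:
        k = int(k)
        if k not in cache:
            s = CohortSummary("sim", 41, {C.MISSENSE: k}, callable_bases=n_callable)
            cache[k] = rate_burden_test(s, nulls).p_value
        rejected += cache[k] < 0.05
    rate = rejected / reps
    assert 0.03 <= rate <= 0.07


def test_power_exceeds_type_one_level():
    """At the elevated observed-scale rate the test rejects far more often
    than under the null (reported magnitude, loosely bounded)."""
    rng = np.random.default_rng(7)
    n_callable = 60_400_000 * 41
    nulls = NullRates(expected_population_rate=1.65e-8)
    reps = 400
    cache: dict[int, float] = {}
    rejections = 0
    for k in rng.binomial(n_callable, 2.58e-8, size=reps):
        k = int(k)
        if k not in cache:
            s = CohortSummary("sim", 41, {C.MISSENSE: k}, callable_bases=n_callable)
            cache[k] = rate_burden_test(s, nulls).p_value
        rejections += cache[k] < 0.05
    assert rejections / reps > 0.5


def test_simulated_rate_recovery_within_binomial_ci():
    """Extracted coding-SNV rate over 500 simulated trios brackets the
    planted per-base SNV rate (Clopper-Pearson 95%)."""
    from scipy.stats import beta

    from triodnm.consequence import CODING_SNV_CLASSES
    from triodnm.filters import FilterConfig, extract_dnms
    from triodnm.simulate import SimConfig, simulate_cohort

    cfg = SimConfig(
        n_trios=500,
        mu_dnm=3e-4,
        n_inherited_per_trio=1.0,
        artifact_rate_per_type=0.2,
        mosaic_fraction=0.0,  # germline rate: sub-threshold-VAF events are
        # censored by the caller and would bias any estimator low
        seed=31,
    )
    cohort = simulate_cohort(cfg)
    records = extract_dnms(cohort.all_calls, cohort.annotations, FilterConfig())
    by_chrom: dict[str, list] = {}
    for m in cohort.models:
        by_chrom.setdefault(m.chrom, []).append(m)
    from triodnm.consequence import classify_worst

    k = sum(
        classify_worst(r.site, by_chrom.get(r.site.chrom, ())) in CODING_SNV_CLASSES
        for r in records
    )
    n = cohort.total_callable_bases
    snv_mass = sum(
        p for cls, p in cfg.class_mixture.items() if cls in CODING_SNV_CLASSES
    )
    planted_mu = cfg.mu_dnm * snv_mass
    lo = beta.ppf(0.025, k, n - k + 1)
    hi = beta.ppf(0.975, k + 1, n - k)
    assert lo <= planted_mu <= hi, (k, n, planted_mu, lo, hi)
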