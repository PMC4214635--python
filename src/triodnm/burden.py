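"""Cohort summarisation, per-base DNM rate, and burden tests.

The quantitative questions answered here: does a trio cohort carry more
coding de novo SNVs per callable base than the population expectation, and
is the loss-of-function fraction among those SNVs elevated relative to
control cohorts?  Both are exact binomial comparisons; the model/results
pair below packages them the way regression models are packaged in
statsmodels: build a :class:`DNMBurdenModel` from a cohort summary and null
rates, ``fit()`` it, and read estimates and p-values off the results.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .binomial import BurdenResult, exact_binomial_test
from .consequence import CODING_SNV_CLASSES, ConsequenceClass, is_lof_snv
from .types import GeneTier

# classes whose counts make up "coding SNVs" in summaries; the two
# synonymous flavours are reported under one label
_CLASS_ORDER = (
    ConsequenceClass.MISSENSE,
    ConsequenceClass.SYNONYMOUS,
    ConsequenceClass.NONSENSE,
    ConsequenceClass.CANONICAL_SPLICE,
    ConsequenceClass.CONSENSUS_SPLICE,
    ConsequenceClass.FRAMESHIFT_INSERTION,
    ConsequenceClass.FRAMESHIFT_DELETION,
    ConsequenceClass.INFRAME_INSERTION,
    ConsequenceClass.INFRAME_DELETION,
)


@dataclass(frozen=True)
class CohortSummary:
    """Per-class DNM counts and callable-base totals for one cohort.

    ``ccds_snvs`` is the coding-SNV count restricted to bases inside the
    callable denominator; it defaults to ``coding_snvs`` and only differs
    when a cohort's callable region excludes some confirmed events.
    """

    name: str
    n_trios: int
    class_counts: Mapping[ConsequenceClass, int]
    callable_bases: int = 0
    per_trio_counts: tuple[int, ...] = ()
    ccds_snvs: Optional[int] = None

    def __post_init__(self) -> None:
        if self.per_trio_counts and len(self.per_trio_counts) != self.n_trios:
            raise ValueError("per_trio_counts length must equal n_trios")

    def count(self, cls: ConsequenceClass) -> int:
        return int(self.class_counts.get(cls, 0))

    @property
    def total_dnms(self) -> int:
        return int(sum(self.class_counts.values()))

    @property
    def coding_snvs(self) -> int:
        """Missense + synonymous + nonsense + canonical splice (consensus excluded)."""
        return sum(self.count(c) for c in CODING_SNV_CLASSES)

    @property
    def lof_snvs(self) -> int:
        return sum(self.count(c) for c in self.class_counts if is_lof_snv(c))

    @property
    def avg_dnm_per_trio(self) -> float:
        return self.total_dnms / self.n_trios

    @property
    def avg_coding_snv_per_trio(self) -> float:
        return self.coding_snvs / self.n_trios

    @property
    def ccds_snv_count(self) -> int:
        return self.coding_snvs if self.ccds_snvs is None else self.ccds_snvs

    @property
    def avg_ccds_snv_per_trio(self) -> float:
        return self.ccds_snv_count / self.n_trios

    @property
    def missense_fraction(self) -> float:
        """Fraction of coding SNVs that are missense."""
        return self.count(ConsequenceClass.MISSENSE) / self.coding_snvs

    @property
    def lof_snv_fraction(self) -> float:
        return self.lof_snvs / self.coding_snvs

    def as_table_row(self) -> dict:
        row = {c.value: self.count(c) for c in _CLASS_ORDER}
        row.update(
            name=self.name,
            n_trios=self.n_trios,
            total_dnms=self.total_dnms,
            coding_snvs=self.coding_snvs,
            lof_snvs=self.lof_snvs,
            avg_dnm_per_trio=round(self.avg_dnm_per_trio, 2),
            avg_coding_snv_per_trio=round(self.avg_coding_snv_per_trio, 2),
        )
        return row


@dataclass(frozen=True)
class ControlCohort:
    """A published control cohort's class counts (the null for LoF excess)."""

    name: str
    n_trios: int
    class_counts: Mapping[ConsequenceClass, int]

    @property
    def summary(self) -> CohortSummary:
        return CohortSummary(self.name, self.n_trios, dict(self.class_counts))


@dataclass(frozen=True)
class NullRates:
    """Null mutation rates and control cohorts for the burden comparisons.

    The default expected population rate of 1.65e-8 per base per generation
    is the consensus human germline point-mutation rate; the alternative
    rates are empirical exome-trio estimates from control studies.
    """

    expected_population_rate: float = 1.65e-8
    alternative_rates: tuple[float, ...] = (1.28e-8, 1.51e-8)
    control_cohorts: tuple[ControlCohort, ...] = ()

    def __post_init__(self) -> None:
        if self.expected_population_rate <= 0:
            raise ValueError("rates must be positive")
        if any(r <= 0 for r in self.alternative_rates):
            raise ValueError("rates must be positive")


def summarize_cohort(
    dnms: Sequence, n_trios: int, callable_bases: int = 0, name: str = "cohort"
) -> CohortSummary:
    """Summarise classified DNM records into a :class:`CohortSummary`.

    ``dnms`` are records carrying ``consequence`` and ``trio_id``
    attributes; trios with no DNMs contribute zeros to ``per_trio_counts``.
    """
    counts: dict[ConsequenceClass, int] = {}
    per_trio: dict[str, int] = {}
    for rec in dnms:
        cls = rec.consequence
        if cls is None:
            raise ValueError(f"unclassified DNM record at {rec.site}")
        counts[cls] = counts.get(cls, 0) + 1
        per_trio[rec.trio_id] = per_trio.get(rec.trio_id, 0) + 1
    observed = sorted(per_trio.values(), reverse=True)
    per_trio_counts = tuple(observed + [0] * (n_trios - len(observed)))
    return CohortSummary(
        name=name,
        n_trios=n_trios,
        class_counts=counts,
        callable_bases=callable_bases,
        per_trio_counts=per_trio_counts,
    )


def dnm_rate(snv_count: int, callable_bases: int) -> float:
    """Per-base per-generation de novo SNV rate: count over callable bases."""
    if callable_bases <= 0:
        raise ValueError("callable_bases must be positive")
    return snv_count / callable_bases


def rate_burden_test(
    summary: CohortSummary,
    nulls: NullRates,
    alternative: str = "greater",
    rate: Optional[float] = None,
) -> BurdenResult:
    """Test the cohort's coding de novo SNV count against a null per-base rate."""
    if summary.callable_bases <= 0:
        raise ValueError("summary has no callable_bases")
    p0 = nulls.expected_population_rate if rate is None else rate
    return exact_binomial_test(
        summary.ccds_snv_count,
        summary.callable_bases,
        p0,
        alternative,
        description=f"coding SNV rate vs {p0:.3g}/bp/gen",
    )


def lof_excess_test(
    case: CohortSummary,
    control: ControlCohort,
    alternative: str = "greater",
    denominator: str = "coding_snvs",
) -> BurdenResult:
    """Test for LoF-SNV excess in cases against a control cohort's proportion.

    ``denominator`` picks the control null construction: ``coding_snvs``
    (LoF over control coding SNVs — the construction matching the published
    p-values) or ``total_dnms`` (LoF over all control DNMs, an alternative
    reading when the published denominator is ambiguous).
    """
    ctrl = control.summary
    if denominator == "coding_snvs":
        d = ctrl.coding_snvs
    elif denominator == "total_dnms":
        d = ctrl.total_dnms
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if d <= 0:
        raise ValueError("control cohort has no SNVs")
    lof = ctrl.lof_snvs
    if lof == 0:
        p0 = 0.5 / (d + 1)  # continuity value for zero-LoF controls
    else:
        p0 = lof / d
    return exact_binomial_test(
        case.lof_snvs,
        case.coding_snvs,
        p0,
        alternative,
        description=f"LoF excess vs {control.name} ({lof}/{d})",
    )


def diagnostic_yield(dnms: Sequence, n_trios: int) -> float:
    """Fraction of trios carrying >= 1 predicted-damaging DNM in a known-ID gene.

    A trio with several qualifying DNMs counts once.
    """
    qualifying = {
        rec.trio_id
        for rec in dnms
        if rec.gene_tier is GeneTier.KNOWN_ID and rec.predicted_damaging
    }
    return len(qualifying) / n_trios


# --------------------------------------------------------------------------
# Model / Results interface
# --------------------------------------------------------------------------


@dataclass
class DNMBurdenModel:
    """Exact-binomial burden model for a trio DNM cohort.

    Parameters
    ----------
    summary : CohortSummary
        Observed per-class DNM counts and callable bases.
    nulls : NullRates
        Null population rate(s) and control cohorts.
    dnms : sequence, optional
        Classified DNM records; needed only for the diagnostic yield.
    """

    summary: CohortSummary
    nulls: NullRates = field(default_factory=NullRates)
    dnms: Optional[Sequence] = None

    @classmethod
    def from_records(
        cls,
        dnms: Sequence,
        n_trios: int,
        callable_bases: int,
        nulls: Optional[NullRates] = None,
        name: str = "cohort",
    ) -> "DNMBurdenModel":
        summary = summarize_cohort(dnms, n_trios, callable_bases, name=name)
        return cls(summary, nulls or NullRates(), dnms=dnms)

    def fit(self, alternative: str = "greater") -> "DNMBurdenResults":
        """Run every burden comparison and return a results object."""
        s = self.summary
        rate = (
            dnm_rate(s.ccds_snv_count, s.callable_bases)
            if s.callable_bases > 0
            else float("nan")
        )
        rate_tests = []
        if s.callable_bases > 0:
            for r in (self.nulls.expected_population_rate, *self.nulls.alternative_rates):
                rate_tests.append(
                    rate_burden_test(s, self.nulls, alternative=alternative, rate=r)
                )
                rate_tests.append(
                    rate_burden_test(s, self.nulls, alternative="two_sided_minlik", rate=r)
                )
        lof_tests = []
        for control in self.nulls.control_cohorts:
            lof_tests.append(lof_excess_test(s, control, alternative=alternative))
            by_total = lof_excess_test(
                s, control, alternative=alternative, denominator="total_dnms"
            )
            if by_total.p0 != lof_tests[-1].p0:  # distinct construction only
                lof_tests.append(by_total)
        yield_frac = (
            diagnostic_yield(self.dnms, s.n_trios) if self.dnms is not None else None
        )
        return DNMBurdenResults(
            model=self,
            rate=rate,
            rate_tests=tuple(rate_tests),
            lof_tests=tuple(lof_tests),
            diagnostic_yield=yield_frac,
            alternative=alternative,
        )


@dataclass(frozen=True)
class DNMBurdenResults:
    """Estimates and test outcomes from :meth:`DNMBurdenModel.fit`."""

    model: DNMBurdenModel
    rate: float
    rate_tests: tuple[BurdenResult, ...]
    lof_tests: tuple[BurdenResult, ...]
    diagnostic_yield: Optional[float]
    alternative: str

    @property
    def summary_data(self) -> CohortSummary:
        return self.model.summary

    def rate_confint(self, alpha: float = 0.05) -> tuple[float, float]:
        """Clopper-Pearson interval for the per-base rate."""
        from scipy.stats import beta

        k, n = self.summary_data.ccds_snv_count, self.summary_data.callable_bases
        lo = 0.0 if k == 0 else beta.ppf(alpha / 2, k, n - k + 1)
        hi = 1.0 if k == n else beta.ppf(1 - alpha / 2, k + 1, n - k)
        return float(lo), float(hi)

    def as_dict(self) -> dict:
        s = self.summary_data
        out = {
            "cohort": s.name,
            "n_trios": s.n_trios,
            "total_dnms": s.total_dnms,
            "coding_snvs": s.coding_snvs,
            "lof_snvs": s.lof_snvs,
            "avg_dnm_per_trio": s.avg_dnm_per_trio,
            "rate_per_base_per_generation": self.rate,
            "alternative": self.alternative,
            "tests": [
                {
                    "description": t.description,
                    "alternative": t.alternative,
                    "k": t.k,
                    "n": t.n,
                    "p0": t.p0,
                    "p_value": t.p_value,
                }
                for t in (*self.rate_tests, *self.lof_tests)
            ],
        }
        if self.diagnostic_yield is not None:
            out["diagnostic_yield"] = self.diagnostic_yield
        return out

    def summary(self) -> str:
        """Human-readable table of counts, rate and every test."""
        s = self.summary_data
        lines = [
            f"DNM burden summary — cohort {s.name!r} ({s.n_trios} trios)",
            "=" * 64,
            f"total DNMs            {s.total_dnms:>12d}",
            f"coding SNVs           {s.coding_snvs:>12d}",
            f"LoF SNVs              {s.lof_snvs:>12d}",
            f"DNMs per trio         {s.avg_dnm_per_trio:>12.2f}",
        ]
        if s.callable_bases:
            lines += [
                f"callable bases        {s.callable_bases:>12d}",
                f"SNV rate /bp/gen      {self.rate:>12.3g}",
            ]
        if self.diagnostic_yield is not None:
            lines.append(f"diagnostic yield      {self.diagnostic_yield:>11.1%}")
        lines.append("-" * 64)
        lines.append(f"{'test':<38}{'k':>6}{'p0':>10}{'p':>10}")
        for t in (*self.rate_tests, *self.lof_tests):
            tag = "(2s)" if t.alternative == "two_sided_minlik" else ""
            lines.append(
                f"{(t.description + tag)[:38]:<38}{t.k:>6}{t.p0:>10.3g}{t.p_value:>10.3g}"
            )
        return "\n".join(lines)


def per_trio_histogram(summary: CohortSummary) -> dict[int, int]:
    """Histogram of DNM count per trio; the zero bin is always present."""
    if not summary.per_trio_counts:
        raise ValueError("summary has no per_trio_counts")
    bins: dict[int, int] = {0: 0}
    for c in summary.per_trio_counts:
        bins[c] = bins.get(c, 0) + 1
    return dict(sorted(bins.items()))
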