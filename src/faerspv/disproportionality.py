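"""Four-algorithm disproportionality analysis over 2x2 reporting tables.

A spontaneous-report database is summarised, for one drug set and one
adverse event, by the 2x2 contingency table

    =============  ===============  ================
    .              event of         all other
    .              interest         events
    =============  ===============  ================
    drug set        a                b
    other drugs     c                d
    =============  ===============  ================

with N = a + b + c + d deduplicated reports. Four frequentist /
Bayesian-flavoured statistics are computed from it:

* ROR, the reporting odds ratio (a/b)/(c/d) with a log-normal 95% CI;
* PRR, the proportional reporting ratio (a/(a+b))/(c/(c+d)) with the
  Pearson chi-squared statistic (no continuity correction);
* IC, the BCPNN-family information component log2[a*N/((a+c)(a+b))],
  with a lower bound IC025 = IC * exp(-1.96*s);
* EBGM, the observed/expected reporting ratio a*N/((a+c)(a+b)), with a
  lower bound EBGM05 = exp(ln EBGM - 1.64*s);

where s = sqrt(1/a + 1/b + 1/c + 1/d) throughout. IC and EBGM are the
same observed/expected ratio on log2 and natural scale, so IC ==
log2(EBGM) identically. The IC025/EBGM05 constructions here are simple
normal approximations, not the canonical BCPNN or MGPS posterior
intervals; see docs/methods.md for the divergence and for two known
formula typos in the source tables that are deliberately corrected.

A drug-event pair is declared a signal only when all four algorithms
meet their criteria simultaneously:

    ROR:   CI lower bound > 1 and N >= 2
    PRR:   PRR >= 2 and chi2 >= 4 and N >= 3
    BCPNN: IC025 >= 0
    EBGM:  EBGM05 > 2

(N here is the case count a.) Zero cells are never continuity-corrected:
the affected statistics are returned as 0/inf/nan, recorded in
``SignalResult.undefined``, and the corresponding criteria fail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, NamedTuple

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "contingency_from_counts",
    "compute_ror",
    "compute_prr",
    "compute_ic",
    "compute_ebgm",
    "evaluate_signal",
    "signal_from_table",
    "scan",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching printed-table style."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts of one drug-set x one event 2x2 reporting table."""

    a: int  # target drug & target event
    b: int  # target drug & all other events
    c: int  # other drugs & target event
    d: int  # other drugs & other events

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("empty table: a+b+c+d must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def se_log(self) -> float:
        """sqrt(1/a+1/b+1/c+1/d); inf when any cell is zero."""
        if min(self.a, self.b, self.c, self.d) == 0:
            return math.inf
        return math.sqrt(1 / self.a + 1 / self.b + 1 / self.c + 1 / self.d)


def contingency_from_counts(a: int, drug_total: int, event_total: int, n: int) -> ContingencyTable:
    """Build the 2x2 table from margins: case count ``a``, total reports for
    the drug set, total reports of the event, and total reports ``n``.

    Raises ``ValueError`` naming the inconsistent margin if any derived
    cell would be negative.
    """
    b = drug_total - a
    c = event_total - a
    d = n - drug_total - c
    if b < 0:
        raise ValueError(f"drug_total {drug_total} < a {a} (cell b negative)")
    if c < 0:
        raise ValueError(f"event_total {event_total} < a {a} (cell c negative)")
    if d < 0:
        raise ValueError(
            f"margins exceed database size: drug_total {drug_total} + c {c} > N {n} (cell d negative)"
        )
    return ContingencyTable(a, b, c, d)


class Ror(NamedTuple):
    ror: float
    ci_low: float
    ci_high: float


class Prr(NamedTuple):
    prr: float
    chi2: float


class Ic(NamedTuple):
    ic: float
    ic025: float


class Ebgm(NamedTuple):
    ebgm: float
    ebgm05: float


def compute_ror(t: ContingencyTable) -> Ror:
    """Reporting odds ratio with 95% log-normal CI.

    a == 0 gives ROR 0 with undefined (nan) CI; a zero in b, c or d gives
    an infinite/undefined ROR. No 0.5 continuity correction is applied.
    """
    if t.a == 0:
        return Ror(0.0, math.nan, math.nan)
    if min(t.b, t.c, t.d) == 0:
        if t.b == 0 or (t.c == 0 and t.d > 0):
            return Ror(math.inf, math.nan, math.nan)
        return Ror(math.nan, math.nan, math.nan)
    ror = (t.a * t.d) / (t.b * t.c)
    s = t.se_log
    return Ror(ror, math.exp(math.log(ror) - 1.96 * s), math.exp(math.log(ror) + 1.96 * s))


def compute_prr(t: ContingencyTable) -> Prr:
    """Proportional reporting ratio and uncorrected Pearson chi-squared."""
    drug_tot = t.a + t.b
    comp_tot = t.c + t.d
    if drug_tot == 0 or comp_tot == 0 or t.c == 0:
        prr = math.inf if (t.a > 0 and t.c == 0 and comp_tot > 0) else math.nan
    else:
        prr = (t.a / drug_tot) / (t.c / comp_tot)
    ev_tot = t.a + t.c
    oth_tot = t.b + t.d
    if min(drug_tot, comp_tot, ev_tot, oth_tot) == 0:
        chi2 = math.nan
    else:
        # exact integer numerator; float division only at the end
        chi2 = t.n * (t.a * t.d - t.b * t.c) ** 2 / (drug_tot * comp_tot * ev_tot * oth_tot)
    return Prr(prr, chi2)


def compute_ic(t: ContingencyTable) -> Ic:
    """Information component (bits) and its lower bound.

    IC025 is the multiplicative normal-approximation construction
    IC * exp(-1.96*s), not the BCPNN posterior quantile.
    """
    expected = (t.a + t.c) * (t.a + t.b)
    if t.a == 0 or expected == 0:
        return Ic(math.nan, math.nan)
    ic = math.log2(t.a * t.n / expected)
    s = t.se_log
    ic025 = ic * math.exp(-1.96 * s) if math.isfinite(s) else math.nan
    return Ic(ic, ic025)


def compute_ebgm(t: ContingencyTable) -> Ebgm:
    """Observed/expected reporting ratio and its lower one-sided bound.

    This is the raw relative reporting ratio a*N/((a+c)(a+b)) — no
    empirical-Bayes shrinkage — with EBGM05 = exp(ln EBGM - 1.64*s).
    """
    expected = (t.a + t.c) * (t.a + t.b)
    if t.a == 0 or expected == 0:
        return Ebgm(0.0 if t.a == 0 and expected > 0 else math.nan, math.nan)
    ebgm = t.a * t.n / expected
    s = t.se_log
    ebgm05 = math.exp(math.log(ebgm) - 1.64 * s) if math.isfinite(s) else math.nan
    return Ebgm(ebgm, ebgm05)


@dataclass(frozen=True)
class SignalResult:
    """All four statistics, their bounds, per-algorithm flags and verdict."""

    name: str
    n_reports: int
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    ror_pass: bool
    prr_pass: bool
    bcpnn_pass: bool
    ebgm_pass: bool
    signal: bool
    undefined: frozenset[str] = field(default_factory=frozenset)

    def display_row(self, ndigits: int = 2) -> dict[str, str]:
        """Printed-table style strings: 'ROR (lo, hi)', 'PRR (chi2)', ..."""

        def f(x: float) -> str:
            return "NA" if not math.isfinite(x) else f"{round_half_up(x, ndigits):.{ndigits}f}"

        return {
            "drug": self.name,
            "N": str(self.n_reports),
            "ROR (95% CI)": f"{f(self.ror)} ({f(self.ror_ci_low)}, {f(self.ror_ci_high)})",
            "PRR (chi2)": f"{f(self.prr)} ({f(self.chi2)})",
            "IC (IC025)": f"{f(self.ic)} ({f(self.ic025)})",
            "EBGM (EBGM05)": f"{f(self.ebgm)} ({f(self.ebgm05)})",
            "signal": "yes" if self.signal else "no",
        }


def evaluate_signal(
    *,
    name: str,
    n: int,
    ror: Ror,
    prr: Prr,
    ic: Ic,
    ebgm: Ebgm,
) -> SignalResult:
    """Apply the four criteria and the all-must-pass conjunction.

    nan comparisons are false, so any undefined statistic fails its
    criterion rather than raising.
    """
    ror_pass = bool(ror.ci_low > 1) and n >= 2
    prr_pass = bool(prr.prr >= 2) and bool(prr.chi2 >= 4) and n >= 3
    bcpnn_pass = bool(ic.ic025 >= 0)
    ebgm_pass = bool(ebgm.ebgm05 > 2)
    undefined = frozenset(
        label
        for label, vals in (
            ("ror", ror),
            ("prr", prr),
            ("ic", ic),
            ("ebgm", ebgm),
        )
        if any(isinstance(v, float) and math.isnan(v) for v in vals)
    )
    return SignalResult(
        name=name,
        n_reports=n,
        ror=ror.ror,
        ror_ci_low=ror.ci_low,
        ror_ci_high=ror.ci_high,
        prr=prr.prr,
        chi2=prr.chi2,
        ic=ic.ic,
        ic025=ic.ic025,
        ebgm=ebgm.ebgm,
        ebgm05=ebgm.ebgm05,
        ror_pass=ror_pass,
        prr_pass=prr_pass,
        bcpnn_pass=bcpnn_pass,
        ebgm_pass=ebgm_pass,
        signal=ror_pass and prr_pass and bcpnn_pass and ebgm_pass,
        undefined=undefined,
    )


def signal_from_table(t: ContingencyTable, name: str = "") -> SignalResult:
    """All four statistics plus the signal verdict for one 2x2 table."""
    return evaluate_signal(
        name=name,
        n=t.a,
        ror=compute_ror(t),
        prr=compute_prr(t),
        ic=compute_ic(t),
        ebgm=compute_ebgm(t),
    )


def signal_from_margins(a: int, drug_total: int, event_total: int, n: int, name: str = "") -> SignalResult:
    return signal_from_table(contingency_from_counts(a, drug_total, event_total, n), name=name)


def scan(cohort, class_label: str = "combined") -> list[SignalResult]:
    """One SignalResult per drug set of a screened cohort.

    The pooled class (union of the per-drug sole-primary-suspect sets,
    disjoint by construction) comes first, followed by each drug in
    descending case-count order. Every table shares the cohort's event
    margin and total report count N.
    """
    results: list[SignalResult] = []
    event_total = len(cohort.event_case_ids)
    n = cohort.n_total

    pooled_drug = set().union(*cohort.drug_case_ids.values()) if cohort.drug_case_ids else set()
    pooled_a = len(pooled_drug & cohort.event_case_ids)
    results.append(
        signal_from_table(
            contingency_from_counts(pooled_a, len(pooled_drug), event_total, n), name=class_label
        )
    )
    per_drug = sorted(
        cohort.drug_case_ids,
        key=lambda d: (-len(cohort.drug_event_case_ids[d]), d),
    )
    for drug in per_drug:
        a = len(cohort.drug_event_case_ids[drug])
        results.append(
            signal_from_table(
                contingency_from_counts(a, len(cohort.drug_case_ids[drug]), event_total, n),
                name=drug,
            )
        )
    return results


def results_to_records(results: Iterable[SignalResult], ndigits: int = 2) -> list[dict]:
    """Flat records (full precision + display columns) for one result set."""
    records = []
    for r in results:
        rec: dict = {
            "drug": r.name,
            "N": r.n_reports,
            "ROR": r.ror,
            "ROR_CI_low": r.ror_ci_low,
            "ROR_CI_high": r.ror_ci_high,
            "PRR": r.prr,
            "chi2": r.chi2,
            "IC": r.ic,
            "IC025": r.ic025,
            "EBGM": r.ebgm,
            "EBGM05": r.ebgm05,
            "ror_pass": r.ror_pass,
            "prr_pass": r.prr_pass,
            "bcpnn_pass": r.bcpnn_pass,
            "ebgm_pass": r.ebgm_pass,
            "signal": r.signal,
        }
        disp = r.display_row(ndigits)
        rec["ROR_display"] = disp["ROR (95% CI)"]
        rec["PRR_display"] = disp["PRR (chi2)"]
        rec["IC_display"] = disp["IC (IC025)"]
        rec["EBGM_display"] = disp["EBGM (EBGM05)"]
        records.append(rec)
    return records
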