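"""Disproportionality signal mining: ROR, PRR and the MHRA criterion.

Every distinct drug-event combination (DEC) in the filtered report
database gets a 2x2 contingency table over the whole database:

    a = reports with the suspect drug AND the suspect event
    b = reports with the suspect drug and other events
    c = reports with other drugs and the suspect event
    d = reports with other drugs and other events

(the conventional orientation, under which ROR = ad/bc and
PRR = [a/(a+b)] / [c/(c+d)] are simultaneously consistent).

Signal criteria:

    ROR  — a >= 3 and lower 95% CI bound > 1
    PRR  — a >= 3, PRR >= 2 and lower 95% CI bound > 1
    MHRA — a >= 3 and Yates-corrected chi-square >= 4

Both CIs use the log-scale standard error sqrt(1/a + 1/b + 1/c + 1/d)
by default; the textbook PRR standard error
sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)) is available via ``prr_se``. The
combined signal flag is the intersection of the three criteria by
default (``rule="union"`` switches to any-of). A signal flags a possible
drug-ADR association in the reporting stream, not causation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

from srsafety.frames import as_frame
from srsafety.srs_data import DomainError

Z95 = 1.959963984540054


@dataclass(frozen=True, slots=True)
class ContingencyTable2x2:
    """DEC 2x2 cell counts; a+b+c+d equals the total report count."""

    drug: str
    event: str
    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


class MetricResult(NamedTuple):
    value: float
    ci_low: float
    ci_high: float
    defined: bool


_UNDEFINED = MetricResult(math.nan, math.nan, math.nan, False)


def build_dec_tables(reports) -> list[ContingencyTable2x2]:
    """One 2x2 table per distinct (drug, event) pair in the database.

    Each report contributes exactly one pair; the four cells of every
    table partition the full report set, so a+b+c+d = n for every DEC
    and the a+b / a+c margins equal the per-drug / per-event tallies.
    """
    frame = as_frame(reports)
    counts = frame.groupby(["drug_name", "adr_term"], sort=True
                           ).size()
    drug_totals = frame.groupby("drug_name").size()
    event_totals = frame.groupby("adr_term").size()
    n = len(frame)
    tables = []
    for (drug, event), a in counts.items():
        a = int(a)
        b = int(drug_totals[drug]) - a
        c = int(event_totals[event]) - a
        d = n - a - b - c
        tables.append(ContingencyTable2x2(drug=str(drug), event=str(event),
                                          a=a, b=b, c=c, d=d))
    return tables


def ror(table: ContingencyTable2x2) -> MetricResult:
    """Reporting odds ratio ad/bc with Woolf-style 95% CI.

    Undefined (flagged) when any cell is zero — such a DEC cannot pass
    the criteria in any case.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) <= 0:
        return _UNDEFINED
    value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return MetricResult(value, value * math.exp(-Z95 * se),
                        value * math.exp(Z95 * se), True)


def prr(table: ContingencyTable2x2, se_mode: str = "printed") -> MetricResult:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)] with 95% CI.

    ``se_mode="printed"`` uses sqrt(1/a + 1/b + 1/c + 1/d) on the log
    scale; ``"textbook"`` uses sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)).
    Undefined when a = 0 or c = 0 (log PRR does not exist) or a margin
    is empty.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a <= 0 or c <= 0 or (a + b) <= 0 or (c + d) <= 0:
        return _UNDEFINED
    value = (a / (a + b)) / (c / (c + d))
    if se_mode == "printed":
        if min(b, d) <= 0:
            return _UNDEFINED
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    elif se_mode == "textbook":
        se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    else:
        raise DomainError(f"unknown PRR SE mode {se_mode!r}")
    return MetricResult(value, value * math.exp(-Z95 * se),
                        value * math.exp(Z95 * se), True)


def mhra_chi2(table: ContingencyTable2x2) -> float:
    """Yates continuity-corrected chi-square of the DEC table.

    n * (max(0, |ad - bc| - n/2))^2 / [(a+b)(c+d)(a+c)(b+d)], clamped to
    zero when |ad - bc| <= n/2 so balanced tables never score positive.
    NaN when any margin is zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    num = max(0.0, abs(a * d - b * c) - n / 2.0)
    return n * num * num / denom


@dataclass(slots=True)
class SignalMetrics:
    """All disproportionality metrics and flags for one DEC."""

    drug: str
    event: str
    a: int
    b: int
    c: int
    d: int
    ror: MetricResult
    prr: MetricResult
    chi2_yates: float
    ror_pass: bool
    prr_pass: bool
    mhra_pass: bool
    signal: bool


def evaluate_signal(table: ContingencyTable2x2, rule: str = "intersection",
                    prr_se: str = "printed") -> SignalMetrics:
    """Compute metrics and apply the three signal criteria to one DEC.

    An undefined metric fails its criterion. ``rule`` combines the three
    flags by intersection (default) or union.
    """
    if rule not in ("intersection", "union"):
        raise DomainError(f"unknown combination rule {rule!r}")
    r = ror(table)
    p = prr(table, se_mode=prr_se)
    chi2 = mhra_chi2(table)
    a_ok = table.a >= 3
    ror_pass = a_ok and r.defined and r.ci_low > 1
    prr_pass = a_ok and p.defined and p.value >= 2 and p.ci_low > 1
    mhra_pass = a_ok and not math.isnan(chi2) and chi2 >= 4
    flags = (ror_pass, prr_pass, mhra_pass)
    signal = all(flags) if rule == "intersection" else any(flags)
    return SignalMetrics(drug=table.drug, event=table.event,
                         a=table.a, b=table.b, c=table.c, d=table.d,
                         ror=r, prr=p, chi2_yates=chi2,
                         ror_pass=ror_pass, prr_pass=prr_pass,
                         mhra_pass=mhra_pass, signal=signal)


def rank_signals(metrics: Iterable[SignalMetrics]) -> pd.DataFrame:
    """Signal table: flagged DECs only, ordered by chi-square descending.

    Columns mirror the standard signal-report layout (drug, ADR, ROR and
    its lower CI bound, PRR and its lower bound, chi-square), values
    rounded to two decimals; ordering is independent of input order
    (ties broken by drug then event name).
    """
    rows = [m for m in metrics if m.signal]
    rows.sort(key=lambda m: (-m.chi2_yates, m.drug, m.event))
    return pd.DataFrame([{
        "drug": m.drug,
        "adr": m.event,
        "a": m.a,
        "ror": round(m.ror.value, 2),
        "ror_ci_low": round(m.ror.ci_low, 2),
        "prr": round(m.prr.value, 2),
        "prr_ci_low": round(m.prr.ci_low, 2),
        "chi2": round(m.chi2_yates, 2),
    } for m in rows], columns=["drug", "adr", "a", "ror", "ror_ci_low",
                               "prr", "prr_ci_low", "chi2"])


def compute_signals(reports, rule: str = "intersection",
                    prr_se: str = "printed"
                    ) -> tuple[list[SignalMetrics], pd.DataFrame]:
    """Full signal-mining pass: DEC tables -> metrics -> ranked table."""
    metrics = [evaluate_signal(t, rule=rule, prr_se=prr_se)
               for t in build_dec_tables(reports)]
    return metrics, rank_signals(metrics)
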