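"""Descriptive comparison of mAb vs non-mAb ADR reports.

Cross-tabulations with column percentages (two decimals, half-away-from-
zero, denominated by the full class size so per-table drops of unknown
values do not shift the printed shares), uncorrected Pearson chi-square
and two-sided Fisher exact tests, onset-time distributions per drug
class, and system-organ-class (SOC) tables split by drug class or, within
mAbs, by patent status (branded vs biosimilar).

The chi-square used descriptively is the UNCORRECTED Pearson statistic;
the Yates continuity correction appears only inside the MHRA signal
formula (:mod:`srsafety.disproportionality`). The exact test is reserved
for 2x2 tables; larger tables always use Pearson chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from srsafety.frames import as_frame, derived_column
from srsafety.srs_data import DomainError

logger = logging.getLogger(__name__)

#: Canonical row orders for the standard table blocks.
ROW_ORDERS = {
    "age_group": ["0-5", "6-17", "18-34", "35-59", "60-79", ">=80"],
    "sex": ["female", "male"],
    "year": [2016, 2017, 2018, 2019, 2020],
    "disease_types": ["single", "multiple"],
    "polypharmacy": ["polypharmacy", "non_polypharmacy"],
    "past_adr_history": ["no", "yes"],
    "severity": ["serious", "non_serious"],
    "impact": ["no_effect", "prolong", "worse", "sequelae", "death"],
    "onset_bin": ["same_day", "d1_3", "d4_7", "d8_30", "d_gt30"],
}

DRUG_CLASS_ORDER = ["mab", "non_mab"]
PATENT_ORDER = ["branded", "biosimilar"]


def percent(count: int, total: int) -> float:
    """Percentage 100*count/total, two decimals, half away from zero."""
    if total < 1:
        raise DomainError("total must be >= 1")
    if count < 0 or count > total:
        raise DomainError("count must satisfy 0 <= count <= total")
    q = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(q)


def pearson_chi2_test(table) -> tuple[float, int, float]:
    """Uncorrected Pearson X^2 = sum (O-E)^2/E on an r x c count table.

    Zero-margin rows/columns are dropped (and logged) before testing.
    Returns ``(statistic, df, p)``.
    """
    t = np.asarray(table, dtype=float)
    keep_rows = t.sum(axis=1) > 0
    keep_cols = t.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        logger.info("dropped %d zero-margin rows and %d columns before chi2",
                    (~keep_rows).sum(), (~keep_cols).sum())
        t = t[keep_rows][:, keep_cols]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise DomainError("chi-square needs at least a 2x2 table "
                          "after dropping zero margins")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sided by summation of all margin-preserving tables whose
    hypergeometric probability does not exceed the observed table's.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise DomainError(f"Fisher exact test needs a 2x2 table, got {t.shape}")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def choose_test(table) -> str:
    """``fisher`` iff any expected count < 5 in a 2x2 table, else ``chi2``."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise DomainError(f"choose_test needs a 2x2 table, got {t.shape}")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    return "fisher" if (expected < 5).any() else "chi2"


@dataclass(slots=True)
class CrossTab:
    """Counts, column percentages and the attached test for one block."""

    counts: pd.DataFrame
    col_pct: pd.DataFrame
    test: str           # "chi2", "fisher" or "NE"
    statistic: float
    df: int
    p: float

    @property
    def row_labels(self):
        return list(self.counts.index)

    @property
    def col_labels(self):
        return list(self.counts.columns)


def _attach_test(counts: pd.DataFrame) -> tuple[str, float, int, float]:
    t = counts.to_numpy()
    nz = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if nz.shape[0] < 2 or nz.shape[1] < 2:
        return "NE", float("nan"), 0, float("nan")
    if nz.shape == (2, 2) and choose_test(nz) == "fisher":
        return "fisher", float("nan"), 1, fisher_exact_2x2(nz)
    stat, df, p = pearson_chi2_test(nz)
    return "chi2", stat, df, p


def crosstab(
    reports,
    row_var: str,
    col_var: str,
    row_order: list | None = None,
    col_order: list | None = None,
    denominators: dict | None = None,
) -> CrossTab:
    """Cross-tabulate two report variables with column percentages.

    Reports with a missing/unknown value for either variable are dropped
    from this table only. ``denominators`` overrides the percentage
    denominator per column (by default the column sum); table builders
    pass the full class sizes so percentages match the convention of
    denominating every block by the class total.

    Degenerate tables (fewer than two non-empty rows or columns) are
    produced with the test marked ``NE``.
    """
    frame = as_frame(reports)
    rows = derived_column(frame, row_var)
    cols = derived_column(frame, col_var)
    keep = rows.notna() & cols.notna()
    counts = pd.crosstab(rows[keep], cols[keep])
    counts.index.name = row_var
    counts.columns.name = col_var
    row_order = row_order if row_order is not None else ROW_ORDERS.get(row_var)
    if row_order is not None:
        counts = counts.reindex([r for r in row_order if r in counts.index])
    if col_order is not None:
        counts = counts.reindex(
            columns=[c for c in col_order if c in counts.columns])
    counts = counts.fillna(0).astype(int)
    denom = {c: (denominators or {}).get(c, int(counts[c].sum()))
             for c in counts.columns}
    col_pct = pd.DataFrame(
        {c: [percent(int(v), denom[c]) if denom[c] else float("nan")
             for v in counts[c]] for c in counts.columns},
        index=counts.index)
    test, stat, df, p = _attach_test(counts)
    return CrossTab(counts=counts, col_pct=col_pct, test=test,
                    statistic=stat, df=df, p=p)


def class_sizes(reports, col_var: str = "drug_class") -> dict:
    """Total report count per level of ``col_var`` (unknowns included)."""
    frame = as_frame(reports)
    col = derived_column(frame, col_var)
    return col.value_counts(dropna=True).to_dict()


def mean_age_test(reports) -> dict:
    """Welch two-sample t test of mean age, mAb vs non-mAb.

    Rows with unknown age are dropped; returns per-class mean/SD and the
    test statistic and p-value.
    """
    frame = as_frame(reports)
    ages = frame["age"].astype("Float64")
    keep = ages.notna()
    mab = ages[keep & (frame["drug_class"] == "mab")].astype(float)
    non = ages[keep & (frame["drug_class"] == "non_mab")].astype(float)
    t, p = stats.ttest_ind(mab, non, equal_var=False)
    return {
        "mean_mab": float(mab.mean()), "sd_mab": float(mab.std(ddof=1)),
        "mean_non_mab": float(non.mean()), "sd_non_mab": float(non.std(ddof=1)),
        "t": float(t), "p": float(p),
        "n_dropped": int((~keep).sum()),
    }


def onset_distribution(reports) -> tuple[pd.DataFrame, int]:
    """Onset-bin counts and percentages per drug class.

    Reports with missing onset are dropped from this table; the drop
    count is returned. Percentages are denominated per drug class among
    known-onset reports.
    """
    frame = as_frame(reports)
    known = frame["onset_days"].notna()
    ct = crosstab(frame[known], "onset_bin", "drug_class",
                  col_order=DRUG_CLASS_ORDER)
    out = []
    for b in ct.counts.index:
        row = {"onset_bin": b}
        for c in ct.counts.columns:
            row[f"count_{c}"] = int(ct.counts.loc[b, c])
            row[f"pct_{c}"] = ct.col_pct.loc[b, c]
        out.append(row)
    return pd.DataFrame(out), int((~known).sum())


def soc_table(reports, split_var: str = "drug_class") -> pd.DataFrame:
    """SOC table split by drug class, or by patent status within mAbs.

    One row per SOC present, sorted by total count descending (ties by
    SOC name); per-row 2x2-vs-rest test chosen by :func:`choose_test`;
    rows with a zero cell in either column are marked ``NE``. Percentages
    are denominated by the class sizes.
    """
    if split_var not in ("drug_class", "patent_status"):
        raise DomainError("split_var must be drug_class or patent_status")
    levels = DRUG_CLASS_ORDER if split_var == "drug_class" else PATENT_ORDER
    frame = as_frame(reports)
    frame = frame[frame[split_var].isin(levels)]
    totals = {lv: int((frame[split_var] == lv).sum()) for lv in levels}
    counts = pd.crosstab(frame["soc"], frame[split_var]).reindex(
        columns=levels, fill_value=0)
    order = sorted(counts.index,
                   key=lambda s: (-int(counts.loc[s].sum()), s))
    rows = []
    for soc in order:
        n = [int(counts.loc[soc, lv]) for lv in levels]
        row = {"soc": soc}
        for lv, k in zip(levels, n):
            row[f"count_{lv}"] = k
            row[f"pct_{lv}"] = percent(k, totals[lv])
        if min(n) == 0:
            row.update(test="NE", statistic=float("nan"), p=float("nan"))
        else:
            t22 = np.array([[n[0], n[1]],
                            [totals[levels[0]] - n[0],
                             totals[levels[1]] - n[1]]])
            if choose_test(t22) == "fisher":
                row.update(test="fisher", statistic=float("nan"),
                           p=fisher_exact_2x2(t22))
            else:
                stat, _, p = pearson_chi2_test(t22)
                row.update(test="chi2", statistic=stat, p=p)
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Standard report tables
# --------------------------------------------------------------------------

def demographics_table(reports) -> dict:
    """Demographic/commorbidity blocks by drug class with per-block tests.

    Blocks: age group, sex, reporting year, disease types, polypharmacy,
    past ADR history, plus a Welch t test on mean age. Percentages use
    the full class sizes as denominators.
    """
    sizes = class_sizes(reports)
    blocks = {}
    for var in ("age_group", "sex", "year", "disease_types",
                "polypharmacy", "past_adr_history"):
        blocks[var] = crosstab(reports, var, "drug_class",
                               col_order=DRUG_CLASS_ORDER,
                               denominators=sizes)
    blocks["age_ttest"] = mean_age_test(reports)
    return blocks


def severity_impact_table(reports) -> dict:
    """Severity and impact blocks by drug class (class-size denominators)."""
    sizes = class_sizes(reports)
    return {
        var: crosstab(reports, var, "drug_class",
                      col_order=DRUG_CLASS_ORDER, denominators=sizes)
        for var in ("severity", "impact")
    }
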