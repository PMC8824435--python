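"""Tabular view of report lists and derived analysis variables.

Analysis modules accept either a list of :class:`~srsafety.srs_data.AdrReport`
or a DataFrame already in the canonical schema; :func:`as_frame`
normalizes. Derived variables (age group, polypharmacy, disease types,
onset bin, dichotomized impact) are computed on demand from the raw
columns, with missing inputs propagating to missing outputs so that
per-table drops stay local to each table.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from srsafety.srs_data import (
    AdrReport,
    CSV_COLUMNS,
    age_group,
    bin_onset,
    dichotomize_impact,
    flag_polypharmacy,
)


def reports_to_frame(reports: Sequence[AdrReport]) -> pd.DataFrame:
    """Convert report records to a DataFrame in the canonical schema."""
    data = {}
    for name in CSV_COLUMNS:
        col = [getattr(r, name) for r in reports]
        if name in ("age", "onset_days", "n_diseases", "n_medications"):
            data[name] = pd.array(col, dtype="Int64")
        elif name in ("past_adr_history", "outcome_death"):
            data[name] = np.asarray(col, dtype=bool)
        elif name == "year":
            data[name] = np.asarray(col, dtype=np.int64)
        else:
            data[name] = [str(v) for v in col]
    return pd.DataFrame(data)


def frame_to_reports(frame: pd.DataFrame) -> list[AdrReport]:
    """Inverse of :func:`reports_to_frame`."""
    from srsafety.srs_data import (
        Causality, DrugClass, Impact, MabType, PatentStatus, Severity, Sex,
    )

    def opt(v):
        return None if pd.isna(v) else int(v)

    out = []
    for row in frame.itertuples(index=False):
        out.append(AdrReport(
            report_id=str(row.report_id),
            year=int(row.year),
            age=opt(row.age),
            sex=Sex(row.sex),
            causality=Causality(row.causality),
            drug_name=str(row.drug_name),
            atc_class=str(row.atc_class),
            drug_class=DrugClass(row.drug_class),
            mab_type=MabType(row.mab_type),
            patent_status=PatentStatus(row.patent_status),
            adr_term=str(row.adr_term),
            soc=str(row.soc),
            onset_days=opt(row.onset_days),
            severity=Severity(row.severity),
            impact=Impact(row.impact),
            n_diseases=opt(row.n_diseases),
            n_medications=opt(row.n_medications),
            past_adr_history=bool(row.past_adr_history),
            outcome_death=bool(row.outcome_death),
        ))
    return out


def as_frame(reports) -> pd.DataFrame:
    """Accept a report list or a canonical-schema DataFrame."""
    if isinstance(reports, pd.DataFrame):
        return reports
    return reports_to_frame(list(reports))


def derived_column(frame: pd.DataFrame, name: str) -> pd.Series:
    """Return an analysis variable, derived if not a raw column.

    Missing or unknown inputs yield NA so each table can drop them
    locally. ``sex`` treats the ``unknown`` level as missing.
    """
    if name == "age_group":
        return frame["age"].map(lambda a: pd.NA if pd.isna(a)
                                else age_group(int(a)))
    if name == "polypharmacy":
        return frame["n_medications"].map(
            lambda n: pd.NA if pd.isna(n)
            else ("polypharmacy" if flag_polypharmacy(int(n))
                  else "non_polypharmacy"))
    if name == "disease_types":
        return frame["n_diseases"].map(
            lambda n: pd.NA if pd.isna(n)
            else ("single" if int(n) == 1 else "multiple"))
    if name == "past_adr_history":
        return frame["past_adr_history"].map({True: "yes", False: "no"})
    if name == "impact_effect":
        return frame["impact"].map(dichotomize_impact)
    if name == "onset_bin":
        return frame["onset_days"].map(
            lambda d: pd.NA if pd.isna(d) else bin_onset(int(d)).value)
    if name == "sex":
        return frame["sex"].replace("unknown", pd.NA)
    if name in frame.columns:
        col = frame[name]
        return col.astype(str) if col.dtype == object else col
    raise KeyError(f"unknown analysis variable {name!r}")
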