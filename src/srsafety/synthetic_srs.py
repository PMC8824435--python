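"""Synthetic spontaneous-reporting-system (SRS) databases.

Two sources of data:

* :func:`generate_reports` draws reports from a configurable generative
  model — categorical marginals for year/sex/age group/drug/event,
  class-dependent onset-time distributions, logistic outcome models for
  severity and impact, and *planted* drug-event combinations (DECs)
  whose event reporting rate is multiplied by a specified ratio under
  the suspect drug. Identical config + seed reproduces the identical
  table; a single seeded generator is consumed in a documented field
  order so added fields append draws rather than reshuffling existing
  ones.

* :func:`reference_fixture` builds a deterministic table of 15,910
  reports whose marginal counts exactly reproduce those published for a
  2016-2020 provincial SRS comparison of monoclonal-antibody vs
  traditional anticancer drugs (age group, sex, year, disease types,
  polypharmacy, past ADR history, SOC by drug class and — within mAbs —
  by patent status, severity, impact, and the anchored onset-bin
  counts). Joint structure beyond those margins is arbitrary but fixed:
  each field's block assignment is spread over the class's rows with a
  field-specific stride coprime to the class size, which decorrelates
  fields without randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from srsafety.frames import frame_to_reports
from srsafety.srs_data import AdrReport, DomainError
from srsafety.terminology import SOC_TERMS


class ConfigError(ValueError):
    """Invalid simulation configuration; the message lists violations."""


# ==========================================================================
# Reference marginal counts (provincial SRS, anticancer drugs, 2016-2020)
# ==========================================================================

MAB_N = 575
NONMAB_N = 15_335
TOTAL_N = MAB_N + NONMAB_N

AGE_COUNTS = {
    "mab": {"0-5": 3, "6-17": 4, "18-34": 26, "35-59": 265, "60-79": 254,
            ">=80": 23},
    "non_mab": {"0-5": 193, "6-17": 231, "18-34": 422, "35-59": 6685,
                "60-79": 7452, ">=80": 308, None: 44},
}
SEX_COUNTS = {
    "mab": {"female": 328, "male": 247},
    "non_mab": {"female": 8363, "male": 6959, "unknown": 13},
}
YEAR_COUNTS = {
    "mab": {2016: 6, 2017: 19, 2018: 33, 2019: 140, 2020: 377},
    "non_mab": {2016: 1398, 2017: 1834, 2018: 2455, 2019: 3865, 2020: 5783},
}
DISEASE_COUNTS = {
    "mab": {"single": 508, "multiple": 67},
    "non_mab": {"single": 13_539, "multiple": 1796},
}
POLY_COUNTS = {
    "mab": {"polypharmacy": 37, "non_polypharmacy": 538},
    "non_mab": {"polypharmacy": 940, "non_polypharmacy": 14_395},
}
HISTORY_COUNTS = {
    "mab": {"no": 549, "yes": 26},
    "non_mab": {"no": 14_279, "yes": 1056},
}
SEVERITY_COUNTS = {
    "mab": {"serious": 174, "non_serious": 401},
    "non_mab": {"serious": 5285, "non_serious": 10_050},
}
IMPACT_COUNTS = {
    "mab": {"no_effect": 506, "prolong": 10, "worse": 58, "sequelae": 1,
            "death": 0},
    "non_mab": {"no_effect": 12_754, "prolong": 123, "worse": 2441,
                "sequelae": 13, "death": 4},
}
#: Onset-bin counts; only mAb same-day (297) and non-mAb 1-3 d (4,929) are
#: anchored by the source margins. The remaining non-mAb bins are chosen so
#: same-day + 1-3 d + 4-7 d = 13,056 of 15,329 known = 85.17% within one
#: week; 6 non-mAb reports carry missing onset (15,910 - 15,904 known).
ONSET_COUNTS = {
    "mab": {"same_day": 297, "d1_3": 150, "d4_7": 60, "d8_30": 45,
            "d_gt30": 23},
    "non_mab": {"same_day": 4100, "d1_3": 4929, "d4_7": 4027, "d8_30": 1500,
                "d_gt30": 773, None: 6},
}
#: Within mAbs: SOC x patent status (branded, biosimilar). Row sums equal
#: the SOC-by-drug-class mAb column; column sums are 495 and 80.
SOC_PATENT_COUNTS: tuple[tuple[str, int, int], ...] = (
    ("General disorders and administration site conditions", 122, 20),
    ("Skin and subcutaneous tissue disorders", 75, 12),
    ("Gastrointestinal disorders", 74, 7),
    ("Blood and lymphatic system disorders", 41, 9),
    ("Respiratory, thoracic, and mediastinal disorders", 38, 12),
    ("Cardiac disorders", 23, 5),
    ("Vascular disorders", 19, 3),
    ("Investigations", 17, 3),
    ("Endocrine disorders", 18, 1),
    ("Nervous system disorders", 15, 3),
    ("Immune system disorders", 12, 2),
    ("Hepatobiliary disorders", 11, 1),
    ("Neoplasms benign, malignant, and unspecified (including cysts and polyps)",
     11, 0),
    ("Renal and urinary disorders", 6, 2),
    ("Metabolism and nutrition disorders", 5, 0),
    ("Musculoskeletal and connective tissue disorders", 5, 0),
    ("Injury, poisoning, and procedural complications", 3, 0),
)
SOC_NONMAB_COUNTS: dict[str, int] = {
    "Gastrointestinal disorders": 5762,
    "Blood and lymphatic system disorders": 3559,
    "Skin and subcutaneous tissue disorders": 1263,
    "Investigations": 1158,
    "General disorders and administration site conditions": 833,
    "Nervous system disorders": 616,
    "Respiratory, thoracic, and mediastinal disorders": 578,
    "Vascular disorders": 264,
    "Musculoskeletal and connective tissue disorders": 276,
    "Cardiac disorders": 249,
    "Hepatobiliary disorders": 251,
    "Metabolism and nutrition disorders": 204,
    "Immune system disorders": 166,
    "Renal and urinary disorders": 72,
    "Endocrine disorders": 17,
    "Psychiatric disorders": 20,
    "Eye disorders": 16,
    "Injury, poisoning, and procedural complications": 10,
    "Neoplasms benign, malignant, and unspecified (including cysts and polyps)": 1,
    "Ear and labyrinth disorders": 10,
    "Infections and infestations": 6,
    "Reproductive system and breast disorders": 4,
}
#: mAb drug-name marginal (name, antibody type, report count).
MAB_DRUG_COUNTS: tuple[tuple[str, str, int], ...] = (
    ("Rituximab", "chimeric", 130),
    ("Cetuximab", "chimeric", 38),
    ("Trastuzumab", "humanized", 171),
    ("Bevacizumab", "humanized", 77),
    ("Camrelizumab", "humanized", 60),
    ("Toripalimab", "humanized", 15),
    ("Pembrolizumab", "humanized", 10),
    ("Pertuzumab", "humanized", 9),
    ("Nimotuzumab", "humanized", 7),
    ("Tislelizumab", "humanized", 2),
    ("Atezolizumab", "humanized", 1),
    ("Tocilizumab", "humanized", 1),
    ("Sintilimab", "fully_human", 48),
    ("Evolocumab", "fully_human", 3),
    ("Nivolumab", "fully_human", 2),
    ("Adalimumab", "fully_human", 1),
)
NONMAB_DRUGS: tuple[str, ...] = (
    "Cisplatin", "Carboplatin", "Oxaliplatin", "Paclitaxel", "Docetaxel",
    "Fluorouracil", "Gemcitabine", "Doxorubicin", "Cyclophosphamide",
    "Etoposide", "Gefitinib", "Capecitabine",
)

#: Integer day ranges represented by each onset bin (inclusive).
ONSET_BIN_DAYS = {
    "same_day": (0, 0), "d1_3": (1, 3), "d4_7": (4, 7), "d8_30": (8, 30),
    "d_gt30": (31, 120),
}


# ==========================================================================
# Deterministic fixture
# ==========================================================================

def _spread(blocks: Sequence[tuple], n: int, stride: int) -> list:
    """Lay out value blocks over ``n`` slots with a coprime stride.

    ``out[(j * stride) % n] = value_j`` is a bijection when
    gcd(stride, n) = 1, giving a fixed, randomness-free interleaving of
    the blocks so different fields are decorrelated.
    """
    if math.gcd(stride, n) != 1:
        raise ValueError(f"stride {stride} not coprime to {n}")
    seq = [v for v, count in blocks for _ in range(count)]
    if len(seq) != n:
        raise ValueError(f"blocks sum to {len(seq)}, expected {n}")
    out = [None] * n
    for j, v in enumerate(seq):
        out[(j * stride) % n] = v
    return out


# Strides are fixed per field and coprime to both class sizes
# (575 = 5^2 * 23 and 15,335 = 5 * 3067).
_STRIDES = {"sex": 3, "age": 7, "year": 11, "disease": 13, "poly": 17,
            "history": 19, "severity": 29, "impact": 31, "onset": 37,
            "drug": 41}


def _fixture_class(drug_class: str, n: int) -> dict[str, list]:
    """All column lists for one drug class of the fixture."""
    cols: dict[str, list] = {}

    def spread(counts: dict, key: str) -> list:
        return _spread(list(counts.items()), n, _STRIDES[key])

    cols["sex"] = spread(SEX_COUNTS[drug_class], "sex")
    cols["year"] = spread(YEAR_COUNTS[drug_class], "year")
    cols["disease_types"] = spread(DISEASE_COUNTS[drug_class], "disease")
    cols["polypharmacy"] = spread(POLY_COUNTS[drug_class], "poly")
    cols["past_adr_history"] = spread(HISTORY_COUNTS[drug_class], "history")
    cols["severity"] = spread(SEVERITY_COUNTS[drug_class], "severity")
    cols["impact"] = spread(IMPACT_COUNTS[drug_class], "impact")

    # concrete ages cycle within each group so group margins are exact
    group_spans = {"0-5": (0, 6), "6-17": (6, 12), "18-34": (18, 17),
                   "35-59": (35, 25), "60-79": (60, 20), ">=80": (80, 20)}
    group_seq = _spread(list(AGE_COUNTS[drug_class].items()), n,
                        _STRIDES["age"])
    seen: dict[str, int] = {}
    ages = []
    for g in group_seq:
        if g is None:
            ages.append(None)
            continue
        k = seen.get(g, 0)
        seen[g] = k + 1
        lo, span = group_spans[g]
        ages.append(lo + k % span)
    cols["age"] = ages

    # onset: bin -> representative cycling day within the bin's range
    bin_seq = _spread(list(ONSET_COUNTS[drug_class].items()), n,
                      _STRIDES["onset"])
    seen = {}
    onset = []
    for b in bin_seq:
        if b is None:
            onset.append(None)
            continue
        k = seen.get(b, 0)
        seen[b] = k + 1
        lo, hi = ONSET_BIN_DAYS[b]
        onset.append(lo + k % (hi - lo + 1))
    cols["onset_days"] = onset

    if drug_class == "mab":
        soc_patent = [((soc, "branded"), nb) for soc, nb, _ in SOC_PATENT_COUNTS]
        soc_patent += [((soc, "biosimilar"), ns)
                       for soc, _, ns in SOC_PATENT_COUNTS if ns > 0]
        pairs = _spread(soc_patent, n, 1)
        cols["soc"] = [p[0] for p in pairs]
        cols["patent_status"] = [p[1] for p in pairs]
        drug_blocks = [((name, mt), c) for name, mt, c in MAB_DRUG_COUNTS]
        dm = _spread(drug_blocks, n, _STRIDES["drug"])
        cols["drug_name"] = [x[0] for x in dm]
        cols["mab_type"] = [x[1] for x in dm]
    else:
        cols["soc"] = _spread(list(SOC_NONMAB_COUNTS.items()), n, 1)
        cols["patent_status"] = ["none"] * n
        cols["drug_name"] = [NONMAB_DRUGS[j % len(NONMAB_DRUGS)]
                             for j in range(n)]
        cols["mab_type"] = ["none"] * n

    # preferred term cycles through the SOC's term list per occurrence
    seen = {}
    terms = []
    for soc in cols["soc"]:
        k = seen.get(soc, 0)
        seen[soc] = k + 1
        opts = SOC_TERMS[soc]
        terms.append(opts[k % len(opts)])
    cols["adr_term"] = terms
    cols["causality"] = [("probable", "possible", "certain")[j % 3]
                         for j in range(n)]
    cols["drug_class"] = [drug_class] * n
    return cols


def reference_fixture() -> list[AdrReport]:
    """Deterministic 15,910-report table matching the reference margins.

    Marginal counts per drug class (and, within mAbs, per patent status)
    reproduce the published table cells exactly; joint structure beyond
    those constraints is arbitrary but byte-stable across calls.
    """
    reports: list[AdrReport] = []
    idx = 0
    for drug_class, n in (("mab", MAB_N), ("non_mab", NONMAB_N)):
        cols = _fixture_class(drug_class, n)
        for j in range(n):
            impact = cols["impact"][j]
            reports.append(AdrReport(
                report_id=f"FX{idx:05d}",
                year=cols["year"][j],
                age=cols["age"][j],
                sex=cols["sex"][j],
                causality=cols["causality"][j],
                drug_name=cols["drug_name"][j],
                atc_class="L01",
                drug_class=drug_class,
                mab_type=cols["mab_type"][j],
                patent_status=cols["patent_status"][j],
                adr_term=cols["adr_term"][j],
                soc=cols["soc"][j],
                onset_days=cols["onset_days"][j],
                severity=cols["severity"][j],
                impact=impact,
                n_diseases=1 if cols["disease_types"][j] == "single"
                else 2 + j % 3,
                n_medications=5 + j % 4
                if cols["polypharmacy"][j] == "polypharmacy" else 1 + j % 4,
                past_adr_history=cols["past_adr_history"][j] == "yes",
                outcome_death=impact == "death",
            ))
            idx += 1
    return reports


#: Spec-facing alias.
paper_fixture = reference_fixture


# ==========================================================================
# Generative model
# ==========================================================================

@dataclass(slots=True)
class DrugSpec:
    name: str
    drug_class: str            # "mab" or "non_mab"
    mab_type: str = "none"
    patent_status: str = "none"
    weight: float = 1.0        # within-class sampling weight


@dataclass(slots=True)
class EventSpec:
    term: str
    soc: str
    baseline: float            # baseline reporting probability


@dataclass(slots=True)
class PlantedDec:
    drug: str
    event: str
    rate_ratio: float          # reporting-rate multiplier under the drug


@dataclass(slots=True)
class SimulationConfig:
    """Full generative specification of a synthetic SRS database.

    Outcome models are logistic: log-odds = intercept + coefficients on
    the report covariates (mab, female, polypharmacy, multiple_disease,
    past_adr); severity draws P(serious), impact draws P(effect) which
    is then split over prolong/worse/sequelae/death by
    ``effect_split``.
    """

    n_reports: int = TOTAL_N
    seed: int = 0
    year_probs: dict = field(default_factory=dict)
    sex_probs: dict = field(default_factory=dict)
    age_group_probs: dict = field(default_factory=dict)
    drug_class_probs: dict = field(default_factory=dict)
    causality_probs: dict = field(default_factory=dict)
    drugs: list = field(default_factory=list)
    events: list = field(default_factory=list)
    planted_decs: list = field(default_factory=list)
    onset_bin_probs: dict = field(default_factory=dict)
    p_missing_onset: float = 0.0
    polypharmacy_p: float = 0.06
    multiple_disease_p: float = 0.12
    past_adr_p: float = 0.07
    severity_model: dict = field(default_factory=dict)
    impact_model: dict = field(default_factory=dict)
    effect_split: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Raise :class:`ConfigError` listing every violation found."""
        problems: list[str] = []
        if self.n_reports < 0:
            problems.append("n_reports must be >= 0")
        for name in ("year_probs", "sex_probs", "age_group_probs",
                     "drug_class_probs", "causality_probs", "effect_split"):
            probs = getattr(self, name)
            if probs and abs(sum(probs.values()) - 1.0) > 1e-9:
                problems.append(f"{name} must sum to 1")
        for cls, probs in self.onset_bin_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                problems.append(f"onset_bin_probs[{cls}] must sum to 1")
        if not self.drugs:
            problems.append("drug catalog is empty")
        if not self.events:
            problems.append("event catalog is empty")
        if any(d.weight <= 0 for d in self.drugs):
            problems.append("drug weights must be > 0")
        if any(e.baseline <= 0 for e in self.events):
            problems.append("event baselines must be > 0")
        drug_names = {d.name for d in self.drugs}
        event_names = {e.term for e in self.events}
        for dec in self.planted_decs:
            if dec.rate_ratio <= 0:
                problems.append(f"rate_ratio must be > 0 for {dec.drug}")
            if dec.drug not in drug_names:
                problems.append(f"planted DEC drug {dec.drug!r} not in catalog")
            if dec.event not in event_names:
                problems.append(f"planted DEC event {dec.event!r} not in catalog")
        if problems:
            raise ConfigError("; ".join(problems))


def default_config(n_reports: int = TOTAL_N, seed: int = 0
                   ) -> SimulationConfig:
    """Generator defaults emulating the reference study's margins."""
    def norm(counts: dict) -> dict:
        known = {k: v for k, v in counts.items() if k is not None}
        tot = sum(known.values())
        return {k: v / tot for k, v in known.items()}

    def merge(per_class: dict) -> dict:
        out: dict = {}
        for counts in per_class.values():
            for k, v in counts.items():
                if k is not None:
                    out[k] = out.get(k, 0) + v
        return norm(out)

    drugs = [DrugSpec(n, "mab", mt, "branded", float(c))
             for n, mt, c in MAB_DRUG_COUNTS]
    # biosimilar share (80 of 575) carried by the three widely copied mAbs
    biosim = {"Rituximab": 40.0, "Trastuzumab": 25.0, "Bevacizumab": 15.0}
    for d in drugs:
        if d.name in biosim:
            d.weight -= biosim[d.name]
    drugs += [DrugSpec(n, "mab", t, "biosimilar", w)
              for (n, t), w in zip(
                  [("Rituximab", "chimeric"), ("Trastuzumab", "humanized"),
                   ("Bevacizumab", "humanized")], biosim.values())]
    nonmab_weights = (2000, 1500, 1800, 2200, 1700, 1400, 1300, 900, 800,
                      700, 600, 435)
    drugs += [DrugSpec(n, "non_mab", weight=float(w))
              for n, w in zip(NONMAB_DRUGS, nonmab_weights)]

    soc_totals = {soc: SOC_NONMAB_COUNTS[soc] for soc in SOC_NONMAB_COUNTS}
    for soc, nb, ns in SOC_PATENT_COUNTS:
        soc_totals[soc] += nb + ns
    grand = sum(soc_totals.values())
    events = []
    for soc, terms in SOC_TERMS.items():
        share = soc_totals.get(soc, 0) / grand
        for term in terms:
            events.append(EventSpec(term, soc, share / len(terms)))

    return SimulationConfig(
        n_reports=n_reports,
        seed=seed,
        year_probs=merge(YEAR_COUNTS),
        sex_probs=merge(SEX_COUNTS),
        age_group_probs=merge(AGE_COUNTS),
        drug_class_probs=norm({"mab": MAB_N, "non_mab": NONMAB_N}),
        causality_probs={"probable": 0.6, "possible": 0.3, "certain": 0.1},
        drugs=drugs,
        events=events,
        planted_decs=[],
        onset_bin_probs={cls: norm(c) for cls, c in ONSET_COUNTS.items()},
        p_missing_onset=6 / TOTAL_N,
        polypharmacy_p=977 / TOTAL_N,
        multiple_disease_p=1863 / TOTAL_N,
        past_adr_p=1082 / TOTAL_N,
        severity_model={"intercept": -0.62, "mab": -0.213, "female": -0.237,
                        "polypharmacy": -0.859, "multiple_disease": 0.175,
                        "past_adr": 0.587},
        impact_model={"intercept": -1.55, "mab": -0.418, "female": -0.158,
                      "polypharmacy": -1.166, "multiple_disease": 0.239,
                      "past_adr": 0.587},
        effect_split={"prolong": 133 / 2650, "worse": 2499 / 2650,
                      "sequelae": 14 / 2650, "death": 4 / 2650},
    )


def _event_probs(config: SimulationConfig, drug: str) -> np.ndarray:
    """Per-event reporting probabilities under one drug (renormalized)."""
    base = np.array([e.baseline for e in config.events], dtype=float)
    base = base / base.sum()
    idx = {e.term: i for i, e in enumerate(config.events)}
    for dec in config.planted_decs:
        if dec.drug == drug:
            base[idx[dec.event]] *= dec.rate_ratio
    return base / base.sum()


def expected_cells(config: SimulationConfig, drug: str, event: str) -> dict:
    """Analytic expectations of the DEC 2x2 cells under the model.

    Serves as an independent oracle for planted-signal tests:
    E[a] = n * P(drug) * P(event | drug), etc.
    """
    class_w: dict[str, float] = {}
    for d in config.drugs:
        class_w[d.drug_class] = class_w.get(d.drug_class, 0.0) + d.weight
    p_drug_entry = {}
    for d in config.drugs:
        p = config.drug_class_probs.get(d.drug_class, 0.0) * (
            d.weight / class_w[d.drug_class])
        p_drug_entry[d.name] = p_drug_entry.get(d.name, 0.0) + p
    idx = {e.term: i for i, e in enumerate(config.events)}
    j = idx[event]
    p_a = p_drug_entry[drug] * _event_probs(config, drug)[j]
    p_event = sum(p * _event_probs(config, name)[j]
                  for name, p in p_drug_entry.items())
    n = config.n_reports
    pa, pb = p_a, p_drug_entry[drug] - p_a
    pc = p_event - p_a
    return {"a": n * pa, "b": n * pb, "c": n * pc,
            "d": n * (1 - pa - pb - pc)}


def _draw_cat(rng: np.random.Generator, labels: list, probs: np.ndarray,
              n: int) -> np.ndarray:
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    u = rng.random(n)
    return np.searchsorted(cdf, u, side="right").clip(0, len(labels) - 1)


def generate_frame(config: SimulationConfig) -> pd.DataFrame:
    """Draw a synthetic report table (canonical schema) from the model.

    Field draw order (fixed; appending fields appends draws): year, sex,
    age group, age-within-group, causality, drug, event, onset bin,
    onset day, onset missingness, disease count, polypharmacy,
    medication count, past ADR history, severity, impact, effect split.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    def cat(probs: dict) -> list:
        labels = list(probs.keys())
        p = np.array(list(probs.values()), dtype=float)
        return [labels[i] for i in _draw_cat(rng, labels, p / p.sum(), n)]

    year = np.array(cat(config.year_probs), dtype=np.int64)
    sex = cat(config.sex_probs)
    age_group_lbl = cat(config.age_group_probs)
    group_spans = {"0-5": (0, 6), "6-17": (6, 12), "18-34": (18, 17),
                   "35-59": (35, 25), "60-79": (60, 20), ">=80": (80, 20)}
    u_age = rng.random(n)
    age = np.array([group_spans[g][0] + int(u * group_spans[g][1])
                    for g, u in zip(age_group_lbl, u_age)], dtype=np.int64)
    causality = cat(config.causality_probs)

    # drug: flatten class prob x within-class weight over catalog entries
    class_w: dict[str, float] = {}
    for d in config.drugs:
        class_w[d.drug_class] = class_w.get(d.drug_class, 0.0) + d.weight
    p_entries = np.array([
        config.drug_class_probs.get(d.drug_class, 0.0)
        * d.weight / class_w[d.drug_class] for d in config.drugs])
    drug_idx = _draw_cat(rng, list(range(len(config.drugs))),
                         p_entries / p_entries.sum(), n)
    specs = config.drugs

    # event: per-drug CDF (planted DECs tilt the suspect drug's vector)
    u_event = rng.random(n)
    event_idx = np.empty(n, dtype=np.int64)
    cdf_cache: dict[str, np.ndarray] = {}
    for k in np.unique(drug_idx):
        name = specs[int(k)].name
        if name not in cdf_cache:
            cdf = np.cumsum(_event_probs(config, name))
            cdf[-1] = 1.0
            cdf_cache[name] = cdf
        mask = drug_idx == k
        event_idx[mask] = np.searchsorted(cdf_cache[name], u_event[mask],
                                          side="right")
    terms = [config.events[int(i)].term for i in event_idx]
    socs = [config.events[int(i)].soc for i in event_idx]

    # onset: class-specific bin, uniform integer day within the bin
    drug_class = np.array([specs[int(k)].drug_class for k in drug_idx])
    u_bin = rng.random(n)
    u_day = rng.random(n)
    missing_onset = rng.random(n) < config.p_missing_onset
    onset = np.zeros(n, dtype=float)
    for cls, probs in config.onset_bin_probs.items():
        labels = list(probs.keys())
        cdf = np.cumsum(np.array(list(probs.values()), dtype=float))
        cdf[-1] = 1.0
        mask = drug_class == cls
        if not mask.any():
            continue
        bins = np.searchsorted(cdf, u_bin[mask], side="right")
        lohi = np.array([ONSET_BIN_DAYS[labels[b]] for b in bins])
        onset[mask] = lohi[:, 0] + np.floor(
            u_day[mask] * (lohi[:, 1] - lohi[:, 0] + 1))
    onset_col = pd.array(onset, dtype="Int64")
    onset_col[missing_onset] = pd.NA

    multiple = rng.random(n) < config.multiple_disease_p
    extra_dis = rng.integers(0, 3, n)
    n_diseases = np.where(multiple, 2 + extra_dis, 1)
    poly = rng.random(n) < config.polypharmacy_p
    extra_med = rng.integers(0, 4, n)
    n_medications = np.where(poly, 5 + extra_med, 1 + extra_med)
    past_adr = rng.random(n) < config.past_adr_p

    female = np.array([s == "female" for s in sex])
    mab = drug_class == "mab"

    def linpred(model: dict) -> np.ndarray:
        return (model["intercept"] + model["mab"] * mab
                + model["female"] * female + model["polypharmacy"] * poly
                + model["multiple_disease"] * multiple
                + model["past_adr"] * past_adr)

    serious = rng.random(n) < expit(linpred(config.severity_model))
    effect = rng.random(n) < expit(linpred(config.impact_model))
    split_labels = list(config.effect_split.keys())
    split_cdf = np.cumsum(np.array(list(config.effect_split.values())))
    split_cdf[-1] = 1.0
    u_split = rng.random(n)
    split_idx = np.searchsorted(split_cdf, u_split, side="right")
    impact = np.where(effect,
                      np.array(split_labels, dtype=object)[split_idx],
                      "no_effect")
    death = impact == "death"
    severity = np.where(serious | death, "serious", "non_serious")

    return pd.DataFrame({
        "report_id": [f"S{config.seed}-{i:06d}" for i in range(n)],
        "year": year,
        "age": pd.array(age, dtype="Int64"),
        "sex": sex,
        "causality": causality,
        "drug_name": [specs[int(k)].name for k in drug_idx],
        "atc_class": ["L01"] * n,
        "drug_class": drug_class,
        "mab_type": [specs[int(k)].mab_type for k in drug_idx],
        "patent_status": [specs[int(k)].patent_status for k in drug_idx],
        "adr_term": terms,
        "soc": socs,
        "onset_days": onset_col,
        "severity": severity,
        "impact": impact,
        "n_diseases": pd.array(n_diseases, dtype="Int64"),
        "n_medications": pd.array(n_medications, dtype="Int64"),
        "past_adr_history": past_adr,
        "outcome_death": death,
    })


def generate_reports(config: SimulationConfig) -> list[AdrReport]:
    """Draw synthetic reports (record view of :func:`generate_frame`)."""
    return frame_to_reports(generate_frame(config))


# ==========================================================================
# Operating characteristics of the signal criteria
# ==========================================================================

def signal_recovery_config(n_reports: int = 50_000, rate_ratio: float = 10.0,
                           seed: int = 0, target_a: float = 30.0
                           ) -> SimulationConfig:
    """Compact config with one planted DEC of a chosen expected count.

    Ten equally weighted non-mAb drugs and twenty events; the planted
    event's baseline probability is solved analytically from
    E[a] = n * P(drug) * P(event | drug) = ``target_a`` given the rate
    ratio, so the study conditions are fixed before any data are drawn.
    """
    cfg = default_config(n_reports=n_reports, seed=seed)
    names = [f"Drug{i:02d}" for i in range(10)]
    cfg.drugs = [DrugSpec(nm, "non_mab", weight=1.0) for nm in names]
    cfg.drug_class_probs = {"non_mab": 1.0}
    p_drug = 0.1
    b = target_a / (n_reports * p_drug * rate_ratio
                    - target_a * (rate_ratio - 1.0))
    rest = (1.0 - b) / 19.0
    cfg.events = ([EventSpec("Event00", "Gastrointestinal disorders", b)]
                  + [EventSpec(f"Event{i:02d}", "Gastrointestinal disorders",
                               rest) for i in range(1, 20)])
    cfg.planted_decs = [PlantedDec("Drug00", "Event00", rate_ratio)]
    return cfg


def null_config(n_reports: int = 50_000, seed: int = 0) -> SimulationConfig:
    """No planted effects; every DEC has expected a = n/200 >= 10."""
    cfg = signal_recovery_config(n_reports=n_reports, rate_ratio=1.0,
                                 seed=seed, target_a=n_reports / 200.0)
    cfg.events = [EventSpec(f"Event{i:02d}", "Gastrointestinal disorders",
                            1 / 20) for i in range(20)]
    cfg.planted_decs = []
    return cfg


def operating_characteristics(config: SimulationConfig, n_replicates: int,
                              rule: str = "intersection",
                              prr_se: str = "printed",
                              n_null_sample: int = 20,
                              min_expected_a: float = 0.0) -> pd.DataFrame:
    """Detection and false-flag fractions of the signal criteria.

    Runs ``n_replicates`` simulations (replicate r uses seed
    ``config.seed + 1 + r``), mines signals in each, and reports per
    planted DEC the fraction of replicates flagged, plus — for a
    deterministic sample of up to ``n_null_sample`` non-planted DECs
    with analytic expected a >= ``min_expected_a`` — the false-flag
    fraction. Returns one row per tracked DEC with columns
    kind/drug/event/expected_a/flag_fraction/n_replicates.
    """
    from srsafety.disproportionality import compute_signals

    if n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    config.validate()
    planted = {(dec.drug, dec.event) for dec in config.planted_decs}
    drug_names = sorted({d.name for d in config.drugs})
    candidates = [(dn, e.term) for dn in drug_names for e in config.events
                  if (dn, e.term) not in planted]
    candidates = [(dn, ev) for dn, ev in candidates
                  if expected_cells(config, dn, ev)["a"] >= min_expected_a]
    pick_rng = np.random.default_rng(config.seed)
    if len(candidates) > n_null_sample:
        chosen = pick_rng.choice(len(candidates), size=n_null_sample,
                                 replace=False)
        candidates = [candidates[int(i)] for i in sorted(chosen)]
    tracked = sorted(planted) + candidates
    hits = dict.fromkeys(tracked, 0)
    for r in range(n_replicates):
        rep = replace(config, seed=config.seed + 1 + r)
        frame = generate_frame(rep)
        metrics, _ = compute_signals(frame, rule=rule, prr_se=prr_se)
        flagged = {(m.drug, m.event) for m in metrics if m.signal}
        for key in tracked:
            if key in flagged:
                hits[key] += 1
    return pd.DataFrame([{
        "kind": "planted" if key in planted else "null",
        "drug": key[0],
        "event": key[1],
        "expected_a": expected_cells(config, key[0], key[1])["a"],
        "flag_fraction": hits[key] / n_replicates,
        "n_replicates": n_replicates,
    } for key in tracked])
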