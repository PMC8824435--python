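"""Risk modelling: crude ORs, logistic regression, Mantel-Haenszel pooling.

Binary logistic regression relates ADR severity (serious vs non-serious)
and impact on the primary disease (effect vs no effect) to drug class and
patient covariates, with the outcome of interest coded 1 so that a
negative coefficient is protective. Mantel-Haenszel stratified analysis
pools the mAb (exposure) odds ratio for the dichotomized impact outcome
across levels of a patient characteristic.

The logistic fit is maximum likelihood via iteratively reweighted least
squares (statsmodels GLM with a binomial family); standard errors come
from the inverse observed information. Coefficients diverging beyond
|beta| > 15 are treated as separation and flagged non-converged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from srsafety.frames import as_frame, derived_column
from srsafety.srs_data import DomainError

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # standard normal 0.975 quantile

#: Reference levels for the standard severity/impact models.
MODEL_TERMS: dict[str, str] = {
    "drug_class": "non_mab",
    "age_group": "18-34",
    "sex": "male",
    "disease_types": "single",
    "polypharmacy": "non_polypharmacy",
    "past_adr_history": "no",
}

STRATIFY_VARS = ("sex", "age_group", "disease_types", "polypharmacy",
                 "past_adr_history")


@dataclass(slots=True)
class ORResult:
    """A crude odds ratio with a Woolf 95% confidence interval."""

    value: float
    ci_low: float
    ci_high: float
    defined: bool = True
    corrected: bool = False  # Haldane-Anscombe +0.5 applied


def crude_or(a: int, b: int, c: int, d: int, alpha: float = 0.05) -> ORResult:
    """Crude OR = ad/bc with the Woolf log-scale CI.

    With exactly one zero cell, 0.5 is added to all four cells
    (Haldane-Anscombe) and the result flagged ``corrected``. Two or more
    zero cells leave the OR undefined (``defined=False``).
    """
    cells = [a, b, c, d]
    if min(cells) < 0:
        raise DomainError("cell counts must be non-negative")
    corrected = False
    n_zero = sum(x == 0 for x in cells)
    if n_zero >= 2:
        return ORResult(math.nan, math.nan, math.nan, defined=False)
    if n_zero == 1:
        a, b, c, d = (x + 0.5 for x in cells)
        corrected = True
    z = float(norm.ppf(1 - alpha / 2.0))
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ORResult(or_, or_ * math.exp(-z * se), or_ * math.exp(z * se),
                    defined=True, corrected=corrected)


@dataclass(slots=True)
class RegressionResult:
    """Coefficients, ORs and Wald CIs for one logistic model.

    Reference levels carry no coefficient; ``terms`` names each fitted
    column as ``var[level]`` (or the bare variable for binary inputs).
    """

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    or_: np.ndarray = field(default=None)
    ci_low: np.ndarray = field(default=None)
    ci_high: np.ndarray = field(default=None)
    converged: bool = True
    iterations: int = 0
    llf: float = math.nan

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        self.bse = np.asarray(self.bse, dtype=float)
        self.or_ = np.exp(self.params)
        self.ci_low = np.exp(self.params - Z95 * self.bse)
        self.ci_high = np.exp(self.params + Z95 * self.bse)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "beta": self.params,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "converged": self.converged,
        })


def fit_logistic(design: pd.DataFrame, outcome,
                 freq_weights=None, add_intercept: bool = True
                 ) -> RegressionResult:
    """Maximum-likelihood logistic fit of a binary outcome.

    ``design`` holds numeric (dummy-coded) columns; an intercept is
    prepended unless ``add_intercept`` is False. ``freq_weights`` allows
    grouped (aggregated) data. Raises on a one-class outcome; flags
    separation (any |beta| > 15) as non-converged rather than emitting a
    silently diverged fit.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise DomainError("outcome must contain both classes")
    X = design.astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Binomial(),
                   freq_weights=freq_weights)
    res = model.fit(maxiter=100, tol=1e-10)
    converged = bool(res.converged) and bool(
        np.all(np.abs(res.params) <= 15))
    if not converged:
        logger.warning("logistic fit flagged non-converged "
                       "(possible separation)")
    terms = list(X.columns)
    iters = len(res.fit_history.get("deviance", [])) - 1
    return RegressionResult(terms=terms, params=res.params.to_numpy(),
                            bse=res.bse.to_numpy(), converged=converged,
                            iterations=max(iters, 0), llf=float(res.llf))


def build_design(reports, terms: dict[str, str] | None = None
                 ) -> pd.DataFrame:
    """Dummy-coded design matrix with the standard reference levels.

    ``terms`` maps variable name to its reference level; defaults to the
    standard model (drug class ref non-mAb, sex ref male, age ref 18-34,
    disease ref single, polypharmacy ref non-polypharmacy, past-ADR ref
    no). Rows with a missing value for any term are dropped; the kept
    row index is preserved so the outcome can be aligned.
    """
    terms = dict(terms or MODEL_TERMS)
    frame = as_frame(reports)
    cols = {var: derived_column(frame, var) for var in terms}
    keep = pd.concat(cols, axis=1).notna().all(axis=1)
    out = {}
    for var, ref in terms.items():
        col = cols[var][keep].astype(str)
        levels = [lv for lv in sorted(col.unique()) if lv != str(ref)]
        for lv in levels:
            out[f"{var}[{lv}]"] = (col == lv).astype(float)
    return pd.DataFrame(out, index=frame.index[keep])


def outcome_vector(reports, outcome: str) -> pd.Series:
    """Binary outcome: severity (serious=1) or impact (effect=1)."""
    frame = as_frame(reports)
    if outcome == "severity":
        return (frame["severity"] == "serious").astype(float)
    if outcome == "impact":
        return (derived_column(frame, "impact_effect") == "effect"
                ).astype(float)
    raise DomainError("outcome must be 'severity' or 'impact'")


def fit_outcome_model(reports, outcome: str) -> RegressionResult:
    """Fit the standard multivariable model for severity or impact."""
    X = build_design(reports)
    y = outcome_vector(reports, outcome).loc[X.index]
    return fit_logistic(X, y)


# --------------------------------------------------------------------------
# Mantel-Haenszel stratified analysis
# --------------------------------------------------------------------------

@dataclass(slots=True)
class MHResult:
    value: float
    ci_low: float
    ci_high: float
    defined: bool = True
    n_informative: int = 0


def mh_pooled_or(strata, alpha: float = 0.05) -> MHResult:
    """Mantel-Haenszel pooled OR across 2x2 strata with RBG 95% CI.

    ``strata`` is an iterable of (a, b, c, d) cell tuples (or 2x2
    arrays). OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i); the CI uses
    the Robins-Breslow-Greenland variance of ln OR_MH. Strata with a zero
    total (or zero on both cross products) contribute nothing and are
    logged; if all strata are degenerate the result is flagged undefined.
    """
    tables = []
    for t in strata:
        arr = np.asarray(t, dtype=float).reshape(4)
        if arr.min() < 0:
            raise DomainError("cell counts must be non-negative")
        tables.append(arr)
    R = S = 0.0
    sum_PR = sum_PSQR = sum_QS = 0.0
    n_informative = 0
    for a, b, c, d in tables:
        n = a + b + c + d
        if n == 0 or (a * d == 0 and b * c == 0):
            logger.info("skipping degenerate stratum (%g,%g,%g,%g)",
                        a, b, c, d)
            continue
        n_informative += 1
        P = (a + d) / n
        Q = (b + c) / n
        Ri = a * d / n
        Si = b * c / n
        R += Ri
        S += Si
        sum_PR += P * Ri
        sum_PSQR += P * Si + Q * Ri
        sum_QS += Q * Si
    if n_informative == 0 or R == 0 or S == 0:
        return MHResult(math.nan, math.nan, math.nan, defined=False,
                        n_informative=n_informative)
    or_mh = R / S
    var = sum_PR / (2 * R * R) + sum_PSQR / (2 * R * S) + sum_QS / (2 * S * S)
    z = float(norm.ppf(1 - alpha / 2.0))
    se = math.sqrt(var)
    return MHResult(or_mh, or_mh * math.exp(-z * se),
                    or_mh * math.exp(z * se), defined=True,
                    n_informative=n_informative)


def stratified_mab_effect(reports, stratify_var: str) -> pd.DataFrame:
    """Per-stratum mAb-vs-non-mAb ORs for the dichotomized impact outcome.

    For each level of ``stratify_var``, builds the 2x2 table
    (a = mAb & effect, b = mAb & no effect, c = non-mAb & effect,
    d = non-mAb & no effect) with its crude OR and Woolf 95% CI, then
    appends the Mantel-Haenszel pooled row. Degenerate levels are emitted
    with ``NE`` flags (NaN estimates).
    """
    if stratify_var not in STRATIFY_VARS:
        raise DomainError(
            f"stratify_var must be one of {STRATIFY_VARS}, got {stratify_var!r}")
    frame = as_frame(reports)
    level_col = derived_column(frame, stratify_var)
    exposure = derived_column(frame, "drug_class")
    outcome = derived_column(frame, "impact_effect")
    keep = level_col.notna()
    rows = []
    strata = []
    for level in sorted(level_col[keep].astype(str).unique()):
        m = keep & (level_col.astype(str) == level)
        a = int(((exposure == "mab") & (outcome == "effect") & m).sum())
        b = int(((exposure == "mab") & (outcome == "no_effect") & m).sum())
        c = int(((exposure == "non_mab") & (outcome == "effect") & m).sum())
        d = int(((exposure == "non_mab") & (outcome == "no_effect") & m).sum())
        strata.append((a, b, c, d))
        res = crude_or(a, b, c, d)
        rows.append({
            "stratum": level, "a": a, "b": b, "c": c, "d": d,
            "or": res.value if res.defined else math.nan,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "ne": not res.defined,
        })
    pooled = mh_pooled_or(strata)
    rows.append({
        "stratum": "MH pooled", "a": sum(s[0] for s in strata),
        "b": sum(s[1] for s in strata), "c": sum(s[2] for s in strata),
        "d": sum(s[3] for s in strata),
        "or": pooled.value, "ci_low": pooled.ci_low,
        "ci_high": pooled.ci_high, "ne": not pooled.defined,
    })
    return pd.DataFrame(rows)
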