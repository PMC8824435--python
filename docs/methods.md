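# Methods

## Scope and data model

`srsafety` analyses spontaneous ADR reports for antineoplastic (ATC
L01) drugs. The unit of analysis is one report carrying exactly one
(suspect drug, ADR preferred term) pair; when a physical report lists
several reactions, selection of the main one is assumed to have
happened upstream. Because SRS data lack a usage denominator, all
quantities are report frequencies and reporting associations — never
incidence rates or causal effects.

ADR terms are grouped into system organ classes (SOC) through a small
bundled SOC→term map (`srsafety.terminology`). It mimics the structure
of the MedDRA hierarchy (22 SOCs, a few preferred-term-like labels
each) but is not MedDRA, which is licensed and cannot be bundled.

## Inclusion filtering

Reports are retained when all of the following hold: reporting year
2016–2020; causality certain/probable/possible; ATC class L01; age,
drug name and ADR term present; age ≤ 120 years; recorded onset time
non-negative; not a duplicate of an earlier retained report. Rules are
checked in the fixed order *year, causality, atc, missing-info,
age>120, negative-onset, duplicate* and each excluded report is logged
under the first rule it violates, which makes the accounting identity
`n_input = n_retained + Σ exclusions` exact. The duplicate key is the
conservative field tuple (year, age, sex, drug name, ADR term, onset
days) with first-kept ordering by file position; with no stated
de-duplication algorithm available, exact field equality is the only
defensible choice. Filtering is idempotent and never raises on row
content.

Variable codings: polypharmacy is ≥ 5 concurrent medications; impact on
the primary disease is dichotomized with prolong/worse/sequelae/death
as *effect*; onset bins are 0 (same day), 1–3, 4–7, 8–30 and > 30 days,
with day 0 defined as the day of first administration (only the
same-day and 1–3-day bins are anchored by the reference margins; the
remaining edges follow common 1-week / 1-month reporting practice). Age
groups are 0–5, 6–17, 18–34, 35–59, 60–79, ≥ 80 with boundary values in
the younger-labelled group.

## Descriptive statistics

Percentages are 100·count/total rounded half-away-from-zero to two
decimals; block denominators are the full class sizes (mAb 575 /
non-mAb 15,335 in the fixture) even when a block drops unknown values,
matching the convention of the tables being reproduced. The
per-table test is the **uncorrected** Pearson X² = Σ(O−E)²/E — on the
fixture's severity 2×2 this gives p = 0.0372, which rounds to the
reported 0.037, whereas the Yates-corrected value (0.0414) does not;
the continuity correction is used only inside the MHRA signal
statistic. For 2×2 tables with any expected count < 5 the two-sided
Fisher exact test (summation of margin-preserving tables no more
probable than the observed one) replaces χ². No r×c exact test
(Freeman–Halton) is provided: larger sparse tables fall back to
Pearson χ², which is adequate at these sample sizes. Mean age is
compared with Welch's two-sample t test on raw ages (the variant is not
dictated by the source; Welch avoids the equal-variance assumption at
no cost). Rows of SOC tables are tested 2×2-vs-rest and marked `NE`
(not evaluated) when a class has zero reports in that SOC.

## Risk models

Crude ORs are ad/bc with the Woolf interval
exp(ln OR ± z·√(1/a+1/b+1/c+1/d)). With exactly one zero cell the
Haldane–Anscombe +0.5 correction is applied to all four cells and
flagged; with two or more zero cells the OR is reported undefined.

The logistic models regress severity (serious = 1) and dichotomized
impact (effect = 1) on drug class (reference non-mAb), age group
(reference 18–34), sex (reference male), disease types (reference
single), polypharmacy and past ADR history; a negative coefficient is
therefore protective. Estimation is maximum likelihood via IRLS
(statsmodels GLM, binomial family, tolerance 1e-10), standard errors
from the inverse observed information, Wald 95% intervals on the OR
scale. Any coefficient beyond |β| > 15 is treated as separation and the
fit flagged non-converged rather than silently reported. Published
multivariable coefficients for these models are not reproduced — they
require the raw provincial database — so the models are validated by
identities instead: a single-binary-predictor grouped fit equals
ln(ad/bc) to 1e-6, and repeated fits on generator output recover the
generating coefficients to within Monte-Carlo error.

The Mantel–Haenszel pooled OR is Σ(aᵢdᵢ/nᵢ) / Σ(bᵢcᵢ/nᵢ) with the
Robins–Breslow–Greenland variance for the log-OR interval. Strata with
zero total or both cross-products zero contribute nothing (logged); a
single informative stratum reproduces the crude OR exactly, and the
implementation is cross-checked against
`statsmodels.stats.contingency_tables.StratifiedTable`. The stratified
mAb analysis builds, per level of sex/age group/disease types/
polypharmacy/past history, the 2×2 of drug class × dichotomized impact
and pools across levels.

## Disproportionality

Cell orientation is the conventional one (a = suspect drug & suspect
event, b = suspect drug & other events, c = other drugs & suspect
event, d = remainder), under which ROR = ad/bc and
PRR = [a/(a+b)]/[c/(c+d)] are simultaneously consistent; ROR is
invariant to transposing b and c, so this choice only matters for PRR.
Both CIs default to the log-scale SE √(1/a+1/b+1/c+1/d); the textbook
PRR SE √(1/a − 1/(a+b) + 1/c − 1/(c+d)) is available via
`prr_se="textbook"`. The MHRA statistic is the standard Yates-corrected
χ² n·(max(0, |ad−bc| − n/2))² / [(a+b)(c+d)(a+c)(b+d)], clamped at zero
so balanced tables can never score positive. A metric with a zero cell
(ROR) or zero a/c (PRR) or an empty margin (χ²) is undefined and fails
its criterion. The combined signal flag is the intersection of the
three criteria — every method's threshold must pass — with a union mode
behind a switch; ranked output keeps only flagged DECs, ordered by χ²
descending with deterministic tie-breaks, rounded to two decimals.

## Synthetic data

The generator draws each report field from configurable marginals whose
defaults are the reference study's margins (mAb share 3.61%, year/sex/
age-group frequencies, class-specific onset-bin frequencies, outcome
log-odds chosen so the implied ORs match the reported associations:
mAb −0.213/−0.418, female −0.237/−0.158, polypharmacy −0.859/−1.166,
multiple disease +0.175/+0.239, past ADR history +0.587 on the
severity/impact scales, with intercepts −0.62/−1.55 giving overall
serious ≈ 34% and effect ≈ 17%). Events are drawn per drug: a planted
DEC multiplies the suspect event's baseline probability by its
reporting-rate ratio under that drug and renormalizes, so
`expected_cells` can state the 2×2 cell expectations in closed form —
the oracle used by the recovery tests. Reports whose impact split lands
on death are forced serious (death is itself a seriousness criterion).
One `numpy` generator seeded from the config is consumed in a
documented field order, so identical config+seed is byte-identical and
new fields append draws instead of reshuffling existing ones.

What the generator does *not* model: reporting-propensity biases
(Weber effect, notoriety bias), drug–drug interactions, within-patient
repeat reports, or any correlation between demographics and drug
choice. Passing tests therefore demonstrate correctness of the
statistical machinery under a clean reporting model, not robustness to
real-world reporting artefacts.

The deterministic fixture satisfies the published marginal counts
exactly by laying each field's value blocks over the class's rows with
a field-specific stride coprime to the class size (575 = 5²·23;
15,335 = 5·3067) — a randomness-free interleaving that decorrelates
fields while keeping every margin exact and the table byte-stable.
Within mAbs, SOC and patent status are assigned jointly because the
branded/biosimilar SOC table must sum row-wise to the SOC-by-class mAb
column. The fixture carries 44 missing-age, 13 unknown-sex and 6
missing-onset rows so per-analysis drops match the published
denominators; its joint distributions are otherwise arbitrary, so
model fits on the fixture are not meaningful — it exists to pin the
descriptive layer cell-for-cell.

## Operating characteristics and problem sizes

`operating_characteristics` replays the full mining pipeline over
replicates (replicate r uses seed + 1 + r) and reports per-DEC flag
fractions for planted DECs and a deterministic sample of null DECs,
optionally restricted to null DECs with analytic expected a above a
floor. The standard study uses 100 replicates of 50,000 reports with
one DEC planted at rate ratio 10 and baseline solved analytically so
E[a] = 30 (detection ≥ 95% expected: the analytic lower CI bound of the
planted ROR sits near 6, far from 1); the matched null uses equal event
baselines giving every DEC E[a] = 250 ≥ 10, where the intersection rule
keeps false flags well under 10%. Parameter-recovery checks use 50
studies of 20,000 reports, which bounds the Monte-Carlo SE of each mean
coefficient near 0.01–0.02. These sizes make the whole validation suite
run in about a minute while leaving all sampling-error margins wide.

## Known limitations

* The exact test is 2×2 only; sparse r×c tables get asymptotic χ².
* PRR's default interval uses the same SE as ROR (kept for fidelity to
  the criteria being implemented); the textbook SE is opt-in.
* The fixture's joint structure is synthetic; only its margins are real.
* Signal flags indicate reporting disproportionality. They are not
  causal claims and inherit all SRS biases (under-reporting, notoriety,
  no exposure denominator).
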