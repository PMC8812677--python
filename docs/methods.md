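# Methods

## Episode model

The unit of analysis is the *episode*: an index contact plus the follow-up
contacts attributed to it.

* A contact is **RTI-relevant** if any of its up-to-8 registered ICD-10
  codes matches the configured code set. Matching normalises codes
  (uppercase, dots stripped) and uses prefix semantics: a listed
  three-character code covers all of its decimal children (J20 covers
  J20.9); the single four-character entry R06.0 covers itself and deeper
  subdivisions but not its siblings (R06.1 is excluded — dyspnea is listed
  specifically, not the whole R06 block); ranges expand inclusively to
  every three-character code they span; the Swedish extension code ZV100 is
  a literal prefix with no WHO-validity check. These are standard
  claims-data conventions; the code set and windows live in configuration
  so alternatives are one edit away.
* An **index** is an outpatient (primary-care or emergency-room, including
  telemedicine providers) physician contact that is RTI-relevant and has no
  RTI-relevant physician contact of the same person in the preceding
  `washout_days` (default 181). The washout is implemented as "blocked if
  an RTI contact occurred in [date−181, date−1]" — a contact exactly 181
  days earlier still blocks; the phrase "at least 181 days" is ambiguous by
  one day and the chosen reading is an explicit config knob
  (`washout_days`). Every RTI-relevant physician contact — index,
  follow-up, limbo, or an inpatient stay — resets the clock, so a fresh
  index needs 181 diagnosis-free days from the person's *last* RTI contact.
* A **follow-up** is any outpatient physician contact, regardless of
  diagnosis, 1–30 days (`followup_days`) after an index of the same person.
  Same-day contacts are not follow-ups (the window starts at day 1).
  Because two indexes of one person are always more than 181 days apart,
  attribution is unique by construction. Inpatient records and
  non-physician contacts are never follow-ups; non-physician contacts are
  ignored by the classifier entirely.
* A **limbo** contact is RTI-relevant but neither index (washout not
  elapsed) nor follow-up (outside every 30-day window): it appears in no
  tally but still resets the washout clock. Limbo contacts are emitted in
  the labelled-contacts output for diagnostics.
* **Same-day ties** are ordered deterministically by (setting,
  provider-class, source, input order). Two same-day RTI contacts cannot
  both be indexes: the one sorting earlier blocks the later one. This
  closes a genuine edge case a purely date-based washout would leave open.

Episodes are assembled from indexes dated inside the configured study
periods (defaults: January–June of 2018, 2019, 2020). Follow-ups dated
after a period's end remain attached — the attribution window belongs to
the index date. Indexes outside every period produce no episode but still
shape the washout. The data window (default 2017-08-01..2020-07-31) is
shorter than 181 days before the first period; the classifier simply uses
the available history, mirroring how a registry extract would be analysed.

## Contact typology

Outpatient physician contacts carry exactly one modality label:
`telemedicine` (telemedicine provider, remote by definition),
`remote_traditional` (remote contact with a primary-care centre or
emergency room), or `in_person`. Primary-care and emergency-room in-person
visits are pooled — the distinction never enters the published-style
outputs.

## Aggregation

Per-1000 rates are `1000·count/population` with the registered population
at December 31 of the preceding year as denominator; hospitalisations
(unique patients with an RTI-coded inpatient stay in the period) use the
same denominator. Display rounding is decimal half-up to 2 places
(matching how such tables are printed); every function also returns
unrounded values (`ndigits=None`) and the exact decimal division avoids
binary-float artefacts at the rounding boundary. The follow-up matrix cell
(i, j) is type-j follow-ups per type-i index; the pooled "all" row is the
index-count-weighted average of the typology rows (checked as a numeric
identity in the tests). Monthly series attribute follow-ups to the index's
month, keeping per-index ratios coherent within months.

## Inference

Contrasts compare episodes indexed March–June 2020 against the pooled
March–June windows of 2018 and 2019, at the index-visit level. The
difference in mean follow-ups per index (total, or of one modality) is the
OLS coefficient of the period indicator — numerically identical to the
difference in group means — with heteroskedasticity-consistent standard
errors. HC1 is the default (count outcomes are heteroskedastic across
groups; HC1 is the common finite-sample-scaled choice) and the variant is
switchable in config; p-values use the t reference with n−2 residual df,
indistinguishable from normal at registry sample sizes. The composition
test is the classic Pearson χ² on the 2×3 table of follow-up *contacts*
(period × follow-up modality), df = 2; contacts rather than episodes are
the units, an interpretational choice recorded here because the
contact-level framing is what a composition-of-contacts question asks.
No multiple-testing correction is applied and variances are not clustered
on person; both are deliberate scope choices of this implementation.
Degenerate inputs (a single period group, an empty stratum, a zero margin)
are flagged or raised explicitly, never silently zeroed.

## Synthetic registry generator

The generator emulates the statistical structure the pipeline assumes,
with ground-truth roles for every contact so recovery can be checked
label-for-label.

* **Episode arrivals.** For each calendar month, the number of new
  episodes is Binomial(population, rate/1000) and episodes are assigned to
  persons whose washout has expired; `monthly_rti_incidence` is therefore
  the *unconditional* expected rate per 1000, and the 181-day gap holds by
  construction (a person is blocked for 181+30+1 days after an index).
  An infeasible schedule — more episodes demanded than eligible persons —
  raises rather than silently degrading. Within-month dates are uniform
  (no within-month distribution is known for such data).
* **Modality and follow-ups.** Each index draws its modality from the
  regime's mix; follow-up counts per (index type, follow-up type) are
  Poisson with the regime's intensity (only means are observable in
  aggregate data, making Poisson the minimal choice), dated uniformly 1–30
  days after the index. Regimes are functions of the calendar date kept in
  the parameters, and both the mix and the intensity matrix are
  regime-keyed so a single registry can carry a mid-window behavioural
  change.
* **Hospitalisation.** With probability 0.06 per episode (≈ the observed
  ratio of hospitalised patients to index contacts, 4.75 vs 79.8 per 1000)
  an RTI-coded inpatient stay occurs 1–10 days after the index. Admission
  follows the index assessment; a same-day stay would block its own index
  under the washout rule.
* **Background utilisation.** Optional non-RTI physician/nurse contacts at
  `background_contact_rate` per person-month, coded outside the RTI set so
  specificity is testable. A background physician outpatient contact
  landing 1–30 days after a true index genuinely *is* a follow-up under
  the attribution rule and is labelled so in the ground truth.
* **Diagnosis masking.** Missing-diagnosis probabilities per
  (provider class, mode) are applied after roles are fixed, so ground
  truth quantifies the misclassification missingness causes downstream
  (traditional providers registering fewer diagnoses for remote contacts
  is the pattern of interest). Masking an index hides it from the
  pipeline; its RTI-coded follow-ups can then surface as spurious indexes,
  which is exactly the bias mechanism described for real registries.

### Presets

`paper_like_params` returns two documented scenarios on a 2017-08-01 to
2020-07-31 window. Incidence (new episodes per 1000 per month) peaks in
February in the seasonal years (Jan–Jun summing to 80/1000 in the first
season and 70/1000 in the later, ~12% lighter one); the pandemic scenario
switches regime on 2020-03-01 to a March peak followed by a drop below
seasonal norms (Jan–Jun 2020 sums to 63/1000). The seasonal modality mix
is 0.91/0.04/0.05 (in-person / remote-traditional / telemedicine) and the
pandemic-regime mix 0.61/0.25/0.14, chosen so the 2020 half-year pools to
roughly 0.74/0.16/0.10. Follow-up intensities are the observed per-index
rates: seasonal rows total 0.48/0.73/0.49 and pandemic rows
0.60/0.90/0.69. Where published two-decimal cells do not sum exactly to
the published row total (a rounding artefact), one cell is raised by 0.01
so the row totals — the quantities the recovery checks target — are exact.

Two generator processes are off in the presets by design. Background
utilisation is zero because observed per-index follow-up rates already
count *every* physician contact in the 30-day window; an independent
background stream would double-count it. Diagnosis masking is zero because
the preset intensities are calibrated to *registered* (observed) data —
missingness has already acted on the quantities being reproduced, and
masking them again would double-count that process too (it biases the
remote-traditional cell by about −0.01). Missingness experiments pass
`missing_diagnosis_prob` explicitly.

### What the generator does not emulate

No demography (age/sex), comorbidity, geographic or provider-level
structure, transmission dynamics, secular trends in utilisation, or
reimbursement behaviour; the population is closed and constant. Passing
tests therefore demonstrate that the pipeline's logic and arithmetic are
correct and that its estimators recover known generating parameters — not
that real registries satisfy the generating assumptions.

## Problem sizes and numerical choices

The acceptance script simulates 1.1 million persons — the smallest round
population giving at least 5,000 indexes of every modality (including
telemedicine, share 0.14) in the March–June 2020 window, so all recovered
matrix cells carry Monte-Carlo standard errors below 0.014. Test-suite
simulations use 40,000–200,000 persons except the one full-scale recovery
check. Type-I-error calibration uses 1,000 replicates of 150-per-group
Poisson null data. All randomness flows through one seeded NumPy
generator per simulation; identical parameters and seed give byte-identical
output. Stochastic assertions use 95% Monte-Carlo intervals (binomial
3-sigma for the calibration rate) with seeds fixed in the tests.

## Known limitations

* The washout boundary ("at least 181 days") and the subcode-matching
  semantics are reasoned choices, not documented facts about any
  particular registry's conventions; both are configurable.
* Contact-level χ² units and unclustered variances understate dependence
  between follow-ups of one episode; with thousands of episodes per cell
  the qualitative conclusions are insensitive, but exact p-values should
  be read accordingly.
* The generator's constant population and year-independent denominators
  slightly flatten per-1000 comparisons relative to a growing region.
* Secular-trend adjustment of the contrasts is out of scope; the contrast
  estimates mix pandemic effects with any underlying trend.
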