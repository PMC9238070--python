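# Methods

`coughphen` implements a two-stage, rules-plus-NLP approach to finding
chronic cough (CC) in electronic health records, together with the
evaluation protocol for the NLP stage and a synthetic-EHR test bench.
This note records the model, its assumptions, the parameters that
matter, and the design decisions taken where the design was genuinely
open.

## The phenotype

Chronic cough is clinically defined as daily cough lasting eight weeks
or more. No ICD-10 code expresses chronicity of cough, so the phenotype
is operationalized over dated *cough encounters*:

> a patient has CC when at least **k = 3** cough encounters fall within
> a **120-day** window and the first and last of them are at least
> **56 days** apart. The **eligibility date** is the date of the third
> encounter of the earliest qualifying set.

Day differences are inclusive integer date differences; "within 120
days" means `d_last − d_first ≤ 120`. The parameters live in
`CCParameters(k_min=3, span_min_days=56, window_days=120)`. `k_min` is
the number of independent care events demanded; `span_min_days` encodes
the eight-week chronicity floor; `window_days` bounds the episode so
that unrelated acute coughs a year apart do not combine.

`find_cc` is a single chronological sliding-window pass. Correctness
rests on one observation: the intermediate members of any candidate set
always lie between its first and last dates, so a qualifying set ends
at encounter *j* iff some earlier encounter *i* with at least
`k_min − 2` encounters between them satisfies the span constraint.
Scanning *j* in date order yields the earliest eligibility date in
O(n). The test suite holds this against an exhaustive search over all
k-subsets on tens of thousands of random timelines.

Same-day encounters of different categories count as distinct records
by default — the per-category deduplication (below) implies they
coexist — and the span constraint already prevents same-day-only
qualification. Whether distinct same-day records should count is not
decidable from the phenotype definition alone, so it is exposed as
`collapse_same_day` rather than chosen silently.

## Cough encounters

Encounters come from three EHR sources, plus two claim sources in the
sensitivity mode:

* **nlp_note** — a positive cough mention in a provider note (below);
* **diagnosis** — ICD-10 R05 (children included by prefix; R05 had no
  children during the 2016–2019 window, so prefix matching is safe) in
  an outpatient setting: ambulatory, day surgery, home visit, urgent
  care. Inpatient and ER diagnoses do not count;
* **medication_order** — a written order containing benzonatate or
  dextromethorphan. Guaifenesin expectorants, other mucoactive agents
  (acetylcysteine, carbocisteine, bromhexine, ambroxol, erdosteine) and
  codeine agents are excluded as not specific to cough; a combination
  product containing any excluded ingredient is excluded, so
  dextromethorphan–guaifenesin does not qualify. Matching is
  case-insensitive substring over drug name and ingredient — RxNorm
  resolution is out of scope;
* **claim_fill / claim_diagnosis** (sensitivity mode) — prescription
  fills under the same medication rule and R05 outpatient claim
  diagnoses.

EHR sources deduplicate to at most one encounter per *category* per
patient-day; claim sources to one per *person* per day (a same-day fill
and claim diagnosis collapse to a single encounter). The asymmetry is
deliberate and follows the two different deduplication rules the source
streams call for; it is covered by tests.

Patients whose CC determination would rest on encounters outside their
enrollment are protected by dropping out-of-enrollment encounters (with
a logged count) before the scan.

## Cohort eligibility

`select_cohort` applies, in order: an enrollment span overlapping the
identification window (January 2016 – March 2017 by default; the
earliest enrolled day inside the window is the *index date*), age
18–85 in the index year, continuous enrollment for 24 months from the
index date (spans merged across gaps of at most one day), and no
ACE-inhibitor evidence — patient flag, written order, or fill claim
matched against a fixed ACE-ingredient list — since ACE inhibitors are
a common iatrogenic cause of cough. Exclusions are attributed to the
*first failing rule* in the order enrollment → age → ACE; the ordering
is a free choice made explicit, and the ledger of exclusion counts is
part of the output.

## The NLP stage

**Entity recognition** is a closed-lexicon matcher: word-bounded,
case-insensitive matches of *cough, coughed, coughing, coughs, cougher,
tussis*. Expectorate terms are deliberately absent (they rarely appear
without a cough term). Because the lexicon is closed, recognition is
deterministic; the interesting problem is context.

**Context classification** assigns each mention one label: POSITIVE,
NEGATED, HYPOTHETICAL, NOT_PATIENT, or OTHER. A mention is POSITIVE iff
no qualifying context claims it — the label-mapping property asserted
in tests. Temporality is detected nowhere: "history of cough × 5 weeks"
is a current, positive mention. Two engines share this contract:

* *Rules engine* (ConText-style): directional triggers with a
  six-token scope, cut by sentence boundaries and scope terminators
  (*but, however, …*). Nearest trigger wins; distance ties break by
  precedence NEGATED > HYPOTHETICAL > NOT_PATIENT > OTHER. The trigger
  lexicon is editable YAML; six tokens is the conventional scope
  default. Sentences split on `.?!` + whitespace and on newlines,
  treating clinical notes' fragmentary lines as boundaries. An `other`
  trigger category (e.g. *etiquette*, *questionnaire*) covers
  administrative mentions that are about cough without asserting it.
* *Trainable classifier* (`ContextClassifier`): a scikit-learn
  estimator (multinomial logistic regression over sparse window
  features: positional and bag tokens within ±6, trigger
  presence/distance indicators, sentence position). A per-mention
  classifier rather than a sequence labeler: mention spans are found
  deterministically by the lexicon, so sequence labeling adds nothing.
  Training is exactly reproducible under a fixed seed (byte-identical
  pickles, asserted in tests).

**Operating point.** The classifier is precision-first: a POSITIVE
*gate* threshold is tuned on the validation split to maximize recall
subject to positive-class precision > 0.90. The gate only ever demotes
argmax-POSITIVE predictions whose positive probability falls below the
threshold — it never adds positive calls — so the tuned model is never
more aggressive than plain argmax. On separable template data the
tuned threshold is typically 0 (argmax already clears the floor).

**Evaluation** follows the standard two-row protocol: entity-level
span matching (exact offsets by default, overlap behind a flag) and
one-vs-rest classification metrics over the entity-matched mentions,
with POSITIVE and NEGATED each reported with their own support.
Conditioning on matched mentions is recorded in the report metadata.
Precision, recall and F1 use the exact formulas; zero denominators
yield an undefined marker (`None`), never 0. The correct F1 bound,
min(p, r) ≤ F1 ≤ (p + r)/2 with equality iff p = r, is property-tested.

**Agreement.** Krippendorff's alpha (nominal distance, any number of
annotators, missing values allowed) is computed from the coincidence
matrix: α = 1 − D_o/D_e. It is implemented in-package and validated
against a hand-computed four-unit coincidence-matrix example (α = 8/15)
and a Monte-Carlo null (random labels → α ≈ 0).

## Characterization

Demographics use the age bands 18–39, 40–44, …, 60–64, ≥65 at the
index year, sex, and region. Comorbidity grouping consumes any
user-supplied prefix → category table with longest-prefix matching and
an explicit `unmapped` bucket; the AHRQ CCSR tables themselves are not
redistributable and are not bundled. HCRU and costs aggregate
per-patient-per-month (PPPM): per patient, adjusted amounts summed and
divided by the observation months (default 24); the cohort mean and SD
(n − 1) are reported per channel, together with any-use percentages,
the ambulatory roll-up (office + hospital outpatient), the medical
roll-up, and total = medical + pharmacy computed per patient before
averaging (so the decomposition identity holds exactly). Inflation
adjustment is a per-calendar-year scalar multiplier supplied in
configuration, standing in for a CPI medical-care series.

## The synthetic-EHR generator

The generator (`synth`) defines the study conditions everything is
tested under; its defaults are fixed once:

* **Corpus**: 1000 notes split 600/200/200 (train/validation/test),
  one to three planted mentions per note with label mixture
  POSITIVE 0.55, NEGATED 0.25, HYPOTHETICAL 0.10, NOT_PATIENT 0.05,
  OTHER 0.05 — positives a slight majority and roughly twice the
  negated share, matching the balance seen in annotated clinical
  corpora of this kind. Note text is template-based (never
  LLM-generated) so character offsets are exact and licensing clean;
  each template is checked against the rules engine at generation
  time, so a "noiseless NLP" run recovers the gold labels exactly. A
  second annotator channel disagrees at a configurable rate
  (default 0) for agreement testing.
* **Population**: 10,000 patients by default; exclusion statuses
  planted at 10% ACE users, 5% age-ineligible, 5% enrollment gaps;
  planted CC prevalence 1.5% of the eligible pool with a further 1.2%
  qualifying only once claims are added; qualifying-set attribution
  mixture 37% NLP-only / 16% structured-only / 47% combination.
  Demographics follow a fixed age-band / sex / region mixture
  (two-thirds female, ≥65 the modal band). CC patients' qualifying
  triples are drawn with span uniform on [56, 120] and certified
  against a brute-force subset oracle (not the production scan — no
  self-fulfilling bugs); non-CC timelines are certified
  non-qualifying, with and without their claims. Eligibility dates
  follow a sinusoidal seasonal rate 1 + A·cos(2π(m − φ)/12) with
  A = 0.6 peaking in January, emulating the winter excess of
  cough-driven care seeking.
* **Utilization**: per-channel Poisson event counts at configured PPPM
  rates with exponential event costs, so recovered PPPM means have
  known targets and Monte-Carlo error.

What the generator does **not** emulate: real note style and discourse
structure (templates are short and fully covered by the trigger
lexicon), realistic ICD code distributions, coding error and missing
data, inter-provider variation, or real cost magnitudes beyond order
of magnitude. Passing tests therefore demonstrate the *algorithmic*
correctness of each stage and of their composition — exact recovery of
planted truth under noiseless NLP, monotone degradation under planted
corruption — not clinical performance on real records, which requires
a licensed annotated corpus.

## Numerical and degenerate-input choices

* Character offsets are 0-based half-open; dates are ISO-8601 with
  integer day arithmetic.
* ICD-10 comparison uppercases and strips the decimal point.
* Gap SD uses n − 1; a single gap reports SD 0.0 rather than NaN. Zero
  CC patients yield absent statistics, not NaN.
* An empty timeline, an empty note, and an empty corpus are valid
  inputs with empty outputs; an empty gold test split and a
  single-label training corpus are errors (the latter directs the
  caller to the rules engine).
* Same-day ties in the qualifying list break by category enum order
  for reproducibility; the eligibility *date* is unaffected by ties.
* Malformed input records fail with file and line number; validation
  never silently drops records.

## Problem sizes

The default test suite and the acceptance script run the full protocol
at the sizes the design states: 1000-note corpora, 10,000-patient
populations, 10,000 random timelines for the oracle-equivalence check.
Shared pytest fixtures use a 300-note / 2,000-patient scale for the
per-module contracts, which exercises every code path while keeping
the suite fast; the end-to-end and NLP-performance checks always run
at full size.

## Known limitations

* The trigger lexicon is compact; real clinical negation ("r/o",
  "w/o", list-scoped negation over many tokens) is broader than the
  shipped defaults, which are meant to be edited.
* Ingredient matching is substring-based; novel formulations or
  misspelled drug names are not resolved.
* Only the first CC episode per patient is detected; recurrence is out
  of scope.
* The claims-supplemented mode cannot distinguish current from
  carried-forward diagnoses, so it trades precision for sensitivity by
  construction.
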