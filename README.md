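# coughphen

Chronic-cough phenotyping from electronic health records.

Chronic cough (CC) — daily cough lasting ≥ 8 weeks — has no specific
ICD-10 diagnosis code, so CC populations cannot be pulled from health
records by code lists alone. `coughphen` implements a computable
phenotype that combines clinical NLP over free-text provider notes
with structured diagnosis codes and medication orders:

1. **Cough-mention NLP.** Every word-bounded match of a closed cough
   lexicon (*cough, coughed, coughing, coughs, cougher, tussis*) is
   extracted from provider notes, and each mention's context is
   classified as POSITIVE, NEGATED, HYPOTHETICAL, NOT_PATIENT, or
   OTHER — by a ConText-style trigger/scope rules engine or by a
   trainable scikit-learn classifier with a precision-first operating
   point (positive-class PPV > 0.90 on validation).
2. **Cough encounters.** Dated encounters are derived from positive
   NLP mentions, ICD-10 R05 diagnoses in outpatient settings, and
   written orders for benzonatate/dextromethorphan (guaifenesin,
   mucoactive and codeine agents excluded), deduplicated to one per
   category per day; a sensitivity mode adds claim fills and claim
   diagnoses at one per person per day.
3. **The temporal CC rule.** A patient has CC when

   ```
   ≥ 3 encounters within 120 days, with ≥ 56 days
   between the first and last qualifying encounter
   ```

   The *eligibility date* is the date of the third encounter of the
   earliest qualifying set, found by an O(n) sliding-window scan that
   is tested for exact agreement with exhaustive subset search.

Around the core sit cohort eligibility filters (age 18–85, 24-month
continuous enrollment, ACE-inhibitor exclusion), diagnostic-accuracy
metrics (span matching, PPV/recall/F1, Krippendorff's alpha for
annotation agreement), cohort characterization (demographics,
prefix-based comorbidity grouping, per-patient-per-month HCRU and
costs), and a fully seeded synthetic-EHR generator that plants ground
truth for every stage, making the entire pipeline testable without
licensed clinical data. It is intended for observational researchers
and informaticists building or validating cough phenotypes.

## Worked example

Run the whole pipeline on freshly simulated data (10,000 patients,
1000-note annotation corpus, all defaults):

```
$ coughphen run-all
cohort=8001 cc=120 prevalence=1.50%
```

8,001 of the 10,000 simulated patients survive the eligibility filters
(the rest are planted ACE-inhibitor users, age-ineligible, or have
enrollment gaps — the per-reason counts are in
`coughphen_run/phenotype_summary.json`). The rules-engine NLP, the
encounter builder, and the temporal rule then recover exactly the 120
planted CC patients: prevalence 120/8001 = 1.50%, matching the planted
rate. `coughphen_run/` also contains the per-patient results
(`cc_results.csv` with eligibility dates, gaps, and NLP/structured
attribution), the monthly eligibility histogram, the held-out NLP
metrics (`model_metrics.tsv`), and the annotation-agreement report.

The same machinery is a library:

```python
import datetime as dt
from coughphen import ProviderNote, classify_corpus, find_cc

note = ProviderNote("n1", "p1", dt.date(2016, 3, 1),
                    "Patient denies fever. Persistent cough for two weeks.")
[(note, mention)] = classify_corpus([note])
print(mention.label)          # ContextLabel.POSITIVE
```

A YAML config (see `coughphen run-all --help` and
`coughphen.pipeline.DEFAULT_CONFIG`) controls seeds, cohort windows,
rule parameters, the NLP engine, and the claims-supplemented
sensitivity mode.

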