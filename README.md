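# textscm

Sparse, semi-supervised rule learning for clinical free text.

Primary-care health records attach free text to coded events. The codes
are easy to query; the text is not — yet investigation results and
diagnoses often live only there ("3 vessel disease, stent to LAD" under a
non-specific "scanned letter" code). `textscm` learns a short list of
**word-combination rules** that flag the texts of interest, training on
labels derived from diagnostic codes alone — no manual annotation — and
tolerating the label noise that entails (typically only ~60% of texts
carrying a target code actually contain the target information).

It is aimed at EHR researchers doing cohort identification and text
triage: the output is a readable rule list (e.g. `{stent}`,
`{ovari, cancer}`), per-record labels, and precision/recall reports
against optional manual-review gold labels.

## The learner

A text is a set of lower-cased word stems. A candidate feature is any word
combination shared by at least two positive texts. The set covering
machine greedily selects features by the penalized score

```
score(h) = |P_h| − p·|N_h| − q·|U_h|
```

(positive / negative / unlabelled records containing `h`, over records not
yet covered), removing covered positives and unlabelled records after each
selection; the classifier is the disjunction of the selected rules. The
semi-supervised loop repeats this T times, each round: mine new word
combinations from the texts currently considered positive, train, then
promote unlabelled texts classified positive into the positive pool as
*pseudo-positives*, while the unlabelled penalty q grows linearly with the
pseudo-positive count. That lets the learner pick up vocabulary (hospital
letter jargon, alternative wordings) that never occurs in the code-labelled
set. See `docs/methods.md` for the full model description.

## Worked example

Generate a synthetic corpus shaped like the angiogram task — 199
code-labelled positive texts of which only 120 truly contain results, 1673
unlabelled case texts hiding 111 true positives, 3539 control texts — then
train and evaluate:

```
$ textscm simulate --task angiogram --seed 11 -o angio
wrote 5411 records to angio/records.tsv

$ textscm train --corpus angio --seed 11 -o angio_run
learned 36 rules over 4 iterations

$ textscm evaluate --labels angio_run/labels.json --corpus angio
Classification of unlabelled texts
  TP=109  FP=8  FN=2  TN=1554
  Precision, % (95% CI): 93.2 (87.1, 96.5)
  Recall, % (95% CI):    98.2 (93.7, 99.5)
  F score, %:            95.6
```

Of the 111 unlabelled texts that truly contain angiogram results, the
semi-supervised learner labels 109 positive (recall 98.2%), at 8 false
positives (precision 93.2%); the parenthesised ranges are 95% Wilson
intervals. The first learned rules are the planted signal stems —
`cathet`, `vessel`, `stenosi`, `lad`, `graft`, … — and `cathet` is
vocabulary that occurs *only* in the unlabelled pool: the supervised
baseline cannot see it, which is exactly the gap the bootstrap closes:

```
$ textscm train --corpus angio --T 0 --q0 0 --seed 11 -o angio_sup
$ textscm evaluate --labels angio_sup/labels.json --corpus angio
Classification of unlabelled texts
  TP=83  FP=18  FN=28  TN=1544
  Precision, % (95% CI): 82.2 (73.6, 88.4)
  Recall, % (95% CI):    74.8 (66.0, 81.9)
  F score, %:            78.3
```

`textscm mine`, `textscm predict` and `textscm loocv` expose candidate
mining, model application, and the semi-supervised leave-one-out error;
real corpora are read from tab-separated or JSON-lines files with columns
`record_id, patient_id, event_date, code, text, gold` (last four
optional). Every run writes its resolved configuration next to its
outputs, and the same seed reproduces outputs byte for byte.

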