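# bcinquiry

Personalized body-constitution inquiry for Traditional Chinese Medicine
(TCM) clinical decision support.

TCM classifies a person's stable health state into nine *body
constitutions* (BC): one Balanced and eight unbalanced types (Qi-deficient,
Yang-deficient, Yin-deficient, Phlegm-dampness, Damp-heat, Stagnant Blood,
Stagnant Qi, Inherited Special). The standard instrument for identifying
them, the 60-item Constitution in Chinese Medicine Questionnaire (CCMQ),
is accurate but slow: patients answer all 60 Likert items (1–5), each
subscale's raw sum is rescaled to a transformed score
`TS = (raw − n) / (4n) × 100`, and the judgment standard converts the nine
scores into a constitution type.

This package implements the machine-learning shortcut: an upstream
image-based classifier (e.g. tongue-coating analysis) narrows the patient
to their **three** most probable constitutions, and only the questions that
discriminate *within that triple* are asked. Concretely:

1. **Simulate** m respondents with i.i.d. uniform answers on {1..5} and
   label each by the constitution with maximal transformed score
   (`synth`, `scoring`).
2. **Enumerate** all C(9,3) = 84 candidate triples and carve each triple's
   training subset from the labeled data (`combinations`).
3. **Rank** the 60 questions per triple by a chi-squared importance score
   `FS(A, Y) = W = (W₁, …, W₆₀)` and keep the top k (`feature_selection`).
4. **Train and cross-validate** one classifier per triple
   (LDA/ANN/SVM/RF/KNN) on the selected question columns —
   `y = classifier(A*)` — with a 5-fold panel of mean/best accuracy and
   micro/macro precision, recall and F score (`bcim`).
5. **Serve** an adaptive inquiry session: candidate triple in, that
   triple's short question list out, one constitution back — always from
   within the triple (`inquiry`).

The questionnaire structure (subscale membership, reverse-scored items,
judgment thresholds) is editable YAML config; the shipped default is a
reconstruction calibrated to the published reference results and must be
verified against the printed instrument before clinical use (see
`src/bcinquiry/data/ccmq_default.yaml` and `docs/methods.md`).

## Worked example

```python
from bcinquiry import (
    build_original_dataset, train_all, top3_from_probabilities,
    start_session, submit_answers, session_report,
)

# 100k simulated respondents, labeled by the scoring standard
dataset = build_original_dataset(m=100_000, seed=7)
print({c.label: n for c, n in dataset.label_counts().items()})
# {'Balanced': 10914, 'Qi-deficient': 10189, 'Yang-deficient': 11353,
#  'Yin-deficient': 9792, 'Phlegm-dampness': 10367, 'Damp-heat': 13090,
#  'Stagnant Blood': 10840, 'Stagnant Qi': 11291, 'Inherited Special': 12164}

# one 16-question LDA model per candidate triple (84 models)
registry = train_all(dataset, classifier_kind="lda", k_policy=16, seed=7)

# a 9-way probability vector stands in for the image classifier's output
triple = top3_from_probabilities(
    [0.02, 0.21, 0.05, 0.48, 0.08, 0.06, 0.04, 0.03, 0.03]
)
print([c.label for c in triple.ordered])
# ['Yin-deficient', 'Qi-deficient', 'Phlegm-dampness']

session = start_session(registry, triple)
print(session.questions)
# [31, 26, 28, 29, 17, 21, 24, 30, 20, 19, 25, 5, 22, 8, 16, 27]

# a patient endorsing the Qi-deficiency items strongly
answers = {q: 5 if q in range(1, 9) else 1 for q in session.questions}
submit_answers(session, answers)
report = session_report(session)
print(report["prediction"], report["n_questions"])
# Qi-deficient 16
```

The patient answered 16 questions instead of 60, and the model returned a
constitution from the candidate triple. The same flow is available from
the shell:

```bash
bcinquiry generate --m 100000 --seed 7 --out data.csv
bcinquiry train --data data.csv --classifier lda --k-policy 16 --out models/
bcinquiry ask --models models/ --candidates "Yin-deficient,Qi-deficient,Balanced"
bcinquiry sweep --data data.csv --combination 1 --classifier lda --k 1:60
```

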