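"""Precision evaluation workflow: sample, annotate, agree, adjudicate.

Samples matched users per evidence channel, simulates two annotators
(one reads the ground truth; the other errs occasionally), measures
Cohen's kappa on the independent labels, adjudicates disagreements from
truth, and computes precision per channel and pooled.
"""

import numpy as np

from msmcohort import (
    AnnotationRecord,
    CorpusSpec,
    adjudicate,
    compute_metrics,
    generate_corpus,
    normalize_record,
    run_pipeline,
    sample_for_annotation,
)
from msmcohort.patterns import Channel

spec = CorpusSpec(n_users=3000, seed=11)
raw, truth = generate_corpus(spec)
records = [normalize_record(r) for r in raw]
result = run_pipeline(records)
is_tp = dict(zip(truth.user_id, truth.is_true_positive))

units = [
    (uid, Channel.TWEET if ev.channel is not Channel.PROFILE else Channel.PROFILE)
    for uid, ev in result.evidences.items()
]
sample = sample_for_annotation(units, n_tweets=300, n_profiles=300, seed=1)

rng = np.random.default_rng(1)
records_ann = []
for uid, channel in sample:
    true_label = "TP" if is_tp[uid] else "FP"
    # annotator A is faithful; B flips 10% of labels
    b = true_label if rng.random() > 0.10 else ("FP" if true_label == "TP" else "TP")
    records_ann.append(AnnotationRecord(uid, channel, true_label, b))

final = adjudicate(records_ann, {r.unit_id: r.label_a for r in records_ann})
m = compute_metrics(final)
print(f"kappa overall      : {m.kappa_overall:.2f}")
print(f"precision tweets   : {m.tweets.precision:.3f}  (n={m.tweets.n})")
print(f"precision profiles : {m.profiles.precision:.3f}  (n={m.profiles.n})")
print(f"precision overall  : {m.precision_overall:.2f}")
# kappa ~0.7-0.8 reflects the simulated 10% annotator error; precision
# ~0.85 is the corpus mixture's operating point.
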