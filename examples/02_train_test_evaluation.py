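"""Hold-out evaluation: discover on a 75% training split, test on the rest.

Mirrors the standard protocol: stratified 75/25 split, greedy cover fitted
on the training samples only, then sensitivity and specificity with 95%
Wilson intervals on both cohorts. Training sensitivity is 1.0 by
construction — the cover loop only stops once every training tumor is
covered.
"""

from multihit.pipeline import RunConfig, run_pipeline
from multihit.synthetic import PlantedModel, simulate_cohort

matrix, labels, _ = simulate_cohort(PlantedModel(seed=7))
result = run_pipeline(matrix, labels, RunConfig(seed=7, train_fraction=0.75))


def show(name, ev):
    c = ev.counts
    lo, hi = ev.sensitivity_ci
    line = (f"{name:<6} TP={c.TP:<3} FP={c.FP:<3} TN={c.TN:<3} FN={c.FN:<3} "
            f"sens={ev.sensitivity:.1%} ({lo:.1%}-{hi:.1%})")
    lo, hi = ev.specificity_ci
    print(line + f"  spec={ev.specificity:.1%} ({lo:.1%}-{hi:.1%})")


show("train", result.train_eval)
show("test", result.test_eval)
print(f"\n{len(result.solution.combinations)} combinations selected; a "
      "sample is called tumor when it carries every gene of at least one "
      "of them. Intervals are 95% Wilson scores.")
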