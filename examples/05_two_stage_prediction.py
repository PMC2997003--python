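"""Run the full cascade: aaRS vs non-aaRS, then class-1 vs class-2.

Trains the two hybrid models on their presets, then routes fresh
class-1-like and background queries through the cascade.
"""

from aarspred import generate_dataset, two_stage_predict
from aarspred.pipeline import SVMPipeline, build_pipeline
from aarspred.synthetic import get_preset

ds1, ann1, _ = generate_dataset(get_preset("stage1", seed=21))
ds2, ann2, _ = generate_dataset(get_preset("stage2", seed=22))
f1, f2 = build_pipeline("hybrid2", 1), build_pipeline("hybrid2", 2)
m1 = SVMPipeline(f1, ann1).fit(ds1).model
m2 = SVMPipeline(f2, ann2).fit(ds2).model

queries, qann, _ = generate_dataset(get_preset("stage2", seed=23))
class1_query = next(s for s, l in queries.records if l == 1)
background = next(s for s, l in ds1.records if l == 0)

for name, seq, ann in [("class-1-like", class1_query, qann),
                       ("background", background, ann1)]:
    p = two_stage_predict(seq, m1, f1, m2, f2, ann)
    s2 = "skipped" if p.stage2_score is None else f"{p.stage2_score:+.2f}"
    print(f"{name:13s} stage1 {p.stage1_score:+.2f} ({p.stage1_label}), "
          f"stage2 {s2} -> {p.final_label}")
# Stage 2 only runs on stage-1 positives; a background protein exits the
# cascade as non-aaRS without ever being scored for class membership.
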