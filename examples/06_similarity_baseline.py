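"""Cross-validated top-hit similarity baseline vs the hybrid SVM.

Each held-out query gets the label of its best local-alignment hit in
the training folds. On composition-level signal this transfers poorly,
which is exactly why a learned classifier is worth building.
"""

from aarspred import generate_dataset
from aarspred.baseline import AlignmentParams, cv_similarity_eval
from aarspred.evaluation import cross_validate, make_folds
from aarspred.pipeline import SVMPipeline, build_pipeline
from aarspred.synthetic import get_preset

ds, ann, _ = generate_dataset(get_preset("stage1", seed=9))
small = ds.subset([s.id for s in ds.sequences[::5]])  # keep alignment cheap
split = make_folds(small, 5, seed=9)

base = cv_similarity_eval(small, split, AlignmentParams(threshold=0.0))
svm = cross_validate(small, split,
                     lambda: SVMPipeline(build_pipeline("hybrid2", 1), ann))
print(f"top-hit baseline: accuracy {base.accuracy:.2f}%, MCC {base.mcc:.2f}")
print(f"hybrid SVM:       accuracy {svm.accuracy:.2f}%, MCC {svm.mcc:.2f}")
# The baseline hovers near chance because the classes differ in dipeptide
# statistics and short motifs, not in overall alignable similarity.
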