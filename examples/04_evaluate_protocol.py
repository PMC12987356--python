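"""The majority-vote evaluation protocol under label-rich and
label-poor fold schemes.

Clustering is transductive (fit once over all segments); per pivot
fold, clusters are mapped to activities by majority vote over the
labeled folds only, and unmapped clusters fall back to 'other'.
E1V1T62 votes with 62 labeled folds (label-rich); T1V1E62 with just 2
(label-poor) — here scaled down to 8 folds.
"""

import numpy as np

import dmmstream as ds

syn = ds.generate(ds.default_recovery_spec(seed=4, M=240, V=120, length=60))
for i, seg in enumerate(syn.corpus.segments):
    seg.fold = i % 8  # round-robin folds
    seg.label = f"activity_{seg.label}"

cfg = ds.GibbsConfig(K=12, iterations=40, seed=5)
fit_result = ds.fit(syn.corpus, ds.Hyperparameters(), cfg)
print(f"{fit_result.estimated_clusters} clusters found over {syn.corpus.M} segments")

for scheme_name in ("E1V1T62", "T1V1E62"):
    cv = ds.cross_validate(
        syn.corpus, ds.FoldScheme(scheme_name, F=8), fit_result=fit_result
    )
    fallback = np.mean([r.fallback_count for r in cv.per_pivot])
    print(
        f"{scheme_name}: accuracy {cv.mean_accuracy:.3f} +- {cv.sd_accuracy:.3f}, "
        f"macro-F1 {cv.mean_macro_f1:.3f} +- {cv.sd_macro_f1:.3f}, "
        f"mean fallback count {fallback:.1f}"
    )
# The assignments vector is shared between the two schemes; only the
# vote/score fold roles differ.  On a well-separated corpus even two
# labeled folds are enough to map every cluster, so both score highly.
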