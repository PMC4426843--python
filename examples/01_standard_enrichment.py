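"""Standard hypergeometric enrichment on a small hand-built dataset.

We build a tiny target-prediction table and gene-set annotation in code,
run the classic over-representation test on the union of predicted
targets of an input miRNA list, and print the resulting table.
"""

import mirenrich as mr

# miRNA -> gene predicted-target pairs (value = number of binding sites)
preds = mr.TargetPredictionSet({
    ("mir-1", "g01"): 1, ("mir-1", "g02"): 2, ("mir-1", "g03"): 1,
    ("mir-2", "g02"): 1, ("mir-2", "g04"): 1,
    ("mir-3", "g05"): 1, ("mir-3", "g06"): 1,
})

# two gene sets over an eight-gene universe
ann = mr.AnnotationSet(
    {"CELL_CYCLE": {"g01", "g02", "g04"}, "APOPTOSIS": {"g05", "g06", "g07"}},
    universe=[f"g{i:02d}" for i in range(1, 9)],
)

mirnas = mr.MiRNAList(names=("mir-1", "mir-2"))

# the test statistic is the union of predicted targets of the list
union = mr.union_targets(preds, mirnas)
print(f"union of predicted targets: {sorted(union)}")

table = mr.standard_enrichment(preds, ann, mirnas)
print(table.frame[["term_id", "term_size", "overlap", "p_value", "q_value"]]
      .to_string(index=False))

# the same tail probability is available directly:
p = mr.hypergeom_sf(mr.HypergeomParams(k=250, n=10057, K=327, N=15733))
print(f"\nlarge-scale worked example: P(X >= 250) = {p:.3g}")
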