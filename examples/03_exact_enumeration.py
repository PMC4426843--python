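"""Exact enumeration of the resampling null on a small problem.

When the number of same-size miRNA subsets C(M, m) is small, the null
can be enumerated exhaustively instead of sampled. This gives exact
p-values and serves as an oracle for the Monte-Carlo sampler.
"""

import numpy as np

import mirenrich as mr

rng = np.random.default_rng(0)
mirnas = [f"m{i}" for i in range(8)]
genes = [f"g{j:02d}" for j in range(30)]
preds = mr.TargetPredictionSet({
    (m, g): 1 for m in mirnas for g in genes if rng.random() < 0.25
})
ann = mr.AnnotationSet({
    "T1": set(rng.choice(genes, size=8, replace=False)),
    "T2": set(rng.choice(genes, size=12, replace=False)),
}, universe=genes)

mirna_list = mr.MiRNAList(names=tuple(mirnas[:3]))  # C(8,3) = 56 subsets

exact = mr.exact_enumeration_enrichment(preds, ann, mirna_list, "union_proportion")
sampled = mr.empirical_enrichment(preds, ann, mirna_list,
                                  n_iterations=200_000, seed=3)

pe = exact.frame.set_index("term_id")["p_value"]
ps = sampled.frame.set_index("term_id")["p_value"]
print(f"{'term':>5} {'exact p':>10} {'sampled p':>10}")
for t in pe.index:
    print(f"{t:>5} {pe[t]:>10.5f} {ps[t]:>10.5f}")

# exact p-values are multiples of 1/56
assert np.allclose((pe * 56) % 1, 0, atol=1e-9)
print("\nexact p-values are integer multiples of 1/C(8,3) = 1/56, and the "
      "sampler converges to them")
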