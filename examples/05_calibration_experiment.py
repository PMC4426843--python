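"""Type-I-error calibration: the headline comparison of the two methods.

Draw many random miRNA lists (so no term is truly enriched), run both
tests on each list, and measure how often each term is called
significant at alpha = 0.05. On biased data the standard hypergeometric
test rejects planted over-targeted terms almost every time, while the
empirical test stays near its nominal rate.

Runtime: about a minute at these settings.
"""

import mirenrich as mr

cfg = mr.SyntheticConfig(seed=7)
preds, ann, _ = mr.generate_dataset(cfg)

report = mr.calibration_experiment(
    preds, ann,
    list_size=20,
    n_lists=100,
    n_iterations=10_000,
    seed=5,
    methods=("standard", "empirical"),
)

f = report.frame.set_index("term_id")
over = [t for t, b in cfg.biased_term_ids().items() if b > 0]
rest = [t for t in f.index if t not in cfg.biased_term_ids()]

print("per-term rejection rate at alpha = 0.05 over 100 random lists:")
print(f"{'group':>28} {'standard':>10} {'empirical':>10}")
print(f"{'planted over-targeted (5)':>28} "
      f"{f.loc[over, 'rejection_rate_standard'].mean():>10.3f} "
      f"{f.loc[over, 'rejection_rate_empirical'].mean():>10.3f}")
print(f"{'unplanted terms (90)':>28} "
      f"{f.loc[rest, 'rejection_rate_standard'].mean():>10.3f} "
      f"{f.loc[rest, 'rejection_rate_empirical'].mean():>10.3f}")
print("\nnominal rate is 0.05; the standard method is badly anti-"
      "conservative on the planted terms")
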