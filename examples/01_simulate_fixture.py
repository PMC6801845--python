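"""Generate the synthetic 36-sample clinostat experiment and inspect it.

Builds the default fixture: 2,000 genes across 10 conditions (standing 1G
and rotating simulated microgravity, each non-irradiated or sampled 3/24 h
after 1 Gy X-ray or carbon-ion exposure), with an 84-gene cell-cycle panel
and 9 planted gravity-radiation interaction genes.
"""

import gravscreen as gs

counts, design, truth, gene_sets = gs.simulate_fixture(seed=0)

print(f"count matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")
print("replicates per condition:")
print(design["condition"].value_counts()[list(gs.CONDITION_ORDER)].to_string())
print(f"panel genes detected: {(truth.in_panel & truth.detected).sum()} of {truth.in_panel.sum()}")
planted = truth[truth.synergy_class_truth != "none"]
print(f"planted interaction genes ({len(planted)}):")
print(planted["synergy_class_truth"].to_string())
# The truth table records every per-condition mean, so downstream stages can
# be scored against known ground truth.
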