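"""TMM scaling factors and counts-per-million normalization.

Library-size factors are drawn in 0.7-1.3 by the simulator, so raw counts
are not comparable across samples; the trimmed-mean-of-M-values factors
bring them onto one relative-abundance scale.
"""

import gravscreen as gs
from gravscreen.normalize import normalize, tmm_factors

counts, design, truth, _ = gs.simulate_fixture(seed=0)
factors = tmm_factors(counts)
norm = normalize(counts, factors)

print("TMM factors (first 6 samples):")
print(factors.head(6).round(4).to_string())
print(f"factor geometric mean: {float((factors.prod()) ** (1 / len(factors))):.6f}")
print("normalized values are counts per million on factor-adjusted library size;")
print(f"e.g. {counts.iloc[0, 0]} raw counts -> {norm.iloc[0, 0]:.1f} CPM for "
      f"gene {counts.index[0]} in {counts.columns[0]}")
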