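"""The small assay computations: ED50 of a Notch inhibitor by linear
interpolation, split-adjusted fold expansion, coating density, delta-Ct
expression, and the normality-gated group comparison."""

import numpy as np

from tcellopt import (
    PassageRecord,
    QpcrMeasurement,
    adaptive_group_test,
    coating_density,
    cumulative_fold_expansion,
    delta_ct_expression,
    ed50_interpolate,
    simulate_dose_response_curve,
)

# ED50 of a gamma-secretase inhibitor from a simulated dose-response curve
doses = (0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6)
curve = simulate_dose_response_curve(ed50_true=0.35, hill=1.5, doses=doses)
est = ed50_interpolate(curve)
print(f"ED50 by linear interpolation: {est.value:.3f} uM "
      f"(true logistic midpoint 0.35 uM)")

# cumulative fold expansion over 4 weekly passages, half the cells carried
seeded, recs = 2000.0, []
for growth, frac in ((8.0, 0.5), (4.0, 0.5), (2.5, 0.5), (1.5, 1.0)):
    counted = seeded * growth
    recs.append(PassageRecord(counted, frac))
    seeded = counted * frac
fold = cumulative_fold_expansion(recs, 2000.0)
print(f"cumulative fold expansion: {fold:.0f}x "
      f"(product of weekly growth, unaffected by the 1:2 splits)")

# plate-coating surface densities
print(f"DL4-Fc  15.0 ug/ml, 50 ul, 32 mm2 -> {coating_density(15.0, 50, 32):.1f} ng/mm2")
print(f"VCAM-1   2.5 ug/ml, 50 ul, 32 mm2 -> {coating_density(2.5, 50, 32):.1f} ng/mm2")

# delta-Ct relative expression vs beta-actin
m = QpcrMeasurement(ct_gene=24.0, ct_reference=21.0, gene="GATA3")
print(f"GATA3 dCt = +3 cycles -> relative expression {delta_ct_expression(m):.3f}")

# normality-gated group comparison
rng = np.random.default_rng(0)
groups = {"control": rng.lognormal(1.0, 0.8, 12),
          "TNFa": rng.lognormal(1.8, 0.8, 12),
          "IL3+TNFa": rng.lognormal(2.6, 0.8, 12)}
out = adaptive_group_test(groups)
print(f"\ngroup test chosen: {out['test']} (omnibus p = {out['p_value']:.2e})")
for pair, p in out["pairwise"].items():
    print(f"  {pair[0]:9s} vs {pair[1]:9s}: adjusted p = {p:.4f}")

# Shapiro-Wilk rejected normality for the lognormal groups, so the
# comparison ran Kruskal-Wallis with Dunn post hoc and BH adjustment.
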