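"""Build the two experimental designs: a 15-cytokine definitive screening
design and a 6-cytokine orthogonal central composite design.

The DSD tests every candidate at three coded levels {-1, 0, +1} in 2m+1
runs; the CCD adds axial points at ±alpha and center replicates so full
quadratic dose-response models can be fitted at five levels per cytokine.
"""

import numpy as np

from tcellopt import Factor, default_factors, generate_ccd, generate_dsd

# a 15-cytokine screen (three levels each)
screen_factors = [Factor(f"cytokine_{i+1:02d}", 10.0, 20.0, 30.0) for i in range(15)]
dsd = generate_dsd(screen_factors)
print(f"DSD: {dsd.n_runs} runs for {len(screen_factors)} cytokines "
      f"(three levels each)")
print("levels per column:", sorted(set(np.unique(dsd.coded.iloc[:, 0]))))

# the 6-cytokine response-surface design
factors = default_factors()
ccd = generate_ccd(factors, n_center=8, alpha_mode="orthogonal")
print(f"\nCCD: {ccd.n_runs} runs, alpha = {ccd.alpha:.4f} "
      f"(orthogonal: quadratic terms decouple from linear ones)")
print("coded levels for SCF:", sorted(np.unique(np.round(ccd.coded['SCF'], 4))))
print("natural ng/ml for SCF:", sorted(np.unique(np.round(ccd.natural()['SCF'], 2))))

# Each cytokine is tested at 5 concentrations; the 8 center replicates
# estimate pure error, and the +-alpha axial runs identify curvature.
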