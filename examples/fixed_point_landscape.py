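"""Enumerate the coexisting fixed points of the mean-field map at low noise.

At T = 0.2 (weak plasticity region) the map holds fifteen fixed points:
six memory states, two symmetric and six asymmetric mixtures, and the
unstable paramagnetic state.
"""

import numpy as np

import dynamem as dm

spec = dm.SublatticeSpec.ideal(0.2)
params = dm.ModelParams(T=0.2, tau_R=4, tau_F=2)

print(f"{'label':8s} {'stable':6s} {'rho(K)':>8s}   overlaps (M1, M2, M3)")
for fp in dm.enumerate_fixed_points(spec, params):
    M = np.round(fp.overlaps, 3)
    print(f"{fp.label.code:8s} {str(fp.stable):6s} {fp.spectral_radius:8.4f}   {M}")
# rho(K) is the spectral radius of the 24-dimensional Jacobian: < 1 means the
# state attracts nearby mean-field trajectories.
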