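"""Joint mRNA-protein propagator of the two-stage telegraph model.

mRNA decays 20x faster than protein (eps = 0.05), so the generating
function is evaluated through the fast-time expansion and inverted on a
two-variable contour.  The sampling interval is kept at a few mRNA
lifetimes (t = 2 eps), the regime the expansion is built for.
"""

import numpy as np

from telprop import (ChiSpec, ModelBParams, chi_markov, default_contour_b,
                     fsp_propagate, gf_total_b, invert_2d)

params = ModelBParams(kappa_0=1.0, kappa_1=1.0, lam=2.0, mu=1.0, eps=0.05)
chi = ChiSpec(mode="markov")
m0, n0 = 2, 3
t = 2 * params.eps

gf = gf_total_b(params, chi, m0, n0, t, eps_order=2)
table = invert_2d(gf, 12, 20, default_contour_b(params.mu), t=t,
                  m0=m0, n0=n0)
oracle = fsp_propagate("B", params, (m0, n0), chi_markov(params, m0, n0), t)

print(f"joint propagator P(m, n | m0={m0}, n0={n0}, t={t}) — "
      "analytic / master equation")
for m in range(4):
    row = "  ".join(f"{table.P[m, n]:.5f}/{oracle.P[m, n]:.5f}"
                    for n in range(4))
    print(f"m={m}: {row}")
err = np.max(np.abs(table.P - oracle.P[:13, :21]))
print(f"mass = {table.mass:.8f},  max |diff| = {err:.2e}")
print("protein marginal (analytic):",
      np.round(table.P.sum(axis=0)[:6], 5))
# The expansion is second order in eps, so at eps = 0.05 the propagator is
# accurate to ~1e-3 absolute; halving eps roughly quarters the error.
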