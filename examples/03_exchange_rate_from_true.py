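"""Slow-exchange rate constants from transverse relaxation alone.

A resonance hopping between two environments 60 Hz apart decays, in a
selective echo, at R2 + k: the echo refocuses static frequencies but not
stochastic site hops.  Injecting a known hop rate into the two-site
simulator, fitting the decay, and subtracting the intrinsic R2 recovers k -
the closure at the heart of measuring exchange below coalescence from
relaxation data.
"""

import numpy as np

from truespin import Simulator
from truespin.fixtures import ENCODING_GRID_S, doublet_sites
from truespin.relaxfit import extract_exchange_rate, fit_monoexponential
from truespin.sequences import simulate_true

site_a, site_b = doublet_sites(delta_nu=60.0, r=2.0)
grid = np.array(ENCODING_GRID_S)

print("two-site doublet: dnu = 60 Hz, intrinsic R2 = 2 s^-1 at both sites\n")
print(f"{'k injected':>10} {'fitted R2':>10} {'k extracted':>12} {'error':>7}")
for k_in in (1.0, 3.0, 10.0):
    sim = Simulator(site_a, exchange_with=site_b, k_exchange=k_in)
    curve = simulate_true(site_a, "A", encoding_times=grid,
                          selective_duration=0.010, sim=sim, observe_sites=(0,))
    fit = fit_monoexponential(curve, weights="relative")
    res = extract_exchange_rate(fit.rate, 2.0, r2_true_se=fit.rate_se)
    print(f"{k_in:10.1f} {fit.rate:10.3f} {res.k:12.3f} "
          f"{100 * (res.k / k_in - 1):+6.2f} %")

print("\nThe fitted echo rate is R2 + k; subtracting the known intrinsic rate "
      "returns the injected hop rate to better than 1 %.")
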