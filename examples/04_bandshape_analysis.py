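"""Two-site bandshape analysis with instrumental-linewidth bounds.

Above the slow-exchange regime, rate constants come from fitting the
exchange-broadened lineshape (closed-form two-site McConnell solution).
The instrumental contribution to the linewidth cannot be measured exactly,
so the fit is run twice with it pinned at a lower and an upper bound; the
resulting [k_low, k_high] interval is the honest uncertainty statement -
typically much wider than the least-squares covariance would suggest.
"""

from dataclasses import replace

import numpy as np

from truespin.exchange_models import (TwoSiteExchange, bm_bandshape,
                                      coalescence_rate, fit_bandshape)

truth = TwoSiteExchange(nu_a=-30.0, nu_b=30.0, k=20.0, r2_a=2.0, r2_b=2.0,
                        p_a=0.5, l_inst=0.5)
grid = np.linspace(-150.0, 150.0, 3001)
spectrum = bm_bandshape(truth, grid)

result = fit_bandshape(spectrum, replace(truth, k=5.0, l_inst=0.0),
                       l_inst_bounds=(0.4, 0.6))
print(f"generated with k = {truth.k} s^-1, instrumental width 0.5 Hz")
print(f"fit with bounds (0.4, 0.6) Hz -> k in [{result.k_low:.2f}, "
      f"{result.k_high:.2f}] s^-1 (mid {result.k_mid:.2f})")
print(f"coalescence for this 60 Hz doublet: k ~ {coalescence_rate(truth):.0f} s^-1")
print("\nThe interval brackets the generating rate; its width ~ pi * (0.2 Hz)"
      " reflects the instrumental-linewidth ambiguity, not fit statistics.")
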