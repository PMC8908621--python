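"""The survival engine on its own: Kaplan-Meier medians, stratified Cox
with Efron ties, and the gamma-frailty fit.

Frailty data attenuate the marginal hazard ratio (frail patients die early,
making the groups look more alike over time); the per-patient gamma
frailty fit estimates that hidden variance and de-attenuates the
coefficient.
"""

import numpy as np

from ivsurv import cox_fit, cox_frailty_fit, km_estimate

rng = np.random.default_rng(4)
n = 4000
x = (rng.random(n) < 0.5).astype(float)          # a binary exposure
frail = rng.gamma(2.0, 0.5, n)                    # variance 0.5, mean 1
t = rng.exponential(1 / (0.0433 * np.exp(-1.0 * x) * frail))
e = t <= 120
t = np.minimum(t, 120)

km1 = km_estimate(t[x == 1], e[x == 1])
km0 = km_estimate(t[x == 0], e[x == 0])
print(f"median survival: exposed {km1.median:.1f} months "
      f"(95% CI {km1.median_ci[0]:.1f}-{km1.median_ci[1]:.1f}), "
      f"unexposed {km0.median:.1f}")

plain = cox_fit(x[:, None], t, e, names=["exposure"])
frailty = cox_frailty_fit(x[:, None], t, e, names=["exposure"])
print(f"plain Cox log-HR:   {plain.coef[0]:+.3f} (true conditional -1.0; "
      "attenuated by the hidden frailty)")
print(f"frailty Cox log-HR: {frailty.coef[0]:+.3f} with estimated frailty "
      f"variance {frailty.frailty_variance:.2f} (true 0.5)")
print("The frailty term recovers part of the attenuation; its variance is "
      "only weakly identified from single-event data.")
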