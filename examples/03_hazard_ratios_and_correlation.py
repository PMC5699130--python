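"""Association hazard ratios and the intercept-slope 'ceiling effect'.

Starting from the registry-informed joint-model estimates, computes the
hazard ratio of pulmonary exacerbation per unit and per SD of the FEV1
trajectory level (U0) and rate of change (U1), and the implied correlation
between FEV1 level at age 6 and the rate of decline.
"""

import cfjoint as cj

p = cj.reference_params()
th0, th1 = p.event.theta0, p.event.theta1
s0, s1 = p.re_dist.sigma0_sq, p.re_dist.sigma1_sq

print("HR per 1 % predicted of FEV1 level      :", round(cj.hazard_ratio_per_sd(th0, 1.0), 3))
print("HR per one SD of FEV1 level             :", round(cj.hazard_ratio_per_sd(th0, s0), 3))
print("HR per 1 %/yr of FEV1 rate of change    :", round(cj.hazard_ratio_per_sd(th1, 1.0), 3))
print("HR per one SD of FEV1 rate of change    :", round(cj.hazard_ratio_per_sd(th1, s1), 3))
corr6 = cj.intercept_slope_correlation_at_age(p.re_dist, 6.0)
print("corr(FEV1 level at age 6, slope)        :", round(corr6, 2))
print(
    "\nHRs < 1: higher or improving lung function protects against\n"
    "exacerbation; the negative correlation is the ceiling effect --\n"
    "patients who start higher tend to decline faster."
)
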