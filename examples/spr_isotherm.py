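"""Fit an SPR saturation isotherm to recover an apparent affinity.

Saturation responses are generated from the 1:1 Langmuir isotherm
R_eq = R_max/(1 + K_d/[P]) with K_d = 340 nM (the apparent affinity of a
PIP2-sensing domain for 5 mol% PI(4,5)P2 vesicles) at 8 protein
concentrations spanning 10-3000 nM, with 1 RU of read noise, then fitted
by nonlinear least squares.  The fitted K_d is the concentration giving
half-maximal binding; R_max reflects surface capacity.
"""

import numpy as np

import pmbind as pb

concs = np.geomspace(10e-9, 3000e-9, 8)  # molar
data = pb.simulate_isotherm(Kd=340e-9, Rmax=100.0, concs=concs,
                            noise_sd=1.0, seed=0)
fit = pb.fit_isotherm(data)

print(f"fitted K_d  = {fit.Kd * 1e9:.0f} nM  (+/- {fit.Kd_se * 1e9:.0f} nM)")
print(f"fitted R_max = {fit.Rmax:.1f} RU (+/- {fit.Rmax_se:.1f} RU)")
print(f"residual sum of squares = {fit.rss:.2f} RU^2")
print(f"half-maximal response at fitted K_d: {fit.predict([fit.Kd])[0]:.1f} RU")
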