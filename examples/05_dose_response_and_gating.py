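"""IC50, Boltzmann gating, and I-V landmarks from patch-clamp summary tables.

The bundled tables are published mean percent-inhibition values of the
L-type calcium current for WK (a compound herbal antiarrhythmic) and Dioscin
(its principal active saponin).  Both are fitted with the constrained
four-parameter logistic on log-concentration.
"""

import numpy as np

import atriamap as am
from atriamap import datasets

for name, table, units, reported in (
    ("WK", datasets.WK_ICAL_INHIBITION, datasets.WK_ICAL_UNITS,
     datasets.WK_REPORTED_IC50),
    ("Dioscin", datasets.DIOSCIN_ICAL_INHIBITION, datasets.DIOSCIN_ICAL_UNITS,
     datasets.DIOSCIN_REPORTED_IC50),
):
    fit = am.fit_hill(table.concentration, table.response, seed=0)
    lo, hi = fit.ic50_ci
    print(f"{name:8s} IC50 = {fit.ic50:7.3f} {units} "
          f"(hill {fit.hill:.2f}, R2 {fit.r2:.3f}, CI95 [{lo:.2f}, {hi:.2f}]; "
          f"reported {reported})")

# steady-state activation of I_Ca-L: noiseless Boltzmann with the reported V1/2
v = np.arange(-40.0, 21.0, 5.0)
g = 1.0 / (1.0 + np.exp((datasets.ICAL_V_HALF_ACTIVATION - v) / 6.0))
gate = am.fit_boltzmann(v, g, "activation")
print(f"\nactivation V1/2 = {gate.v_half:.3f} mV, k = {gate.k:.2f} mV "
      f"(constructed from the reported {datasets.ICAL_V_HALF_ACTIVATION} mV)")

# I-V landmarks on a synthetic curve built to the reported shape
gate_v = 1.0 / (1.0 + np.exp(-(v - 1.0) / 11.5))
density = (v - 55.0) * gate_v / 8.0
iv = am.iv_summary(np.append(v, np.arange(25.0, 56.0, 5.0)),
                   np.append(density,
                             (np.arange(25.0, 56.0, 5.0) - 55.0)
                             / 8.0 * (1 / (1 + np.exp(-(np.arange(25.0, 56.0, 5.0) - 1) / 11.5)))))
print(f"I-V: peak {iv.peak_potential:.1f} mV, reversal {iv.reversal_potential:.1f} mV "
      f"(reported landmarks: peak {datasets.ICAL_IV_LANDMARKS['peak']:.0f}, "
      f"reversal {datasets.ICAL_IV_LANDMARKS['reversal']:.0f})")
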