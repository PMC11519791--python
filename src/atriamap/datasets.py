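"""Bundled summary tables for the worked examples and reproduction scripts.

These are published group-mean summary tables for two L-type calcium current
(I_Ca-L) blockers characterized by whole-cell patch clamp in rat atrial
myocytes: Wenxin Keli (WK), a compound herbal antiarrhythmic, and Dioscin,
its principal active saponin.  Each table lists mean percent inhibition of
peak I_Ca-L at four bath concentrations.  The reported half-maximal
inhibitory concentrations are 24.2546 +/- 2.0517 mg/mL (WK) and 8.666 +/-
0.777 umol/L (Dioscin).
"""

from __future__ import annotations

import pandas as pd

#: WK concentration (mg/mL) vs mean % inhibition of I_Ca-L
WK_ICAL_INHIBITION = pd.DataFrame(
    {"concentration": [1.0, 10.0, 20.0, 50.0],
     "response": [4.072, 13.225, 40.819, 80.512]}
)
WK_ICAL_UNITS = "mg/mL"
WK_REPORTED_IC50 = 24.2546
WK_REPORTED_IC50_SD = 2.0517

#: Dioscin concentration (umol/L) vs mean % inhibition of I_Ca-L
DIOSCIN_ICAL_INHIBITION = pd.DataFrame(
    {"concentration": [1.0, 3.0, 10.0, 30.0],
     "response": [15.065, 28.270, 60.040, 93.574]}
)
DIOSCIN_ICAL_UNITS = "umol/L"
DIOSCIN_REPORTED_IC50 = 8.666
DIOSCIN_REPORTED_IC50_SD = 0.777

#: reported Boltzmann half-activation / half-inactivation of I_Ca-L (control), mV
ICAL_V_HALF_ACTIVATION = -9.831
ICAL_V_HALF_INACTIVATION = -20.786

#: reported I-V landmarks of I_Ca-L: activation threshold, peak, reversal (mV)
ICAL_IV_LANDMARKS = {"threshold": -30.0, "peak": 10.0, "reversal": 55.0}
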