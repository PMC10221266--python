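"""Physical constants and unit-conversion factors.

Internal computations use SI units throughout (Pa, m3, K, mol); hPa, mL,
Vol% and umol mL-1 appear only at I/O boundaries.
"""

#: Ideal gas constant (Pa m3 K-1 mol-1).
R = 8.314

#: Molar mass of carbon (g mol-1).
M_C = 12.011

#: Molar mass of nitrogen (g mol-1).
M_N = 14.007

#: Pa per hPa.
PA_PER_HPA = 100.0

#: m3 per mL.
M3_PER_ML = 1e-6

#: mol m-3 equals umol mL-1 exactly (1e6 umol / 1e6 mL).
MOL_M3_PER_UMOL_ML = 1.0
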