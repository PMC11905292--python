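"""Physiological and MR constants shared across modules.

Consensus 3T values; all are overridable through the relevant function or
dataclass arguments, these are only the defaults.
"""

# Blood / labelling
T1_BLOOD = 1.65  # s, arterial blood longitudinal relaxation at 3T
ALPHA = 0.85  # PCASL labelling efficiency
LAMBDA = 0.9  # ml/g, brain-blood water partition coefficient

# Tissue relaxation defaults (used by the phantom and as PVEc per-tissue T1s)
T1_GM = 1.3  # s
T1_WM = 1.1  # s
T1_CSF = 4.3  # s

# Phantom proton-density (a.u.); blood M0 = GM M0 / LAMBDA
M0_GM = 100.0
M0_WM = 70.0

# CSF reference-region calibration constants (3T)
LAMBDA_CSF = 1.15  # CSF:blood water partition factor
T2_CSF = 0.75  # s
T2_BLOOD = 0.15  # s

# ml/100g/min per (ml/g/s): 100 g * 60 s
CBF_UNIT_SCALE = 6000.0
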