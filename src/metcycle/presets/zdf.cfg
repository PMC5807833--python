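# Final methionine-cycle population model — ZDF (diabetic) preset.
# Typical rate constants in 1/h; VC in L/kg.
K_CM = 0.13        # methionine peripheral -> central
K_MC = 0.0629      # methionine central -> peripheral
K_MS = 0.605       # methionine -> SAM (MAT)
K_SS = 3220        # SAM -> SAH
K_EL = 0.245       # methionine elimination
VC = 0.15          # apparent central volume, L/kg
K_SH = 11.6        # SAH -> homocysteine (SAHH), control typical
K_HM = 30.7        # homocysteine -> methionine (BHMT), control typical
K_HC = 11.1        # homocysteine -> cysteine (CbS), control typical
K_HP = 142         # homocysteine central -> peripheral, control typical
K_PH = 5.13        # homocysteine peripheral -> central, control typical
# Diabetic-group (ZDF) typical values for the five group-affected rates
ZDF_K_SH = 13.5
ZDF_K_HM = 2.54
ZDF_K_HC = 0.526
ZDF_K_HP = 20.4
ZDF_K_PH = 0.032
# Inter-individual variability (%CV of the log-normal random effects)
IIV_CV_K_HM = 70.1
IIV_CV_K_HP = 45.4
# Combined residual error
SIGMA_ADD = 0.01   # mmol/L
SIGMA_PROP = 0.15  # fraction
GROUP = 1          # this preset simulates the ZDF (diabetic) group
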