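"""Unit conversions and fixed model constants.

Every conversion literal used anywhere in the package lives here, so that a
single table defines the unit system (a test asserts no duplicated literals
elsewhere).
"""

# --- molar / unit conversions -------------------------------------------------
#: insulin: pmol/L per uU/mL (1 uU/mL = 6.00 pmol/L)
INSULIN_PMOL_PER_UU_ML = 6.00
#: exogenous insulin: nmol per international unit (1 IU = 6.00 nmol)
INSULIN_NMOL_PER_IU = 6.00
#: glucose: mg/dL per mmol/L
GLUCOSE_MGDL_PER_MMOLL = 18.02
#: glucose molar mass, g/mol (mg -> mmol dose conversion)
GLUCOSE_MG_PER_MMOL = 180.16
#: C-peptide: ng/dL per pmol/L (MW ~= 3020 g/mol; 1 pmol/L = 3.02 ng/L)
CPEPTIDE_NGDL_PER_PMOLL = 0.302

# --- protocol defaults --------------------------------------------------------
#: glucose bolus, mg per kg body weight
GLUCOSE_DOSE_MG_PER_KG = 300.0
#: exogenous insulin dose, IU per kg body weight
INSULIN_DOSE_IU_PER_KG = 0.03
#: insulin infusion start / duration, min
INFUSION_START_MIN = 20.0
INFUSION_DURATION_MIN = 5.0
#: sampling schedule: fasting plus 18 post-injection times, min
SAMPLE_SCHEDULE_MIN = (
    0.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 14.0, 19.0, 22.0, 27.0,
    30.0, 35.0, 40.0, 50.0, 70.0, 100.0, 140.0, 180.0,
)
#: total test duration, min
TEST_DURATION_MIN = 180.0
#: landmark separating first and second phase of the test (infusion start), min
PHASE_SPLIT_MIN = 20.0

# --- model constants ----------------------------------------------------------
#: insulin distribution volume per kg body weight, L/kg
INSULIN_VOLUME_L_PER_KG = 0.141
#: default second-difference regularisation weight for ISR deconvolution
#: (fixed from an L-curve sweep on the noise-free synthetic fixture)
DECONV_LAMBDA_DEFAULT = 0.25
#: deconvolution / interpolation grid step, min
GRID_STEP_MIN = 1.0
#: minimal-model fit window start, min
FIT_START_MIN = 8.0
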