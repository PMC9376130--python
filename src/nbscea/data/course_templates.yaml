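# Synthetic disease-course template library (versioned and frozen).
#
# Each disease has a screened (detected at birth, treated early) and an
# unscreened (undetected until symptomatic) arm. early_mortality applies
# to ages 0-1, late_mortality to ages >= 2; sequela onset probabilities
# are annual and apply within the onset window [0, 5). Unscreened arms
# carry excess late mortality as well: untreated, symptomatic disease
# keeps killing beyond infancy, which is also why undetected patients do
# not accrue decades of sequela-care costs.
#
# These are stand-in synthetic curves, not literature estimates. The
# values were calibrated once against the engine so the per-case
# discounted QALY gains of screening reproduce the gains implied by the
# published single-disease cost-effectiveness table; see docs/methods.md.
version: "1"
onset_window: [0, 5]
templates:
  PKU:
    screened:   {early_mortality: 0.0,    late_mortality: 0.0,    onset: {ND: 0.002}}
    unscreened: {early_mortality: 0.0076, late_mortality: 0.0034, onset: {ND: 0.075}}
  MSUD:
    screened:   {early_mortality: 0.02,   late_mortality: 0.001,  onset: {ND: 0.01, DD: 0.005}}
    unscreened: {early_mortality: 0.4051, late_mortality: 0.018,  onset: {ND: 0.30, DD: 0.10}}
  CIT1:
    screened:   {early_mortality: 0.0,    late_mortality: 0.0,    onset: {MR: 0.004}}
    unscreened: {early_mortality: 0.0065, late_mortality: 0.0024, onset: {MR: 0.16}}
  CIT2:
    screened:   {early_mortality: 0.0,    late_mortality: 0.0,    onset: {MR: 0.004}}
    unscreened: {early_mortality: 0.0219, late_mortality: 0.0041, onset: {MR: 0.15}}
  HCY:
    screened:   {early_mortality: 0.0,    late_mortality: 0.0,    onset: {MR: 0.003}}
    unscreened: {early_mortality: 0.0020, late_mortality: 0.0008, onset: {MR: 0.14}}
  MMA:
    screened:   {early_mortality: 0.008,  late_mortality: 0.001,  onset: {ND: 0.008, RD: 0.004}}
    unscreened: {early_mortality: 0.0748, late_mortality: 0.0181, onset: {ND: 0.08, RD: 0.05}}
  IVA:
    screened:   {early_mortality: 0.008,  late_mortality: 0.001,  onset: {ND: 0.006, RD: 0.003}}
    unscreened: {early_mortality: 0.0965, late_mortality: 0.0161, onset: {ND: 0.05, RD: 0.04}}
  GA1:
    screened:   {early_mortality: 0.0,    late_mortality: 0.0,    onset: {ND: 0.005}}
    unscreened: {early_mortality: 0.0410, late_mortality: 0.0077, onset: {ND: 0.06}}
  PA:
    screened:   {early_mortality: 0.008,  late_mortality: 0.001,  onset: {ND: 0.006, RD: 0.003}}
    unscreened: {early_mortality: 0.0900, late_mortality: 0.0166, onset: {ND: 0.05, RD: 0.045}}
  PCD:
    screened:   {early_mortality: 0.0,    late_mortality: 0.0,    onset: {DD: 0.002}}
    unscreened: {early_mortality: 0.0594, late_mortality: 0.0069, onset: {DD: 0.08}}
  MCAD:
    screened:   {early_mortality: 0.0,    late_mortality: 0.0,    onset: {DD: 0.003}}
    unscreened: {early_mortality: 0.1110, late_mortality: 0.0065, onset: {DD: 0.09}}
  VLCAD:
    screened:   {early_mortality: 0.0,    late_mortality: 0.0,    onset: {DD: 0.003}}
    unscreened: {early_mortality: 0.0368, late_mortality: 0.0049, onset: {DD: 0.06}}
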