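# PLACEHOLDER risk-of-recurrence model -- NOT the published ROR-C coefficients.
#
# The ROR-C score is a weighted sum of the per-class centroid correlations
# plus a tumour-size term, fitted originally as a Cox proportional-hazards
# model.  The published coefficient values are not shipped with this
# package; transcribe them from the original publication (or your validated
# source) into the fields below before using ROR scores for anything beyond
# smoke testing.  The numbers here are synthetic round values that merely
# exercise the scoring code path.
ror_model:
  class_weights:
    BASAL: 1.0
    HER2: 1.0
    LUMA: -1.0
    LUMB: 1.0
    # Normal-like intentionally absent: not used in ROR models.
  tumor_size_weight: 1.0
  # (low/intermediate, intermediate/high); boundary values fall in the lower group.
  thresholds: [0.0, 1.0]
  # Optional affine rescaling [a, b] applied as a * raw + b, e.g. to map the
  # raw score onto a 0-100 range.  Null disables rescaling.
  score_rescaling: null
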