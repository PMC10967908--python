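# Default ProbDecoder input-lead assignment for Frank-XYZ recordings.
# For each standard lead, the Frank lead whose training-set correlation
# magnitude is highest feeds the decoder.  Several assignments rest on
# strongly *negative* correlations (aVR, V1-V4 face the opposite side of
# the cardiac vector), which is why selection uses |r|.
version: 1
input_system: frank
pairs:
  I: VX
  II: VY
  III: VY
  aVR: VX
  aVL: VX
  aVF: VY
  V1: VZ
  V2: VZ
  V3: VZ
  V4: VZ
  V5: VX
  V6: VX
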