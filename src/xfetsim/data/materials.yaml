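# Material registry: elemental compositions (mass fractions) and densities (g/cm^3).
# Tissue compositions follow the ICRP/ICRU reference recipes commonly used in
# voxel-phantom work; fractions are normalized on load.
air:
  density: 0.0012
  composition: {N: 0.768, O: 0.232}
water:
  density: 1.0
  composition: {H: 0.1119, O: 0.8881}
soft_tissue:
  density: 1.06
  composition: {H: 0.102, C: 0.143, N: 0.034, O: 0.708, Na: 0.002, P: 0.003, S: 0.003, Cl: 0.002, K: 0.003}
muscle:
  density: 1.05
  composition: {H: 0.102, C: 0.143, N: 0.034, O: 0.710, Na: 0.001, P: 0.002, S: 0.003, Cl: 0.001, K: 0.004}
adipose:
  density: 0.95
  composition: {H: 0.114, C: 0.598, N: 0.007, O: 0.278, Na: 0.001, S: 0.001, Cl: 0.001}
brain:
  density: 1.04
  composition: {H: 0.107, C: 0.145, N: 0.022, O: 0.712, Na: 0.002, P: 0.004, S: 0.002, Cl: 0.003, K: 0.003}
lung:
  density: 0.26
  composition: {H: 0.103, C: 0.105, N: 0.031, O: 0.749, Na: 0.002, P: 0.002, S: 0.003, Cl: 0.003, K: 0.002}
cortical_bone:
  density: 1.92
  composition: {H: 0.034, C: 0.155, N: 0.042, O: 0.435, Na: 0.001, Mg: 0.002, P: 0.103, S: 0.003, Ca: 0.225}
lead:
  density: 11.35
  composition: {Pb: 1.0}
gold:
  density: 19.32
  composition: {Au: 1.0}
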