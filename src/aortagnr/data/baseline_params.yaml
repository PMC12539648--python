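# Baseline material and growth-and-remodelling parameters for the murine
# (Marfan, non-dilated) ascending aorta. Keys carry units in their names.
geometry:
  a0_mm: 0.809            # in-vivo inner radius at 120 mmHg
  h0_mm: 0.041            # in-vivo wall thickness at 120 mmHg
mass_fractions:
  phi_e: 0.354            # elastin-dominated matrix
  phi_m: 0.345            # smooth muscle
  phi_c: 0.311            # collagen-dominated matrix
collagen_orientation_fractions:
  beta_theta: 0.012       # circumferential family
  beta_z: 0.012           # axial family
  beta_d: 0.976           # symmetric diagonal pair (split equally)
material:
  ce_kPa: 42.03           # elastin neo-Hookean modulus
  c1m_kPa: 1.26           # smooth muscle Fung modulus
  c2m: 30.0               # smooth muscle Fung exponent
  c1c_kPa: 665.6          # collagen Fung modulus
  c2c: 2.14               # collagen Fung exponent
deposition_stretches:
  G_theta_e: 1.74         # elastin circumferential
  G_z_e: 2.24             # elastin axial (radial = 1/(G_theta_e*G_z_e))
  Gm: 1.19                # smooth muscle (scalar)
  Gc: 1.25                # collagen (scalar, evolves under insult)
orientation:
  alpha0_deg: 51.1        # diagonal collagen angle from the axial direction
mechanosensing:
  delta: 0.0
  xi: 0.0
growth_remodelling:
  eta: 0.9                # smooth-muscle-to-collagen turnover ratio
  Ktauw_over_Ksigma: 0.9  # shear-to-intramural gain ratio
  gamma: 0.2              # collagen fibre-reorientation exponent
  omega: 0.0              # removal-stimulus weight
options:
  neo_hookean_half: true  # use (ce/2)(I1-3); false uses ce(I1-3)
  perivascular_kPa: null  # null -> calibrated so the in-vivo state equilibrates
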