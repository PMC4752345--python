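# Default model parameters: zebrafish retinal neural progenitor cell,
# literature values (see docs/methods.md for sources and units).
geometry:
  length_um: 50.0          # apico-basal cell length L
  width_um: 1.0            # diameter of the thin cytoplasmic process
  nuclear_semi_major_um: 5.0   # ellipsoidal nucleus, semi-axis along the cell axis
  nuclear_semi_minor_um: 2.5   # transverse semi-axes
  apical_gap_um: 1.0       # apical nuclear membrane to apical cell membrane, at rest

transport:
  diffusivity_um2_s: 2.9   # cytoplasmic NICD diffusion coefficient D
  thiele_modulus: 10.0     # sets degradation k = phi^2 D / L^2 (k is not measured)
  import_um_h: 12.0        # nuclear import mass-transfer coefficient K_i
  export_um_h: 2.0         # nuclear export mass-transfer coefficient K_e
  production: 1.0          # apical production rate R, arbitrary units (cancels in theta)

motion:
  v_basal_um_h: 8.0        # drift speed apex -> base
  v_apical_um_h: -27.0     # drift speed base -> apex (negative = toward apex)
  dn_um2_h: 0.125          # positional diffusivity of the Wiener process

distributions:
  turning:                 # stand-in for the unmeasured turning-position law
    kind: uniform
    low: 0.3
    high: 0.9              # basal-most admissible centroid position (1 - a/L)
  pause:                   # stand-in for the unmeasured pause-time law
    kind: exponential
    mean: 1.0              # hours

simulation:
  n_cells: 250
  dt_trajectory: 1.0e-3    # dimensionless (units of t_d = L^2/D)
  dt_solver: 5.0e-3
  ensemble_size: 1500
  threshold:
    fraction: 0.6
    reference: max_cytoplasmic
  bin_edges: [0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
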