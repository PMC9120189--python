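# Material constants for the core-shell magnetoelectric particle model.
# Units as conventionally tabulated: conductivity S/m, magnetostriction ppm,
# density kg/m^3, saturation magnetization A/m, moduli GPa, coupling C/m^2.
# Elasticity matrices are flat upper-triangle, column-major (COMSOL order):
# [D11, D12, D22, D13, D23, D33, D14, D24, D34, D44, ...].
barium_titanate:
  name: BTO
  sigma: 1.0e-7
  chi0: null
  lambda_s_ppm: null
  density: 5700.0
  Ms: null
  poisson: null
  eps_r: [1115.1, 1115.1, 1251.3]
  youngs_GPa: null
  elasticity_voigt_GPa: [150.377, 656.308, 150.377, 65.9391, 65.9391, 145.521,
                         0, 0, 0, 43.8596,
                         0, 0, 0, 0, 43.8596,
                         0, 0, 0, 0, 0, 42.3729]
  coupling_voigt:
    - [0.0, 0.0, -4.32015, 0.0, 0.0, -4.32015]
    - [0.0, 0.0, 17.3624, 0.0, 11.4035, 0.0]
    - [11.4035, 0.0, 0.0, 0.0, 0.0, 0.0]

cobalt_ferrite:
  name: CFO
  sigma: 4.2e-5
  chi0: 70.0
  lambda_s_ppm: 315.0
  density: 6060.0
  Ms: 181800.0
  poisson: 0.33
  eps_r: [9.0355, 9.0355, 10.5037]
  youngs_GPa: 188.4
  elasticity_voigt_GPa: null
  coupling_voigt: null

# Surrounding medium (cerebrospinal-fluid-like electrolyte); values are
# typical literature figures, not part of the particle constant table.
electrolyte:
  name: CSF
  sigma: 1.79
  chi0: 0.0
  lambda_s_ppm: null
  density: 1007.0
  Ms: 0.0
  poisson: null
  eps_r: [80.0, 80.0, 80.0]
  youngs_GPa: null
  elasticity_voigt_GPa: null
  coupling_voigt: null

# Magnetite-like superparamagnetic iron oxide preset used for the MPI
# harmonic benchmark (30 nm particle, Langevin saturation 347.1 kA/m).
spion:
  name: SPION
  sigma: 2.5e4
  chi0: null
  lambda_s_ppm: null
  density: 5170.0
  Ms: 347100.0
  poisson: null
  eps_r: [20.0, 20.0, 20.0]
  youngs_GPa: null
  elasticity_voigt_GPa: null
  coupling_voigt: null
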