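# Consensus dosimetry dataset for the IR06-type Pd-103 brachytherapy seed.
# Units are explicit per section; g and F values are unitless TG-43 functions.
source:
  name: IR06-Pd103
  medium: perspex
lambda:
  units: cGy/(h*U)
  experimental: {value: 0.689, sigma: 0.058, method: TLD, medium: perspex}
  monte_carlo: {value: 0.691, sigma: 0.021, method: MCNP5, medium: perspex}
  monte_carlo_water: {value: 0.692, sigma: 0.021}
  consensus: 0.690
geometry:
  units: cm
  physical_length: 0.47
  active_length: 0.30
  capsule_outer_diameter: 0.08
  capsule_inner_diameter: 0.07
  end_cap_thickness: 0.06
  bead_count: 5
  bead_diameter: 0.06
  capsule_material: titanium
  core_material: resin
  core_mass_fractions: {H: 0.08, C: 0.90, N: 0.003, Cl: 0.007, Pd: 0.01}
nuclide:
  name: Pd-103
  half_life_days: 16.991
  spectrum: []
g_table:
  units: {radii: cm}
  radii: [0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0]
  geometry_model: line
  reference_radius: 1.0
  consensus_column: water_mc
  columns:
    water_mc:    [1.42, 1.000, 0.822, 0.668, 0.426, 0.264, 0.161]
    perspex_mc:  [1.448, 1.000, 0.817, 0.668, 0.422, 0.264, 0.156]
    perspex_tld: [1.49, 1.000, 0.841, 0.689, 0.431, 0.276, 0.168]
F_table:
  units: {radii: cm, angles: deg}
  radii: [0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0]
  angles: [0, 10, 20, 30, 40, 50, 60, 70, 80, 90]
  values:
    - [0.053, 0.074, 0.616, 0.854, 0.924, 0.959, 0.979, 0.992, 0.998, 1.000]
    - [0.132, 0.165, 0.472, 0.701, 0.845, 0.927, 0.964, 0.985, 0.996, 1.000]
    - [0.190, 0.242, 0.491, 0.686, 0.816, 0.903, 0.956, 0.982, 0.996, 1.000]
    - [0.229, 0.281, 0.512, 0.692, 0.813, 0.899, 0.952, 0.982, 0.995, 1.000]
    - [0.265, 0.309, 0.526, 0.696, 0.814, 0.896, 0.950, 0.982, 0.996, 1.000]
    - [0.294, 0.345, 0.545, 0.705, 0.815, 0.897, 0.949, 0.981, 0.997, 1.000]
    - [0.319, 0.369, 0.558, 0.709, 0.818, 0.895, 0.948, 0.979, 0.995, 1.000]
    - [0.337, 0.392, 0.568, 0.715, 0.820, 0.900, 0.948, 0.981, 0.995, 1.000]
# Sparse TLD-measured anisotropy values kept separate from the dense Monte
# Carlo lattice: the two methods have different angular support.
F_measured:
  radii: [1.5, 2.0, 3.0, 5.0]
  angles: [0, 30, 60]
  values:
    - [0.209, 0.656, 0.920]
    - [0.253, 0.675, 0.921]
    - [0.270, 0.681, 0.925]
    - [0.301, 0.682, 0.905]
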