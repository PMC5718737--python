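# Dose-rate constants (cGy/(h*U)) for comparable commercial Pd-103 seeds,
# as compiled for the IR06 comparison. "benchmark" rows are this toolkit's
# packaged benchmark values; "published" rows are the literature references
# a comparison report is made against.
records:
  - {source: Theragenics 200, method: Monte Carlo simulation (MCNP5), medium: liquid water,
     value: 0.685, sigma: 0.021, citation: benchmark}
  - {source: Theragenics 200, method: Monte Carlo simulation, medium: liquid water,
     value: 0.686, sigma: 0.030, citation: published}
  - {source: Theragenics 200, method: TLD dosimetry, medium: solid water,
     value: 0.650, sigma: 0.080, citation: published}
  - {source: MED3633, method: Monte Carlo simulation, medium: liquid water,
     value: 0.677, sigma: 0.020, citation: published}
  - {source: MED3633, method: TLD dosimetry, medium: liquid water,
     value: 0.680, sigma: 0.050, citation: published}
  - {source: Best double-wall, method: TLD dosimetry, medium: solid water,
     value: 0.69, sigma: 0.08, citation: published}
  - {source: Best double-wall, method: Monte Carlo simulation, medium: liquid water,
     value: 0.67, sigma: 0.02, citation: published}
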