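# Two phenotypes predicted to converge to a common operational CheY-P
# while drifting in a steep exponential gradient.
environment:
  L0: 200.0        # µM at the origin
  g: 0.001         # 1/µm (gradient length scale 1000 µm)
phenotypes:
  - {Y0: 2.6, tau: 10}
  - {Y0: 3.0, tau: 30}
simulation:
  n_cells: 2000
  T: 300.0
  dt: 0.01
  window: [60.0, 300.0]
  seed: 1
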