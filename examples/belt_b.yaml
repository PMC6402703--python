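# A commercial lumbar belt chaining a double-face plain weave, a narrow
# plain-weave ribbon (single tested direction) and a laminated knit
# (catalog Belt B, k_eq ~ 11.17 kN/m).
schema: 1
name: Belt B
height: 0.26
poisson: 0.3
transverse_stiffness: 21641.0
fabrics:
  fabric2: {stiffness_warp: 16611.0, poisson_warp: -0.03, stiffness_weft: 52772.0, poisson_weft: -0.35}
  fabric4: {stiffness_warp: 101433.0, poisson_warp: 0.30}
  fabric5: {stiffness_warp: 51429.0, poisson_warp: 0.46, stiffness_weft: 57470.0, poisson_weft: 0.55}
network:
  - series
  - [leaf, fabric2, warp]
  - [leaf, fabric4, any]
  - [leaf, fabric5, warp]
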