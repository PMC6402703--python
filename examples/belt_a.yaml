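# A commercial lumbar belt assembled from a twill panel and two coated
# plain-weave panels in series (catalog Belt A, k_eq ~ 13.55 kN/m).
schema: 1
name: Belt A
height: 0.26
poisson: 0.3
transverse_stiffness: 11421.5
fabrics:
  fabric1: {stiffness_warp: 39226.0, poisson_warp: -0.08, stiffness_weft: 38948.0, poisson_weft: -0.32}
  fabric3: {stiffness_warp: 41421.0, poisson_warp: 0.52, stiffness_weft: 32321.0, poisson_weft: 0.45}
network:
  - series
  - [leaf, fabric1, warp]
  - [leaf, fabric3, warp]
  - [leaf, fabric3, warp]
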