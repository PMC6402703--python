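# Synthetic torso with a pronounced abdominal protrusion (obese habitus).
# All lengths in meters; see beltsim.trunk_surface.TorsoParams for defaults.
schema: 1
n_theta: 360
n_z: 80
length: 0.40
lateral_radius: 0.17
ap_radius: 0.135
protrusion: 0.07
lordosis_depth: 0.025
lordosis_center: 0.18
furrow_depth: 0.008
noise: 0.002
seed: 42
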