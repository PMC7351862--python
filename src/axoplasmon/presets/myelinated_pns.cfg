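# Myelinated peripheral-nervous-system axon preset.
# Schwann-cell segments of length 2a = 100 um; Ranvier node 0.5 um
# (period/half-length ratio d/a = 2.01; edit node length to 5e-6 or 1e-5
# for d/a = 2.1 or 2.2).  Effective segment self-frequency 4e6 rad/s.

geometry.cord_radius_m = 3.4e-9
geometry.segment_half_length_m = 50e-6
geometry.node_length_m = 0.5e-6
geometry.myelin_thickness_m = 1e-6

medium.eps = 80.0
medium.n_cord_per_m3 = 6e24

segment.omega1_rad_per_s = 4e6

node.gate_activation_time_s = 1e-6
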