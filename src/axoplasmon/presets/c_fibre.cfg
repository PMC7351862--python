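# Unmyelinated C-fibre preset: periodic lipid-raft Na+ channel clusters.
# Raft (node) length 0.1 um with a 5 um raft-to-raft span; no myelin.
# The segment oscillation is red-shifted by trans-membrane damping; the
# damping strength tau*omega1 is a free knob, default 1.5 (oscillatory,
# strongly red-shifted).

geometry.cord_radius_m = 5e-8
geometry.segment_half_length_m = 2.45e-6
geometry.node_length_m = 1e-7

medium.eps = 80.0

segment.omega1_rad_per_s = 4e6
segment.tau_omega1 = 1.5

node.gate_activation_time_s = 1e-6
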