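# Wave-segmentation parameters for 2D cylinder projections.  The two
# lateral sides of the unrolled surface need mirrored reference vectors
# (rx = +/- cos(45 deg)); the field is split at a configurable column and
# polar rows are cropped before analysis.  The dorsal half-plane gate is
# off: only the V/D separation angle constrains the D direction here.
representation = "cylinder"

[reference]
rx_left = -0.7071067811865476   # -cos(45 deg)
rx_right = 0.7071067811865476   # +cos(45 deg)
ry = -0.7071067811865476        # -sin(45 deg)

[params]
theta_r = 50.0
theta_V = 40.0
theta_D = 40.0
theta_VD = 30.0
M_min = 1.0      # px/frame
M_avg = 3.0      # px/frame
M_total = 10.0   # px
window_N = 2
max_gap = 2
enforce_dorsal_halfplane = false
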