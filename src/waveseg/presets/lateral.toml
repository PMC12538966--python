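# Wave-segmentation parameters for 2D lateral maximum intensity projections.
# Anatomical axes: x = anteroposterior, y = dorsal (up); the reference
# vector points posteroventrally along the bisector of the third quadrant.
representation = "lateral"

[reference]
rx = -0.7071067811865476   # -cos(45 deg)
ry = -0.7071067811865476   # -sin(45 deg)
dorsal = "up"

[params]
theta_r = 40.0
theta_V = 60.0
theta_D = 60.0
theta_VD = 30.0
M_min = 0.5      # px/frame
M_avg = 1.0      # px/frame
M_total = 10.0   # px
window_N = 2
max_gap = 2
enforce_dorsal_halfplane = true
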