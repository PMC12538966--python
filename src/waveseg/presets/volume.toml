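# Wave-segmentation parameters for fused 3D volumes (single static
# reference vector tilted 8.4 deg off the sagittal plane).
representation = "volume"

[reference]
rx = -0.14608302856241162  # -sin(8.4 deg)
ry = 0.6995211750783651    # sin(45 deg) * cos(8.4 deg)
rz = -0.6995211750783652   # -cos(45 deg) * cos(8.4 deg)
dorsal = "up"

[params]
theta_r = 50.0
theta_V = 60.0
theta_D = 60.0
theta_VD = 30.0
M_min = 0.5      # vx/frame
M_avg = 1.0      # vx/frame
M_total = 10.0   # vx
window_N = 2
max_gap = 2
enforce_dorsal_halfplane = true
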