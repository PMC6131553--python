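"""Velocity correlation length of a gridded flow field.

Generates two synthetic PIV-like fields — one spatially smoothed
(ordered flow), one with independent vector angles — and computes the
angle-distance curve and the 5-sigma correlation length C_vv: the
largest separation at which vectors still point, on average, within 90
degrees of each other with 5-sigma confidence.
"""

from sheetflock import FlowSpec, angle_correlation_curve, correlation_length, gen_gridded_flow, iop_frame

for label, scale in (("ordered (smoothing 4 windows)", 4.0), ("disordered", 0.0)):
    spec = FlowSpec(
        grid_shape=(48, 48), angular_noise_sd=120.0, correlation_scale=scale,
        window_spacing=90.0, seed=3,
    )
    field = gen_gridded_flow(spec)[0]
    curve = angle_correlation_curve(field)
    c_vv = correlation_length(field)
    print(f"{label}:")
    print(f"  IOP = {iop_frame(field):.3f}")
    print(f"  C_vv = {c_vv:.0f} µm  ({c_vv / spec.window_spacing:.0f} windows)")
    for k in (0, 1, 3, 7, 15):
        print(
            f"  theta({curve.r_um[k]:6.0f} µm) = {curve.theta_mean_deg[k]:5.1f}"
            f" ± {curve.theta_sem_deg[k]:.1f} deg  (n={curve.n_samples[k]})"
        )
# The smoothed field stays far below 90 deg over many windows (large
# C_vv); independent angles average ~90 deg everywhere, so C_vv = 0.
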