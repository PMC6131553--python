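"""Division-direction order statistics and pre-mitotic nuclear motion.

Draws division angles from a concentrated and a uniform circular law and
summarises their common orientation through the resultant-vector
magnitude; then reconstructs the relative nuclear position p(t) of a
nucleus drifting to the cell front before mitosis.
"""

from sheetflock import (
    gen_division_angles,
    gen_premitotic_track,
    direction_order_stats,
    relative_nuclear_position,
    rose_histogram,
)

for label, kappa in (("aligned divisions", 4.0), ("random divisions", 0.0)):
    sample = gen_division_angles(120, mean_angle=15.0, concentration=kappa, seed=2)
    stats = direction_order_stats(sample)
    edges, heights = rose_histogram(sample, n_bins=12)
    print(f"{label} (n=120):")
    print(f"  ||<d>|| = {stats.magnitude:.2f}   <theta> = {stats.mean_angle_deg:.1f} deg")
    print(f"  rose heights: {[round(float(h), 2) for h in heights]}")

series = gen_premitotic_track(n_frames=61, frame_interval=2.0, drift_onset=30.0,
                              jitter_sd=0.3, seed=4)
p = relative_nuclear_position(series)
print("\nrelative nuclear position (0 = near membrane, 0.5 = cell centre):")
for t in (-120, -60, -30, -16, 0):
    row = p[p.t_min == t].iloc[0]
    print(f"  t = {t:4d} min before mitosis: p = {row.p:.2f}")
# ||<d>|| near 1 flags a common division direction; the nucleus holds the
# cell midpoint (p ~ 0.5) and moves membrane-ward in the last ~30 min.
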