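"""Project a simulated scan onto the scanner's angular lattice.

The instrument can present its returns as a cylindrical range map or
intensity map: one cell per (vertical angle, horizontal angle) lattice
direction.  This demo builds both for a small simulated plot.
"""

import numpy as np

import stemscan as ss

config = ss.ScannerConfig(delta_theta=1.0, delta_phi=1.0, range_accuracy_sigma=0.0)
plot = ss.generate_plot(extent=8.0, vacancy_prob=0.0, seed=2)
records, _ = ss.simulate_scan(plot, scanner_pos=(0, 0, 1.5), config=config, seed=0)

for kind in ("range", "intensity"):
    m = ss.build_map(records, config, value_kind=kind)
    filled = m.filled_cells()
    print(
        f"{kind:>9} map: {m.shape[0]} x {m.shape[1]} cells, "
        f"{filled} filled ({100 * filled / m.values.size:.1f}% of the sphere)"
    )

rng_map = ss.build_map(records, config, value_kind="range")
row = rng_map.values[60]  # one horizontal sweep below the horizon
finite = row[np.isfinite(row)]
print(
    f"\nsweep at theta = {rng_map.theta_centers[60]:.1f} deg: "
    f"{finite.size} returns, ranges {finite.min():.2f}-{finite.max():.2f} m"
)
print(
    "\nEmpty cells are sky or out-of-range directions; near-vertical stripes"
    "\nof short ranges in the map are tree trunks standing out of the ground."
)
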