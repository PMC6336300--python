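"""Compare the three circle fitters on a noisy stem arc.

A scanner sees roughly the front half of a stem cross-section.  This demo
fits a half-arc of a 12 cm stem, sampled with 5 mm noise, with the Pratt
and Taubin algebraic methods and Gauss-Newton geometric refinement.
"""

import numpy as np

import stemscan as ss

rng = np.random.default_rng(3)
r_true, center = 0.06, (4.0, 1.0)
t = np.linspace(np.pi * 0.75, np.pi * 1.75, 120)  # half facing the origin
pts = np.column_stack(
    [center[0] + r_true * np.cos(t), center[1] + r_true * np.sin(t)]
) + rng.normal(0, 0.005, (120, 2))

print(f"true circle: center {center}, radius {r_true*100:.2f} cm\n")
for fit in (ss.fit_pratt, ss.fit_taubin, ss.fit_gauss_newton):
    c = fit(pts)
    print(
        f"{c.method:>12}: center ({c.xc:.4f}, {c.yc:.4f}), "
        f"radius {c.r*100:.3f} cm, RMS residual {c.rms_residual*1000:.2f} mm"
    )
print(
    "\nAll three agree to well under a millimetre on an arc like this;"
    "\nthe algebraic fits are non-iterative and fast, which is why the"
    "\npipeline uses the Pratt fit by default."
)
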