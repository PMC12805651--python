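"""Phase-resolved inflation curves: a slow-filling tumor focus vs the whole lung.

Plants spherical foci with delayed filling, then extracts the mean
specific-ventilation curve across the ten breath phases for a small box
around one focus and for the whole lung. The focus curve stays below the
whole-lung curve and dips between the first two post-baseline phases —
the signature of tissue that resists expansion early in the breath.
"""

from xvlung import extract_roi_curve
from xvlung.synth import TumorFociSpec, VirtualLung, generate_phase_series

lung = VirtualLung()
series, ct, truth = generate_phase_series(
    lung, TumorFociSpec(n_foci=3, radius_mm=(0.5, 0.8), fill_delay=1.0, severity=0.5, seed=21)
)

cx, cy, cz = truth.foci_centers_mm[0]
h = 0.4
focus = extract_roi_curve(
    series, ((cx - h, cx + h), (cy - h, cy + h), (cz - h, cz + h)), label="tumor focus"
)
extent = tuple((0.0, s * n) for s, n in zip(series.spacing, series.volumes[0].shape))
whole = extract_roi_curve(series, extent, label="whole lung")

print("phase   whole-lung SV   focus SV")
for k, (w, f) in enumerate(zip(whole.phase_means, focus.phase_means)):
    print(f"{k:>5d}   {w:13.4f}   {f:8.4f}")
print(
    "\nThe whole lung inflates fast early then plateaus; the focus expands\n"
    "slowly, briefly losing specific ventilation early in the breath, and never\n"
    "reaches the surrounding tissue's expansion."
)
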