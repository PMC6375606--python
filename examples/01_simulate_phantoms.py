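"""Generate a small synthetic cine cohort and inspect its annotations.

Each phantom is a transverse cine stack (240x196 px, 1.6 mm pixels, 50
frames) containing a body ellipse, the two aortic cross-sections and a few
distractor vessels; the ground truth records the time-averaged circles on
the standard 480x392 grid plus an image-quality (IQ) grade in 0-3.
"""

import aortafinder as af

cohort = af.generate_cohort(6, iq_mix=(0.2, 0.2, 0.3, 0.3), seed=42)

for series, gt in cohort:
    print(f"{series.scan_id}: shape={series.shape}, IQ={gt.iq:.0f}")
    for name, circle in (("AA", gt.aa), ("PDA", gt.pda)):
        if circle is af.NOT_VISIBLE:
            print(f"  {name}: not visible")
        else:
            r, c = circle.centre_rc
            print(f"  {name}: centre=({r:.1f}, {c:.1f}) px, radius={circle.radius_mm:.1f} mm")

# IQ 0 phantoms simulate a wrong slice location: both vessels are absent
# and annotated as not visible, which is how unusable scans enter training.
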