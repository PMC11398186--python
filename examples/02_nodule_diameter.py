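"""Nodule diameter: from visible chord to real buried-sphere diameter.

A nodule bigger than the visible soil depth L (~1 mm) shows only a chord
of its cross-section, so the observed diameter underestimates the real
one.  This script converts a table of observed mean diameters, then
renders a nodule as a buried-sphere cap, measures it off the mask and
recovers its true diameter through the same conversion.
"""

from rhizocurl import (
    Calibration,
    NoduleSpec,
    SceneSpec,
    apply_conversion_policy,
    detect_nodules,
    observed_diameter,
    render_scene,
)
from rhizocurl.hair_separation import build_graph
from rhizocurl.skeletonize import thin

calib = Calibration(mm_per_pixel=0.01, visible_depth_L=1.0)

print("day   observed d (mm)   real D (mm)   converted?")
for day, d_obs in [(20, 0.71), (25, 1.14), (30, 2.33), (35, 3.33), (40, 3.82), (45, 4.16)]:
    meas = apply_conversion_policy(d_obs, calib, day=day)
    print(f"{day:>3}   {d_obs:15.2f}   {meas.real_D_mm:11.2f}   {meas.converted}")
print("Diameters at or below L = 1 mm are fully visible and stay unconverted.\n")

# now measure a rendered day-45-sized nodule (true D = 5.33 mm) off a mask
spec = SceneSpec(
    image_shape=(900, 900),
    nodules=[NoduleSpec(true_D_mm=5.33, attachment_row=450)],
    seed=5,
)
mask, truth = render_scene(spec)
graph = build_graph(thin(mask), mask)
region = detect_nodules(mask, graph)[0]
d_measured = observed_diameter(mask, region)
result = apply_conversion_policy(d_measured, calib, day=45)
print(f"rendered nodule: true D = 5.33 mm, expected chord = "
      f"{truth.nodules[0].expected_d_mm:.2f} mm")
print(f"measured observed d = {d_measured:.2f} mm -> real D = "
      f"{result.real_D_mm:.2f} mm")
print("The conversion recovers the true diameter from the visible chord.")
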