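"""Depth registration and observation area of an inclined minirhizotron tube.

Maps positions along a 5.5-m tube to soil depth (0.6 m at the first image,
3.0 m at the far end) and shows the observation-area calibration that turns
root length per depth interval into planar root length density (pRLD).
"""

from rhizotrace import TubeGeometry, depth_at_position, observation_area_m2, pixels_to_cm

geom = TubeGeometry()
print(f"images per tube: {geom.n_images} (every {geom.image_step_mm:g} mm)")
for pos in (0.0, 2750.0, 5500.0):
    print(f"tube position {pos:6.0f} mm -> soil depth {depth_at_position(pos, geom):.3f} m")

area = observation_area_m2(0.6, 0.85, geom)
print(f"\nobservation area for the 0.60-0.85 m depth interval: {area:.5f} m^2")
print("(the default image width is calibrated so a 0.25-m interval exposes ~0.0125 m^2)")

print(f"\n250 px at {geom.px_per_cm:g} px/cm -> {pixels_to_cm(250, geom):.2f} cm of root")
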