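"""Fit a nitroxide linewidth-pO2 calibration from three oxygen fractions.

A soluble nitroxide probe is equilibrated at 0, 3 and 21 % O2; the oxygen
fractions convert to partial pressures at one atmosphere (760 torr), and an
ordinary least-squares line maps peak-to-peak linewidth to pO2.
"""

import oxymap as ox

fractions = [0.0, 3.0, 21.0]
# synthetic linewidths: 1.0 G at anoxia, 0.01 G per torr of oxygen
points = [(ox.percent_o2_to_po2(f), 1.0 + 0.01 * ox.percent_o2_to_po2(f)) for f in fractions]
curve = ox.fit_calibration(points)

print("calibration points (pO2 torr, linewidth G):")
for p, w in curve.fit_points:
    print(f"  {p:7.1f}  {w:.3f}")
print(f"intercept: {curve.intercept:.4f} G   (linewidth at zero oxygen)")
print(f"slope:     {curve.slope:.4f} G/torr (oxygen broadening sensitivity)")
print(f"residual:  {curve.residual_rms:.2e} G rms")

lw = curve.linewidth(20.0)
po2, clamped = curve.po2(lw)
print(f"\nround trip: 20 torr -> {lw:.3f} G -> {po2:.6f} torr (clamped: {clamped})")
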