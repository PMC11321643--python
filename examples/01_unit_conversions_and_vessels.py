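"""Oxygen-tension units and vessel geometry.

Converts between the three units O2 is reported in and shows how a
(vessel, volume) pair fixes the media-column height of the 1-D model.
"""

from pericell import MediaColumn, builtin_vessels, convert_tension

print("1 % O2  =", convert_tension(1.0, "percent", "mmHg"), "mmHg")
print("1 % O2  =", round(convert_tension(1.0, "percent", "micromolar"), 3), "uM")
print("10 mmHg =", round(convert_tension(10.0, "mmHg", "percent"), 2),
      "% O2  (median breast-tumor tension)")
print("18.6 % O2 =", round(convert_tension(18.6, "percent", "mmHg"), 1),
      "mmHg  (room-air incubator)")

print("\nBuilt-in vessels and the column height of a typical fill:")
fills = {"96-well": 0.2, "24-well": 1.0, "12-well": 2.0, "6-well": 2.0}
for name, vessel in builtin_vessels().items():
    volume = fills.get(name, 5.0)
    column = MediaColumn(vessel, volume)
    print(f"  {name:9s} {vessel.growth_area_cm2:6.2f} cm2, {volume:4.1f} mL "
          f"-> L = {column.height_cm:.3f} cm")

# Taller columns mean longer diffusion paths: the same medium volume stands
# 5x higher in a 24-well than a 6-well, which is why equilibration and
# pericellular O2 depend so strongly on the vessel.
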