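"""Build the stepped-hypoxia trial protocol and query the arena geometry.

The default trial: 40 min normoxic baseline, then DO on the fish's preferred
side is lowered through 70/50/30/25/20/15/10 % air saturation (10 min ramp +
10 min hold each), then 20 min reoxygenation — 200 min in total, analyzed as
a baseline block plus sixteen 10-min bins.
"""

import shuttlebox as sb

protocol = sb.default_protocol()
print(f"total duration: {protocol.total_min:.0f} min")

print("\nanalysis bins (id, kind, start min, nominal DO %sat):")
for iv in protocol.intervals():
    print(f"  {iv.interval_id:9s} {iv.kind:14s} {iv.start_s / 60:6.1f}   "
          f"{iv.nominal_do:6.1f}")

geometry = sb.ArenaGeometry()
print("\ncompartment centers:", geometry.compartment_centers)
for x, y, label in [(-32.0, 0.0, "left shelter"), (0.0, 0.0, "passage midpoint"),
                    (40.0, 10.0, "right compartment, off-shelter")]:
    z = sb.assign_zone(x, y, geometry)
    print(f"  ({x:6.1f}, {y:5.1f}) -> {z.compartment:8s} "
          f"in_shelter={z.in_shelter}  ({label})")
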