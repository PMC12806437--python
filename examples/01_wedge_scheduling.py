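"""Wedge scheduling arithmetic.

A tomoscopy reconstruction needs a 180-degree half turn per 3D volume.
Assigning each volume a narrow angular wedge of width dtheta instead raises
the temporal resolution by 180/dtheta; this script prints that enhancement
factor, the total swept angle of an acquisition, and how often the same
viewing angle recurs.
"""

from strtomo import build_schedule, revisit_period, temporal_enhancement

for wedge in (3.0, 9.0, 18.0, 0.9):
    print(f"wedge {wedge:5.1f} deg -> temporal enhancement "
          f"{temporal_enhancement(wedge):6.1f}x over tomoscopy")

sched = build_schedule(n_timepoints=75, wedge_deg=3.0, frames_per_rotation=400)
print(f"\n75 time points x 3 deg sweep {sched.total_coverage_deg:.0f} deg in total")
sched = build_schedule(n_timepoints=200, wedge_deg=0.9, frames_per_rotation=400)
print(f"200 time points x 0.9 deg sweep {sched.total_coverage_deg:.0f} deg "
      f"({'single' if sched.single_frame else 'several'} frame(s) per wedge)")

print(f"\nwith 18 deg wedges the same viewing angle recurs every "
      f"{revisit_period(18.0)} time steps; with 7 deg wedges it never "
      f"recurs exactly ({revisit_period(7.0)})")
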