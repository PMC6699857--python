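"""Kovats retention indices from an n-alkane ladder.

Builds a calibration from the n-alkane rows of the packaged compound table
and evaluates a few peaks, including one falling in the C20-C22 gap where
the interpolation spans 200 RI units.
"""

from chcid import fit_ladder, retention_index_flagged, round_ri
from chcid.datasets import load_tf_compounds, nalkane_ladder

anchors = nalkane_ladder(load_tf_compounds())
cal = fit_ladder(anchors)
print(f"calibration from {len(anchors)} n-alkane anchors, "
      f"C{anchors[0][0]}-C{anchors[-1][0]}")

for rt, note in [(14.05, "a methylpentadecane"),
                 (20.50, "an ethyl ester"),
                 (20.98, "an aldehyde in the C20-C22 ladder gap"),
                 (43.29, "a methylnonacosane")]:
    ri, extrapolated = retention_index_flagged(cal, rt)
    flag = " (extrapolated)" if extrapolated else ""
    print(f"  Rt {rt:6.2f} min -> RI {round_ri(ri):4d}{flag}   # {note}")

# An integer RI places a peak on the n-alkane scale: RI 1541 elutes 41% of
# the way from pentadecane (1500) to hexadecane (1600).
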