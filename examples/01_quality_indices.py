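"""Compute the scalar OD / freeze-thaw quality indices from raw measurements.

A cherry tomato weighed before and after 60 min of osmotic dehydration, its
colour before and after, and its weight loss on thawing.
"""

from osmofreeze import (
    ColorReading,
    ODMassRecord,
    ThawWeights,
    delta_e,
    drip_loss,
    is_visible_difference,
    solid_gain,
    water_loss,
)

rec = ODMassRecord(M0=10.0, m0=1.0, M=8.0, m=1.5, t=60.0)
wl = water_loss(rec)
sg = solid_gain(rec)
print(f"water loss  WL = {wl:.2f} g water / g initial dry mass")
print(f"solid gain  SG = {sg:.2f} g solids / g initial dry mass")
# WL = 2.5 means 2.5 g of water left the tissue per gram of its initial dry
# matter; SG = 0.5 means half a gram of osmotic solutes entered per gram.

before = ColorReading(L=30.0, a=20.0, b=13.0)
after = ColorReading(L=27.0, a=16.0, b=13.0)
de = delta_e(after, before)
print(f"colour change dE = {de:.2f} ({'visible' if is_visible_difference(de) else 'not visible'})")

dl = drip_loss(ThawWeights(w_before=10.0, w_after=9.2))
print(f"drip loss = {dl:.1f} % of the frozen weight lost as exudate on thawing")
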