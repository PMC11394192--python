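"""Closed-form shelf lives of frozen cherry tomato from the kinetic presets.

Vitamin C and lycopene decay first-order (limit: 50% retention); the sensory
score decays zero-order (limit: score 4 on the 9-point scale).  Rates scale
with temperature via the Arrhenius model anchored at T_ref = −18 °C.
"""

from osmofreeze import presets, rate_at, shelf_life

print("quality        treatment   k(-18 °C)/d   E_a kJ/mol   SL(-18 °C) d")
for (quality, treatment), model in sorted(presets.KINETIC_PRESETS.items()):
    sl = shelf_life(model, -18.0)
    print(f"{quality:<14} {treatment:<10}  {model.k_ref:<12.4g} "
          f"{model.E_a / 1000:<12.4g} {sl:8.0f}")

# sensory rejection is the shelf-life-limiting criterion for both treatments;
# OD pretreatment roughly halves the sensory loss rate (0.009 vs 0.017 /d)
# and raises the starting score (9.0 vs 7.1), extending shelf life ~3x.
u = presets.KINETIC_PRESETS[("sensory", "untreated")]
o = presets.KINETIC_PRESETS[("sensory", "od")]
for T in (-5.0, -18.0, -23.0):
    print(f"sensory SL at {T:>5} °C: untreated {shelf_life(u, T):6.0f} d, "
          f"OD {shelf_life(o, T):6.0f} d "
          f"(rates {rate_at(u, T):.4f} vs {rate_at(o, T):.4f} /d)")
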