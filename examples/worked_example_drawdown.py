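"""CO2 drawdown through the boundary layer and stomata at two wind speeds.

A leaf assimilating 20 umol m-2 s-1 with stomatal conductance 0.4 mol m-2
s-1 sits in air at 420 umol mol-1 CO2 and 25 degC.  Fick's law splits the
CO2 drop from ambient air to the intercellular airspace into a
boundary-layer step (Ca -> Cs) and a stomatal step (Cs -> Ci).
"""

from leafwind import worked_example

res = worked_example()
cols = ["scenario", "u", "gbw_one_sided", "Cs", "Ci",
        "bl_drawdown_pct_rounded", "stomatal_drawdown_pct_rounded"]
print(res.table[cols].round(3).to_string(index=False))
# At 0.15 m s-1 the boundary layer removes ~17% of the CO2 before the
# stomata act (a co-limiting resistance); at 1.0 m s-1 only ~6% — wind
# thins the boundary layer and hands control back to the stomata.
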