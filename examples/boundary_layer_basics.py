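"""Boundary-layer conductance from wind speed, leaf size and buoyancy.

Evaluates the forced-laminar flat-plate formula for a mid-sized leaf at two
wind speeds, the free-convection conductance for a sun-warmed leaf in still
air, and the blending options for the mixed regime.
"""

from leafwind import air_properties, gb_combine, gb_forced_laminar, gb_free_convection

props = air_properties(T=25.0)

L = 0.0825  # leaf characteristic dimension, m
for u in (0.15, 1.0):
    g = gb_forced_laminar(u, L, props, "water")
    print(f"u = {u:4.2f} m s-1 -> one-sided gbw = {g:.3f} mol m-2 s-1")
# A ~7x wind increase only ~2.6x the conductance (sqrt law): at the low
# wind speeds of greenhouses, small airflow changes move gbw a lot.

g_free = gb_free_convection(dT=5.0, L=L, props=props, species="water")
print(f"\nstill air, leaf 5 K warmer than air -> free-convection gbw = {g_free:.3f}")

g_forced = gb_forced_laminar(0.1, L, props, "water")
for mode in ("max", "parallel_sum", "smooth"):
    print(f"mixed regime ({mode:12s}): {gb_combine(g_forced, g_free, mode):.3f}")
# The three blends bracket the plausible mixed-convection conductance when
# weak wind and buoyancy act together.
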