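"""Frozen-drive phase plane: how the nullcline intersections move.

The dendrite talks to the soma only through the internal current I_DS.
Freezing I_DS turns the soma into a 2D (V_S, w) system whose V_S- and
w-nullclines intersect three times at rest (node, saddle, unstable point);
raising the drive lifts the V_S-nullcline until node and saddle annihilate.
"""

import bacfire as bf

p = bf.default_parameters()

for i_s in (10.0, 40.0):
    eqs = None
    try:
        eq = bf.find_resting_state("5d", p, I_S=i_s)
        ids = p.coupling.g_c * (eq[2] - eq[0])
    except bf.NoStableRestingState:
        ids = 0.0
    ctx = bf.FrozenDriveContext(I_S=i_s, I_DS_eff=ids)
    fps = bf.fixed_points_2d(ctx, p)
    print(f"I_S = {i_s:.0f} uA/cm^2 (frozen I_DS = {ids:+.2f}):")
    if not fps:
        print("   no fixed points in range - the trajectory has nowhere to "
              "rest and circulates on the limit cycle (repetitive APs)")
    for fp in fps:
        print(f"   V_S = {fp.V_S:7.2f} mV, w = {fp.w:.4f}  [{fp.kind}]")
print("Losing the stable node is what converts quiescence into spiking.")
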