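"""In-silico sweep over enzyme loading and particle radius.

Reproduces the design question the simulator exists for: when does extra
cellulase pay off?  Small particles are reaction-limited (little benefit
beyond full surface coverage, e_l = 1), large particles are
diffusion-limited and keep benefiting from the steeper concentration
gradient that excess enzyme maintains.
"""

import lignosim as ls
from lignosim.scenarios import ScenarioConfig

config = ScenarioConfig(
    substrate="severe",
    seed=1,
    e_l=[0.5, 1.0, 2.0],
    b_l=[0.02],
    radius_cm=[12.5e-4, 0.02, 0.08],  # 25 um, 400 um, 1.6 mm diameter
    times_min=[60.0, 600.0],          # 1 h and 10 h
    n=16,
)
table = ls.sweep(config)

ok = table[table.status == "ok"]
for t in (60.0, 600.0):
    snap = ok[ok.time_min == t]
    print(f"glucose yield after {t / 60:.0f} h:")
    print(snap.pivot_table(index="radius_cm", columns="e_l",
                           values="yield_fraction").round(4))
    for r, grp in snap.groupby("radius_cm"):
        g = grp.sort_values("e_l")["yield_fraction"].to_numpy()
        print(f"  R = {r * 1e4:7.1f} um: gain from e_l 1 -> 2 = {g[2] - g[1]:+.4f}")
    print()

# The 25 um particle is covered almost instantly, so doubling the enzyme
# beyond full coverage barely moves the 1 h yield; the larger particles are
# penetration-limited and keep profiting from the steeper gradient.
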