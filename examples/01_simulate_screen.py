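"""Generate a synthetic pooled chronological-lifespan screen.

Two replicate pools of deletion strains age together in one culture; each
strain dies along its own sigmoid, and at days 3/9/11/15/20 we read out
per-tag barcode intensities plus a pool-level CFU/mL count.  Ground truth
(which strains were planted short-/long-lived) is kept for later scoring.
"""

from chronoscreen import ScreenConfig, simulate_screen

config = ScreenConfig(n_strains=500, seed=1)
truth, viable, pool_cfu, intensities = simulate_screen(config)

print("planted classes:", truth.table["true_class"].value_counts().to_dict())
print("pool survival (replicate 1, % of day 3):")
rep1 = pool_cfu[pool_cfu["replicate"] == 1]
for _, row in rep1.iterrows():
    print(f"  day {int(row.day):2d}: {row.percent_survival:6.1f}%")
print(f"{len(intensities)} tag-intensity records "
      f"({config.n_strains} strains x 2 tags x 2 replicates x 5 days)")

# The percent column falls from 100% at day 3 and can bump upward late if
# regrowing strains re-enter the cell cycle (the adaptive-regrowth artifact).
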