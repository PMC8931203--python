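"""Delineate simulated PET tumors and extract SUV metrics.

The Nestle adaptive threshold T = beta * I70 + I_bg (beta = 0.3)
segments each tumor inside a seed box; SUVmax, SUVmean, metabolic tumor
volume (MTV) and total lesion glycolysis (TLG) are measured, and SUVmax
is correlated with pseudotime.
"""

from scipy.stats import pearsonr

import bulktime as bt

cfg = bt.SimulationConfig(n_samples=300, n_genes=50, seed=1, n_pet=30)
_, _, truth = bt.simulate_cohort(cfg)
pet = bt.simulate_pet(truth, cfg)

suvmax, dice = [], []
for vol, true_mask, box in zip(pet.volumes, pet.true_masks, pet.seed_boxes):
    mask, thr = bt.segment_nestle(vol, box, beta=0.3)
    m = bt.suv_metrics(vol, mask, thr)
    suvmax.append(m.suv_max)
    dice.append(2 * (mask & true_mask).sum() / (mask.sum() + true_mask.sum()))

first = bt.suv_metrics(pet.volumes[0], bt.segment_nestle(pet.volumes[0], pet.seed_boxes[0])[0])
print(f"first tumor: SUVmax {first.suv_max:.2f}, SUVmean {first.suv_mean:.2f}, "
      f"MTV {first.mtv_ml:.2f} mL, TLG {first.tlg:.2f}")
print(f"segmentation Dice vs true mask: min {min(dice):.3f}, mean {sum(dice)/len(dice):.3f}")

r, p = pearsonr(suvmax, truth.z_true[: len(suvmax)])
print(f"SUVmax vs pseudotime: r = {r:.3f} (p = {p:.2g})")
print("Positive r reproduces the expected rise of glucose uptake with "
      "tumor progression; Dice near 1 shows the adaptive threshold "
      "recovers the true tumor volume.")
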