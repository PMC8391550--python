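"""Per-class spectral distributions, with and without SNV normalization.

Prints the mean relative absorption and spread of each tissue class, then the
pairwise distances that define the recognition problem's difficulty: muscle,
nerve and fat are deliberately the most similar classes (nerves are routinely
confused with the muscle they run across), while vein and skin stand apart.
SNV removes per-pixel illumination gain/offset, shrinking intra-class spread —
at the cost of some inter-class contrast.
"""

import numpy as np

from hsitissue import SceneConfig, build_dataset, class_spectral_stats, make_cohort

cohort = make_cohort(SceneConfig(seed=0), 3)

for normalization in ("none", "snv"):
    dataset = build_dataset(cohort, normalization=normalization)
    stats = class_spectral_stats(dataset)
    print(f"\nnormalization = {normalization}")
    for label, block in stats.groupby("class"):
        print(f"  {label:7s} mean absorption {block['mean'].mean():7.3f}  "
              f"mean per-band sd {block['sd'].mean():.3f}")

dataset = build_dataset(cohort)
stats = class_spectral_stats(dataset)
means = {label: block["mean"].to_numpy() for label, block in stats.groupby("class")}
print("\nmean-curve distance to muscle (no SNV):")
for label in sorted(means):
    if label != "muscle":
        d = np.linalg.norm(means[label] - means["muscle"]) / np.sqrt(100)
        print(f"  {label:7s} {d:.3f}")
print("smaller = harder to tell apart from muscle; nerve should be closest.")
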