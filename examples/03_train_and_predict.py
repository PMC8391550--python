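"""Train the 3-D CNN on two subjects and predict a third, unseen one.

The CNN consumes 5 x 5 x 100 sub-volumes centered on each annotated pixel and
is trained with Adam (learning rate 0.001) on class-weighted cross-entropy.
Prediction on the held-out subject reports per-class sensitivity and writes an
error-map PNG: black where predictions agree with the annotations, otherwise
the color of the incorrectly predicted class.
"""

from pathlib import Path

import numpy as np
from PIL import Image

from hsitissue import (
    CNNConfig,
    SceneConfig,
    build_cnn,
    build_dataset,
    make_cohort,
    one_vs_all_metrics,
    predict_image,
    train_cnn,
)
from hsitissue.report import error_map

cohort = make_cohort(SceneConfig(seed=0), 3)
train_subjects, held_out = cohort[:2], cohort[2]

dataset = build_dataset(train_subjects)
config = CNNConfig(epochs=10, batch_size=32, seed=0)
model = train_cnn(build_cnn(config), dataset, config)
print(f"trained on {len(dataset)} sub-volumes from "
      f"{sorted(set(dataset.subject_ids))}; final loss "
      f"{model.training_log[-1][1]:.4f}")

mask = held_out.mask
pixels = [(r, c) for r, c in zip(*np.nonzero(mask.labels))]
label_map, _ = predict_image(model, held_out.cube, pixels=pixels)

true = mask.labels[mask.labels > 0]
pred = label_map[mask.labels > 0]
print(f"\nheld-out subject {held_out.subject_id}, per-class sensitivity:")
for code in mask.class_set.codes:
    m = one_vs_all_metrics(true, pred, code)
    print(f"  {mask.class_set.label(code):7s} {m['sensitivity']:.3f}")

out = Path("scratch/error_map.png")
out.parent.mkdir(exist_ok=True)
Image.fromarray(error_map(mask, label_map)).save(out)
print(f"\nerror map written to {out} (black = correct or unlabeled)")
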