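"""Generate a synthetic annotated cohort and look at its composition.

Each subject is a 64 x 64 x 100 hypercube (500-1000 nm) of a dissected-neck
scene — skin background, fat margin, muscle block, artery/vein tubes, a
one-pixel-wide nerve and a metal retractor bar — plus a sparse annotation mask
covering the eroded core of each structure. The printed counts show the severe
class imbalance the classifiers must cope with: skin and muscle dominate while
the nerve is rarest.
"""

from hsitissue import SceneConfig, make_cohort, write_cohort

config = SceneConfig(seed=0)
cohort = make_cohort(config, n_subjects=8)

print(f"cohort: {len(cohort)} subjects, scenes {config.height} x {config.width} "
      f"x {config.n_bands} bands")
for subject in cohort[:3]:
    counts = subject.mask.class_counts()
    named = {config.class_set.label(c): n for c, n in sorted(counts.items())}
    print(f"  {subject.subject_id}: {subject.mask.n_annotated()} annotated px  {named}")

manifest = write_cohort(cohort, "scratch/example_cohort", seed=0)
print(f"written to scratch/example_cohort ({len(manifest['subjects'])} subject dirs "
      "of ENVI cube + indexed-PNG mask)")
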