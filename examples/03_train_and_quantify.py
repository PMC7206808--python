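"""Train a small segmentation network on phantoms and quantify images.

Uses the desk-scale study profile (128-px phantoms, depth-3/base-8 U-Net,
50 short epochs) so the whole script runs in about two minutes on one CPU.
The full-scale operating point — 384-px images, the deep U-Net with 487,730
parameters, 650 epochs — is the same code with different configs.

Run:  python examples/03_train_and_quantify.py
"""

from nervetrace import analyze_image, generate_dataset, train_final
from nervetrace.profiles import (
    demo_model_config,
    demo_phantom_config,
    demo_train_config,
)

samples = generate_dataset(n_subjects=4, images_per_subject=3,
                           cfg=demo_phantom_config(128), seed=1)
train_set, held_out = samples[:9], samples[9:]

print(f"training on {len(train_set)} images "
      f"({len({s.subject_id for s in train_set})} subjects) ...")
trained = train_final(train_set,
                      model_cfg=demo_model_config(128),
                      train_cfg=demo_train_config(epochs=50, seed=0))
print(f"best validation loss: {min(trained.history['val_loss']):.4f}")

print(f"\n{'image':<12} {'true CNFL':>10} {'predicted':>10} {'FD':>6} {'parts':>6}")
for s in held_out:
    rec = analyze_image(s.image, trained)
    print(f"{s.image_id:<12} {s.true_cnfl:>10.2f} {rec.cnfl_mm_per_mm2:>10.2f} "
          f"{rec.fractal_dimension:>6.2f} {rec.n_components:>6d}")
print("\n(held-out subject: the model never saw any image of this animal)")
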