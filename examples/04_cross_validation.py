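"""Subject-wise cross-validation of the full pipeline on phantoms.

Folds partition subjects, never images: no animal contributes to both the
training and the test side of any fold. Held-out predictions from all folds
are pooled into one predicted-vs-reference CNFL comparison, summarized by
R^2 and Bland-Altman limits of agreement.

This is the package's acceptance experiment (about 7-8 minutes on one CPU);
pass smaller numbers to make it quicker.

Run:  python examples/04_cross_validation.py
"""

from nervetrace import cross_validate, generate_dataset
from nervetrace.profiles import (
    demo_model_config,
    demo_phantom_config,
    demo_train_config,
)

samples = generate_dataset(n_subjects=10, images_per_subject=3,
                           cfg=demo_phantom_config(128), seed=0)
report = cross_validate(samples, k=5,
                        model_cfg=demo_model_config(128),
                        train_cfg=demo_train_config(seed=0), seed=0)

print(report.per_image.to_string(index=False))
print(f"\npooled R^2 = {report.pooled_r2:.3f}")
ba = report.bland_altman
print(f"Bland-Altman: mean difference {ba.mean_diff:+.2f} mm/mm^2, "
      f"RPC {ba.rpc:.2f} (LoA [{ba.loa_low:.2f}, {ba.loa_high:.2f}])")
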