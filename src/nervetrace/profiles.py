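"""Desk-scale study profiles.

The full-scale operating point (384-px images, the deep U-Net, 650 epochs)
is config-reachable but impractical for routine verification on a laptop
CPU. These profiles fix, in one place, the reduced problem sizes used by the
demo cross-validation experiment: 128-px phantoms, a depth-3/base-8 U-Net
and a short foreground-weighted training run. They are deliberately chosen
once and shared by the CLI, the examples and the validation scripts so all
of them exercise identical study conditions.
"""

from __future__ import annotations

from .model import AugmentConfig, ModelConfig, TrainConfig
from .phantom import PhantomConfig

__all__ = ["demo_phantom_config", "demo_model_config", "demo_train_config"]


def demo_phantom_config(size_px: int = 128) -> PhantomConfig:
    """Phantoms for desk-scale runs: same appearance model, smaller canvas.

    Cell-confounder counts scale with area so clutter density matches the
    native 384-px configuration; the along-nerve fade period shortens so
    nerves still fade in and out within the smaller field of view.
    """
    scale = size_px / 384.0
    return PhantomConfig(
        size_px=size_px,
        n_cells=(max(1, round(5 * scale**2)), max(2, round(25 * scale**2))),
        fade_period_px=max(60.0, 150.0 * scale),
    )


def demo_model_config(size_px: int = 128) -> ModelConfig:
    """A small U-Net (depth 3, base 8) sufficient for phantom nerve ridges.

    Dropout is disabled: regularization noise is counterproductive in runs
    this short, and the phantom task has ample data relative to ~25k weights.
    """
    return ModelConfig(
        architecture="unet",
        depth=3,
        base_filters=8,
        dropout_rate=0.0,
        input_size_px=size_px,
    )


def demo_train_config(epochs: int = 50, seed: int = 0) -> TrainConfig:
    """Short training run for the demo profile.

    Batch size 4 (rather than the full-scale 8) doubles the number of Adam
    steps per epoch, which is what convergence is limited by on a ~25-image
    training set; foreground weighting (nerve pixels are ~4% of a phantom)
    speeds up recall of faint fading segments; light augmentation keeps the
    runs quick.
    """
    return TrainConfig(
        epochs=epochs,
        batch_size=4,
        lr_initial=2e-3,
        seed=seed,
        foreground_weight=4.0,
        augmentation=AugmentConfig(
            rotation_degrees_max=10.0,
            skew_shear_max=0.05,
        ),
    )
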