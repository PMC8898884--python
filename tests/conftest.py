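import numpy as np
import pytest

from cytosemi import DEFAULT_CLASS_DEFS, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Four nucleated families, 30 crops each, clean images."""
    spec = tuple(DEFAULT_CLASS_DEFS[n]
                 for n in ("single_round", "pyknotic", "abnormal", "lobed"))
    cfg = SyntheticConfig(class_spec=spec, per_class_counts=(30,) * 4,
                          blur_fraction=0.0, noise_sigma=1.0, seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def blurred_half_dataset():
    """Single high-contrast family, half the crops strongly blurred.

    Dense pyknotic nuclei keep the within-family focus-score spread small
    relative to the blur-induced gap, so the mean threshold separates
    sharp from blurred cleanly."""
    spec = (DEFAULT_CLASS_DEFS["pyknotic"],)
    cfg = SyntheticConfig(class_spec=spec, per_class_counts=(40,),
                          blur_fraction=0.5, blur_sigma_range=(2.5, 3.5),
                          noise_sigma=0.0, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def separable_two_class():
    """Trivially separable two-class image set (dark vs light discs)."""
    rng = np.random.default_rng(3)
    images, labels = [], []
    for _ in range(60):
        dark = np.clip(rng.normal(40, 8, (16, 16)), 0, 255).astype(np.uint8)
        light = np.clip(rng.normal(210, 8, (16, 16)), 0, 255).astype(np.uint8)
        images += [dark, light]
        labels += [0, 1]
    return images, np.array(labels)
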