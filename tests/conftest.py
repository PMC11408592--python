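import pytest

import kidneyfusion as kf


@pytest.fixture(scope="session")
def small_manifest(tmp_path_factory):
    """40 synthetic images (10 per class) at 64 px, written once per session."""
    out = tmp_path_factory.mktemp("synth64")
    return kf.generate_synthetic_dataset(
        {c: 10 for c in kf.CLASSES}, image_size=64, seed=123, out_dir=out
    )


@pytest.fixture(scope="session")
def small_aug():
    """Transform stack matched to the 64 px fixture images."""
    return kf.AugmentationConfig(resize_to=(72, 72), center_crop=(64, 64))


@pytest.fixture(scope="session")
def tiny_fused():
    return kf.build_fused_classifier(
        kf.lookup("tiny_a"), kf.lookup("tiny_b"), head_seed=11
    )
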