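"""Single and concatenated (feature-fusion) classifiers.

A classifier is one or two frozen feature extractors whose outputs are
concatenated (extractor A's features always first) and mapped to class
logits by a single trainable linear layer with bias.  The head is the only
trainable component: its parameter count is ``(dim_a + dim_b) * C + C``.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .backbones import BackboneSpec, build_feature_extractor, count_parameters
from .datapipe import CLASSES


class FusedClassifier(nn.Module):
    """Frozen extractor(s) -> feature concatenation -> linear head."""

    def __init__(self, extractor_a: nn.Module, extractor_b: nn.Module | None,
                 n_classes: int, class_names=None, head_seed: int = 0):
        super().__init__()
        if n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        self.extractor_a = extractor_a
        self.extractor_b = extractor_b
        dim_a = extractor_a.spec.feature_dim
        dim_b = extractor_b.spec.feature_dim if extractor_b is not None else 0
        self.feature_dim = dim_a + dim_b
        self.n_classes = n_classes
        if class_names is None:
            class_names = CLASSES if n_classes == len(CLASSES) else \
                tuple(f"class_{i}" for i in range(n_classes))
        if len(class_names) != n_classes:
            raise ValueError("class_names length must equal n_classes")
        self.class_names = tuple(class_names)
        rng = np.random.default_rng(np.random.SeedSequence((head_seed, 0x4EAD)))
        self.head = nn.Linear(rng, self.feature_dim, n_classes)
        # head init: small, so initial logits are near-uniform
        self.head.weight.data *= np.float32(0.1)

    def _check_images(self, images):
        images = np.asarray(images, dtype=np.float32)
        if images.ndim != 4 or images.shape[1] != 3:
            raise ValueError(f"expected images of shape [B,3,H,W], got {images.shape}")
        if not np.all(np.isfinite(images)):
            raise ValueError("image batch contains non-finite values")
        for ext in (self.extractor_a, self.extractor_b):
            if ext is None:
                continue
            req = ext.spec.input_size
            if req is not None and images.shape[2:] != (req, req):
                raise ValueError(
                    f"{ext.spec.name} expects {req}x{req} input "
                    f"(center-cropped), got {images.shape[2]}x{images.shape[3]}"
                )
        return images

    def features(self, images) -> np.ndarray:
        """Concatenated frozen features, [B, dim_a + dim_b]."""
        images = self._check_images(images)
        fa = self.extractor_a(images)
        if self.extractor_b is None:
            return fa
        fb = self.extractor_b(images)
        return np.concatenate([fa, fb], axis=1)

    def forward(self, images) -> np.ndarray:
        return self.head(self.features(images))

    def predict(self, images) -> np.ndarray:
        """Argmax class indices; ties break toward the lowest index."""
        return np.argmax(self.forward(images), axis=1)


def build_single_classifier(spec: BackboneSpec, n_classes: int = 4,
                            class_names=None, weights=None,
                            head_seed: int = 0) -> FusedClassifier:
    """Frozen single-backbone classifier with a trainable linear head."""
    ext = build_feature_extractor(spec, weights=weights)
    return FusedClassifier(ext, None, n_classes, class_names, head_seed)


def build_fused_classifier(spec_a: BackboneSpec, spec_b: BackboneSpec,
                           n_classes: int = 4, class_names=None,
                           weights_a=None, weights_b=None,
                           head_seed: int = 0) -> FusedClassifier:
    """Two frozen backbones, concatenated features, one trainable head.

    ConvNeXt-Large inside a fusion uses its ``drop_norm`` truncation (the
    pre-head layer norm is removed before concatenation).
    """
    if spec_a.name == "convnext_large":
        spec_a = spec_a.with_policy("drop_norm")
    if spec_b.name == "convnext_large":
        spec_b = spec_b.with_policy("drop_norm")
    ext_a = build_feature_extractor(spec_a, weights=weights_a)
    ext_b = build_feature_extractor(spec_b, weights=weights_b)
    return FusedClassifier(ext_a, ext_b, n_classes, class_names, head_seed)


def audit(model: FusedClassifier):
    """Parameter audit of an assembled classifier (delegates to
    :func:`kidneyfusion.backbones.count_parameters`)."""
    return count_parameters(model)
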