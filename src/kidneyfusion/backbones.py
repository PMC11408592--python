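"""Feature-extractor registry, builders, freezing, and parameter audits.

Each backbone is a standard image-classification network with its final
class-mapping layer(s) removed so that it emits a fixed-width feature vector.
Which trailing layers are removed is the *truncation policy*:

* ``alexnet`` — drop only the last 4096->1000 linear of the classic AlexNet
  classifier, keeping both 4096-wide hidden linears (backbone 57,003,840
  parameters, feature width 4096).
* ``vit_b16`` — ViT-Base/16 without its 768->1000 head; the feature is the
  class token after the final layer norm (backbone 85,798,656, width 768).
* ``convnext_large`` — two policies: ``keep_norm`` removes only the
  1536->1000 linear and keeps the pre-head layer norm (196,230,336), while
  ``drop_norm`` also removes that norm's 3,072 parameters (196,227,264).
  Single-backbone classifiers use ``keep_norm``; fused ones use ``drop_norm``.
* ``swin_b`` — Swin-Base without its head (width 1024).  Its reference
  parameter total is deliberately not asserted: the structural count of the
  standard Swin-Base (86,743,224 backbone parameters) is provided for
  information only.
* ``tiny_a`` / ``tiny_b`` — small fixed convnets for desk-scale work, with
  handcrafted (not random) filters standing in for pretrained weights:
  conv1 (3x3, stride 2; 8 resp. 12 channels) is a blur + threshold ladder
  over standardized intensity, conv2 (3x3, stride 2; 16 resp. 24 channels)
  carries per-band band-pass, edge-energy, and mid-intensity-mass
  detectors, and the feature vector concatenates global average and global
  max pooling of every map (4 * bands features: 32 resp. 48).  See
  :class:`_Tiny` for the layer-by-layer account.

Parameter counts depend only on layer shapes, never on the weight values, so
audits are valid under any initialization source.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn

CONVNEXT_EXPECTED = {"keep_norm": 196_230_336, "drop_norm": 196_227_264}


@dataclass(frozen=True)
class BackboneSpec:
    """Descriptor of a registered feature-extractor architecture."""

    name: str
    feature_dim: int
    truncation_policy: str
    frozen: bool = True
    expected_backbone_params: int | None = None
    input_size: int | None = 224  # required H=W; None means size-agnostic

    def __post_init__(self):
        if self.feature_dim <= 0:
            raise ValueError("feature_dim must be positive")

    def with_policy(self, policy: str) -> "BackboneSpec":
        if self.name == "convnext_large":
            if policy not in CONVNEXT_EXPECTED:
                raise ValueError(f"unknown convnext truncation policy {policy!r}")
            return replace(
                self,
                truncation_policy=policy,
                expected_backbone_params=CONVNEXT_EXPECTED[policy],
            )
        if policy != self.truncation_policy:
            raise ValueError(f"{self.name} has a fixed truncation policy")
        return self


@dataclass
class ParamAudit:
    """Exact integer parameter counts of an assembled model."""

    total_params: int
    trainable_params: int
    by_component: list[tuple[str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "total": self.total_params,
            "trainable": self.trainable_params,
            "by_component": [list(t) for t in self.by_component],
        }


def _specs() -> dict[str, BackboneSpec]:
    return {
        s.name: s
        for s in (
            BackboneSpec("alexnet", 4096, "drop_final_linear",
                         expected_backbone_params=57_003_840),
            BackboneSpec("vit_b16", 768, "drop_head",
                         expected_backbone_params=85_798_656),
            BackboneSpec("swin_b", 1024, "drop_head",
                         expected_backbone_params=None),
            BackboneSpec("convnext_large", 1536, "keep_norm",
                         expected_backbone_params=CONVNEXT_EXPECTED["keep_norm"]),
            BackboneSpec("tiny_a", 32, "full", expected_backbone_params=1_392,
                         input_size=None),
            BackboneSpec("tiny_b", 48, "full", expected_backbone_params=2_952,
                         input_size=None),
        )
    }


def registry() -> list[BackboneSpec]:
    """All registered architectures (fresh descriptors)."""
    return list(_specs().values())


def lookup(name: str, policy: str | None = None) -> BackboneSpec:
    specs = _specs()
    if name not in specs:
        raise KeyError(
            f"unknown backbone {name!r}; registered: {', '.join(sorted(specs))}"
        )
    spec = specs[name]
    return spec.with_policy(policy) if policy is not None else spec


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _build_alexnet(rng) -> nn.Module:
    return nn.Sequential(
        nn.Conv2d(rng, 3, 64, 11, stride=4, pad=2), nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.Conv2d(rng, 64, 192, 5, pad=2), nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.Conv2d(rng, 192, 384, 3, pad=1), nn.ReLU(),
        nn.Conv2d(rng, 384, 256, 3, pad=1), nn.ReLU(),
        nn.Conv2d(rng, 256, 256, 3, pad=1), nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.AdaptiveAvgPool2d((6, 6)),
        nn.Flatten(),
        nn.Dropout(0.5), nn.Linear(rng, 256 * 6 * 6, 4096), nn.ReLU(),
        nn.Dropout(0.5), nn.Linear(rng, 4096, 4096), nn.ReLU(),
    )


class _ViTBlock(nn.Module):
    def __init__(self, rng, dim, heads, mlp_dim):
        super().__init__()
        self.ln1 = nn.LayerNorm(dim)
        self.attn = nn.MultiheadSelfAttention(rng, dim, heads)
        self.ln2 = nn.LayerNorm(dim)
        self.mlp = nn.Mlp(rng, dim, mlp_dim)

    def forward(self, x):
        x = x + self.attn(self.ln1(x))
        return x + self.mlp(self.ln2(x))


class _ViT(nn.Module):
    """ViT-Base/16 trunk; feature = class token after the final norm."""

    def __init__(self, rng, dim=768, depth=12, heads=12, mlp_dim=3072,
                 patch=16, image_size=224):
        super().__init__()
        n_patches = (image_size // patch) ** 2
        self.patch = patch
        self.proj = nn.Conv2d(rng, 3, dim, patch, stride=patch)
        cls = np.zeros((1, 1, dim), np.float32) if rng is None else \
            rng.standard_normal((1, 1, dim), dtype=np.float32) * 0.02
        pos = np.zeros((1, n_patches + 1, dim), np.float32) if rng is None else \
            rng.standard_normal((1, n_patches + 1, dim), dtype=np.float32) * 0.02
        self.cls_token = nn.Param(cls)
        self.pos_embed = nn.Param(pos)
        self.blocks = nn.ModuleList(
            _ViTBlock(rng, dim, heads, mlp_dim) for _ in range(depth)
        )
        self.ln = nn.LayerNorm(dim)

    def forward(self, x):
        B = x.shape[0]
        t = self.proj(x)                                   # [B, D, 14, 14]
        t = t.reshape(B, t.shape[1], -1).transpose(0, 2, 1)  # [B, N, D]
        cls = np.broadcast_to(self.cls_token.data, (B, 1, t.shape[2]))
        t = np.concatenate([cls, t], axis=1) + self.pos_embed.data
        for blk in self.blocks:
            t = blk(t)
        return self.ln(t)[:, 0]


class _ConvNeXtBlock(nn.Module):
    def __init__(self, rng, dim):
        super().__init__()
        self.dwconv = nn.Conv2d(rng, dim, dim, 7, pad=3, groups=dim)
        self.norm = nn.LayerNorm(dim)
        self.pwconv1 = nn.Linear(rng, dim, 4 * dim)
        self.act = nn.GELU()
        self.pwconv2 = nn.Linear(rng, 4 * dim, dim)
        self.gamma = nn.Param(np.full(dim, 1e-6, dtype=np.float32))

    def forward(self, x):
        y = self.dwconv(x)
        y = np.moveaxis(y, 1, -1)
        y = self.pwconv2(self.act(self.pwconv1(self.norm(y)))) * self.gamma.data
        return x + np.moveaxis(y, -1, 1)


class _ConvNeXt(nn.Module):
    """ConvNeXt-Large trunk; feature = globally pooled (optionally normed)."""

    def __init__(self, rng, policy: str,
                 depths=(3, 3, 27, 3), dims=(192, 384, 768, 1536)):
        super().__init__()
        self.stem = nn.Sequential(
            nn.Conv2d(rng, 3, dims[0], 4, stride=4), nn.LayerNorm2d(dims[0])
        )
        downs, stages = [], []
        for i, (depth, dim) in enumerate(zip(depths, dims)):
            if i:
                downs.append(nn.Sequential(
                    nn.LayerNorm2d(dims[i - 1]),
                    nn.Conv2d(rng, dims[i - 1], dim, 2, stride=2),
                ))
            stages.append(nn.Sequential(
                *[_ConvNeXtBlock(rng, dim) for _ in range(depth)]
            ))
        self.downsamples = nn.ModuleList(downs)
        self.stages = nn.ModuleList(stages)
        if policy == "keep_norm":
            self.head_norm = nn.LayerNorm(dims[-1])
        else:
            self.head_norm = None

    def forward(self, x):
        x = self.stem(x)
        for i, stage in enumerate(self.stages):
            if i:
                x = self.downsamples.items[i - 1](x)
            x = stage(x)
        feat = x.mean(axis=(2, 3))
        return self.head_norm(feat) if self.head_norm is not None else feat


# ---- Swin ------------------------------------------------------------------

def _window_partition(x, w):
    B, H, W, C = x.shape
    x = x.reshape(B, H // w, w, W // w, w, C).transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(-1, w * w, C)


def _window_reverse(win, w, H, W):
    B = win.shape[0] // ((H // w) * (W // w))
    x = win.reshape(B, H // w, W // w, w, w, -1).transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B, H, W, -1)


def _relative_position_index(w):
    coords = np.stack(np.meshgrid(np.arange(w), np.arange(w), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]
    rel = rel.transpose(1, 2, 0) + (w - 1)
    return rel[..., 0] * (2 * w - 1) + rel[..., 1]


def _shift_mask(H, W, w, shift):
    """Additive attention mask separating non-adjacent regions after a
    cyclic shift; shape [nW, N, N] with 0 / -100 entries."""
    img = np.zeros((1, H, W, 1), np.float32)
    cnt = 0
    slices = (slice(0, -w), slice(-w, -shift), slice(-shift, None))
    for hs in slices:
        for ws in slices:
            img[:, hs, ws, :] = cnt
            cnt += 1
    win = _window_partition(img, w).reshape(-1, w * w)
    mask = win[:, None, :] - win[:, :, None]
    return np.where(mask != 0, np.float32(-100.0), np.float32(0.0))


class _WindowAttention(nn.Module):
    def __init__(self, rng, dim, heads, window):
        super().__init__()
        self.window = window
        self.heads = heads
        self.attn = nn.MultiheadSelfAttention(rng, dim, heads)
        n = (2 * window - 1) ** 2
        table = np.zeros((n, heads), np.float32) if rng is None else \
            rng.standard_normal((n, heads), dtype=np.float32) * 0.02
        self.rel_pos_table = nn.Param(table)
        self._index = _relative_position_index(window)  # buffer, not a Param

    def forward(self, windows, shift_mask=None):
        # windows: [B*nW, N, C]
        bias = self.rel_pos_table.data[self._index]       # [N, N, heads]
        bias = bias.transpose(2, 0, 1)[None]              # [1, heads, N, N]
        if shift_mask is not None:
            nW = shift_mask.shape[0]
            B_ = windows.shape[0]
            mask = np.tile(shift_mask[:, None], (B_ // nW, 1, 1, 1))
            bias = bias + mask
        return self.attn(windows, attn_bias=bias)


class _SwinBlock(nn.Module):
    def __init__(self, rng, dim, heads, window, shift):
        super().__init__()
        self.window, self.shift = window, shift
        self.ln1 = nn.LayerNorm(dim, eps=1e-5)
        self.wattn = _WindowAttention(rng, dim, heads, window)
        self.ln2 = nn.LayerNorm(dim, eps=1e-5)
        self.mlp = nn.Mlp(rng, dim, 4 * dim)

    def forward(self, x):
        B, H, W, C = x.shape
        w = self.window
        shortcut = x
        x = self.ln1(x)
        if self.shift:
            x = np.roll(x, (-self.shift, -self.shift), axis=(1, 2))
            mask = _shift_mask(H, W, w, self.shift)
        else:
            mask = None
        win = _window_partition(x, w)
        win = self.wattn(win, mask)
        x = _window_reverse(win, w, H, W)
        if self.shift:
            x = np.roll(x, (self.shift, self.shift), axis=(1, 2))
        x = shortcut + x
        return x + self.mlp(self.ln2(x))


class _PatchMerging(nn.Module):
    def __init__(self, rng, dim):
        super().__init__()
        self.norm = nn.LayerNorm(4 * dim, eps=1e-5)
        self.reduction = nn.Linear(rng, 4 * dim, 2 * dim, bias=False)

    def forward(self, x):
        x = np.concatenate(
            [x[:, 0::2, 0::2], x[:, 1::2, 0::2], x[:, 0::2, 1::2], x[:, 1::2, 1::2]],
            axis=-1,
        )
        return self.reduction(self.norm(x))


class _Swin(nn.Module):
    """Swin-Base trunk; feature = mean token after the final norm."""

    def __init__(self, rng, embed=128, depths=(2, 2, 18, 2),
                 heads=(4, 8, 16, 32), window=7):
        super().__init__()
        self.patch_embed = nn.Conv2d(rng, 3, embed, 4, stride=4)
        self.embed_norm = nn.LayerNorm(embed, eps=1e-5)
        blocks, merges = [], []
        dim = embed
        for i, (depth, h) in enumerate(zip(depths, heads)):
            blocks.append(nn.ModuleList(
                _SwinBlock(rng, dim, h, window, shift=(window // 2) * (j % 2))
                for j in range(depth)
            ))
            if i < len(depths) - 1:
                merges.append(_PatchMerging(rng, dim))
                dim *= 2
        self.stages = nn.ModuleList(blocks)
        self.merges = nn.ModuleList(merges)
        self.norm = nn.LayerNorm(dim, eps=1e-5)

    def forward(self, x):
        t = self.patch_embed(x)                    # [B, C, 56, 56]
        t = np.moveaxis(t, 1, -1)                  # [B, H, W, C]
        t = self.embed_norm(t)
        for i, stage in enumerate(self.stages):
            for blk in stage:
                t = blk(t)
            if i < len(self.merges.items):
                t = self.merges.items[i](t)
        t = self.norm(t)
        return t.reshape(t.shape[0], -1, t.shape[-1]).mean(axis=1)


class _Tiny(nn.Module):
    """Fixed two-conv stand-in backbone with handcrafted filters.

    Layer sizes: conv1 3->``bands`` (3x3, stride 2) is a blur + threshold
    bank — channel ``k`` responds as ReLU(local mean intensity - t_k) for
    thresholds ``t_k`` evenly spaced over the standardized intensity range
    [-1.5, 2.3] — and conv2 ``bands``->``2*bands`` (3x3, stride 2) carries
    an identity pass-through of each band plus its Laplacian (edge energy).
    The feature vector concatenates global average and global maximum
    pooling of the 2*``bands`` maps: area and peak statistics of each
    intensity band and of its edge response (4*``bands`` features total).

    The filters are deterministic (these stand-ins play the role of
    pretrained weights); a ``"zeros"`` or mapping weights source overrides
    them as for every other backbone.
    """

    def __init__(self, structured: bool, bands: int):
        super().__init__()
        self.conv1 = nn.Conv2d(None, 3, bands, 3, stride=2, pad=1)
        self.conv2 = nn.Conv2d(None, bands, 2 * bands, 3, stride=2, pad=1)
        self.relu = nn.ReLU()
        if structured:
            thresholds = np.linspace(-1.5, 2.3, bands)
            self.conv1.weight.data[:] = np.float32(1.0 / 27.0)
            self.conv1.bias.data[:] = -thresholds.astype(np.float32)
            lap = np.array([[-0.125, -0.125, -0.125],
                            [-0.125, 1.0, -0.125],
                            [-0.125, -0.125, -0.125]], np.float32)
            w2 = np.zeros_like(self.conv2.weight.data)
            for k in range(bands):
                # band-pass: ReLU(z-t_k) - ReLU(z-t_{k+1}) is bounded by the
                # threshold spacing, so every channel reaches the head on a
                # comparable scale (the top channel stays a pass-through)
                w2[k, k, 1, 1] = 1.0
                if k + 1 < bands:
                    w2[k, k + 1, 1, 1] = -1.0
                w2[bands + k, k] = lap        # band edge energy
            # noise floor: only genuinely sharp transitions reach the edge
            # channels, so their pooled statistics are not noise-dominated
            self.conv2.bias.data[bands:] = -0.2
            # one channel detects contiguous intermediate-intensity regions
            # (solid masses neither background-dark nor organ-bright): a
            # center-surround average of a low ladder channel with a strong
            # brighter-channel exclusion; thin bright-to-dark transitions
            # average out, solid mid-intensity interiors do not
            lo = max(1, round(0.13 * (bands - 1)))
            hi = round(0.421 * (bands - 1))
            w2[bands + lo] = 0.0
            w2[bands + lo, lo, :, :] = 1.0 / 9.0
            w2[bands + lo, hi, :, :] = -5.0 / 9.0
            self.conv2.bias.data[bands + lo] = -0.3
            self.conv2.weight.data = w2

    #: fixed rescaling of the average-pooled block so area statistics and
    #: peak statistics reach the linear head on comparable scales
    AVG_GAIN = 16.0

    def forward(self, x):
        x = self.relu(self.conv1(x))
        x = self.relu(self.conv2(x))
        return np.concatenate(
            [x.mean(axis=(2, 3)) * self.AVG_GAIN, x.max(axis=(2, 3))], axis=1
        )


_BUILDERS = {
    "alexnet": lambda rng, spec: _build_alexnet(rng),
    "vit_b16": lambda rng, spec: _ViT(rng),
    "convnext_large": lambda rng, spec: _ConvNeXt(rng, spec.truncation_policy),
    "swin_b": lambda rng, spec: _Swin(rng),
    "tiny_a": lambda rng, spec: _Tiny(rng is not None, 8),
    "tiny_b": lambda rng, spec: _Tiny(rng is not None, 12),
}


def build_feature_extractor(spec: BackboneSpec, weights=None) -> nn.Module:
    """Build the architecture named by ``spec``.

    ``weights`` selects the initialization source: ``None`` for a
    deterministic random draw keyed on the architecture name, an ``int``
    seed, the string ``"zeros"`` (useful for audits, which are
    weight-independent), or a ``{name: array}`` mapping of concrete weights
    (shape-checked; incompatible arrays raise ``ValueError``).
    """
    if spec.name not in _BUILDERS:
        raise KeyError(f"unknown backbone {spec.name!r}")
    if weights is None:
        rng = nn.rng_for(spec.name)
    elif isinstance(weights, (int, np.integer)):
        rng = nn.rng_for(spec.name, seed=int(weights))
    elif weights == "zeros":
        rng = None
    elif isinstance(weights, dict):
        rng = None
    else:
        raise ValueError(f"unsupported weights source: {weights!r}")
    model = _BUILDERS[spec.name](rng, spec)
    if isinstance(weights, dict):
        model.load_state(weights)
    if spec.frozen:
        model.freeze()
    model.eval()
    object.__setattr__(model, "spec", spec)
    return model


def count_parameters(model: nn.Module) -> ParamAudit:
    """Exact parameter audit: every weight/bias array contributes its
    element count; components are the model's top-level children."""
    total = trainable = 0
    comp: dict[str, int] = {}
    for name, p in model.named_parameters():
        n = p.size
        total += n
        if p.trainable:
            trainable += n
        key = name.split(".", 1)[0]
        comp[key] = comp.get(key, 0) + n
    return ParamAudit(total, trainable, list(comp.items()))
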