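"""MSLF-Net: encoder-decoder lesion segmentation with multi-scale,
category-preserving feature fusion.

The network is a U-Net-shaped encoder-decoder.  The encoder follows the
VGG16 convolutional configuration — five stages of widths (64, 128, 256,
512, 512) with 2x max-pooling after the first four, so a 1440x960 input
reaches 90x60x512 at stage five.  The decoder mirrors it with a transition
block at 1/16 scale and four up-sampling steps (2x2 stride-2 transposed
convolutions) with skip concatenation from the encoder, ending in a 1x1
classification head.  That head is kept as a deep-supervision output: it is
trained alongside the fused output and helps suppress background pixels.

Two modules sit on top of the decoder:

* **MSFE** (multi-scale feature extraction) taps the five decoder feature
  maps — scales 1/16, 1/8, 1/4, 1/2 and full resolution — and, per tap,
  applies a residual 3x3 refinement (output *added* to the tap), projects to
  the class count M with a 1x1 convolution, and bilinearly upsamples to full
  resolution.  The full-resolution tap needs no upsampling.

* **MLFF** (multi-level feature fusion) rearranges the five M-channel maps
  into a single 5M-channel stack ordered *category-major* (all five scales
  of class 0, then class 1, ...) and fuses with an M-group 1x1 convolution,
  so each output class channel sees only same-class evidence across scales
  and classes cannot contaminate each other.

Ablation flags reproduce the component study: ``use_msfe=use_mlff=False`` is
the plain U-Net baseline (main output = deep-supervision head);
``use_msfe`` alone fuses the five maps by element-wise mean (simple fusion);
``use_mlff`` enables the full category-major fusion.

Everything runs at any resolution divisible by 16, which makes toy-scale
testing possible; all layers are numpy with explicit backward passes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from .nn import (BilinearUpsample, CategoryGroupedConv1x1, Conv2d,
                 ConvTranspose2d, MaxPool2d, Module, Param, ReLU, softmax)

__all__ = [
    "ModelConfig",
    "FeaturePyramid",
    "Encoder",
    "Decoder",
    "MSFE",
    "MSLFNet",
    "build_encoder",
    "build_decoder",
    "mlff_rearrange",
    "mlff_split_blocks",
]

#: VGG16 convolution counts per stage.
_VGG_STAGE_CONVS = (2, 2, 3, 3, 3)
#: Decoder tap widths in pyramid order A1..A5 (full resolution -> 1/16).
_TAP_WIDTHS = (64, 64, 128, 256, 512)


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    n_classes: int = 5
    input_size: tuple[int, int] = (960, 1440)  # (H, W)
    use_msfe: bool = True
    use_mlff: bool = True
    pretrained_encoder: bool | str = False
    base_channels: tuple[int, int, int, int, int] = (64, 128, 256, 512, 512)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        h, w = self.input_size
        if h % 16 or w % 16:
            raise ValueError(
                f"input size {w}x{h} must be divisible by 16 (four 2x poolings)")


@dataclasses.dataclass
class FeaturePyramid:
    """The five decoder taps A1..A5, full resolution down to 1/16."""

    maps: list[np.ndarray]

    def validate(self) -> None:
        if len(self.maps) != 5:
            raise ValueError("a feature pyramid has exactly 5 levels")
        for a, b in zip(self.maps, self.maps[1:]):
            if (a.shape[2] != 2 * b.shape[2]) or (a.shape[3] != 2 * b.shape[3]):
                raise ValueError("pyramid spatial dims must halve level to level")


class Encoder(Module):
    """Five VGG16-style convolutional stages; pooling after stages 1-4 only."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator) -> None:
        self.config = config
        chans = config.base_channels
        self.stages: list[list[Module]] = []
        cin = 3
        for s, (n_convs, cout) in enumerate(zip(_VGG_STAGE_CONVS, chans)):
            stage: list[Module] = []
            for i in range(n_convs):
                stage.append(Conv2d(cin if i == 0 else cout, cout, 3, rng=rng,
                                    name=f"enc{s + 1}.c{i}"))
                stage.append(ReLU())
                cin = cout
            self.stages.append(stage)
        self.pools = [MaxPool2d() for _ in range(4)]
        if config.pretrained_encoder:
            self._load_pretrained(config.pretrained_encoder)

    def _load_pretrained(self, source: bool | str) -> None:
        if source is True:
            raise ValueError(
                "pretrained_encoder=True requires a path to an .npz of VGG16 "
                "convolutional weights (arrays enc{stage}.c{idx}.w / .b); "
                "automatic download is not supported")
        data = np.load(Path(source))
        for stage in self.stages:
            for layer in stage:
                if isinstance(layer, Conv2d):
                    layer.w.value[...] = data[layer.w.name]
                    layer.b.value[...] = data[layer.b.name]

    def params(self) -> list[Param]:
        return [p for stage in self.stages for layer in stage
                for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = True
                ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Return (pre-pool skip features s1..s5, post-pool stage outputs)."""
        f = x
        skips: list[np.ndarray] = []
        stage_outs: list[np.ndarray] = []
        for s, stage in enumerate(self.stages):
            for layer in stage:
                f = layer.forward(f, train)
            skips.append(f)
            if s < 4:
                f = self.pools[s].forward(f, train)
            stage_outs.append(f)
        return skips, stage_outs

    def backward(self, dskips: list[np.ndarray]) -> np.ndarray:
        d = dskips[4]
        for layer in reversed(self.stages[4]):
            d = layer.backward(d)
        for s in (3, 2, 1, 0):
            d = self.pools[s].backward(d)
            if dskips[s] is not None:
                d = d + dskips[s]
            for layer in reversed(self.stages[s]):
                d = layer.backward(d)
        return d


class Decoder(Module):
    """Transition block at 1/16 plus four up-steps with skip concatenation.

    Produces the five taps of the feature pyramid (widths 512, 256, 128, 64,
    64 from coarse to fine) and the deep-supervision logits from a 1x1 head
    on the full-resolution tap.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator) -> None:
        self.config = config
        cb = config.base_channels
        self.transition: list[Module] = [
            Conv2d(cb[4], 512, 3, rng=rng, name="dec.t0"), ReLU(),
            Conv2d(512, 512, 3, rng=rng, name="dec.t1"), ReLU(),
        ]
        skip_ch = (cb[3], cb[2], cb[1], cb[0])
        out_ws = (256, 128, 64, 64)
        self.steps: list[tuple[ConvTranspose2d, Conv2d, ReLU, Conv2d, ReLU]] = []
        in_w = 512
        for i, out_w in enumerate(out_ws):
            up = ConvTranspose2d(in_w, out_w, rng=rng, name=f"dec.up{i}")
            c1 = Conv2d(out_w + skip_ch[i], out_w, 3, rng=rng, name=f"dec.s{i}c1")
            c2 = Conv2d(out_w, out_w, 3, rng=rng, name=f"dec.s{i}c2")
            self.steps.append((up, c1, ReLU(), c2, ReLU()))
            in_w = out_w
        self.head = Conv2d(64, config.n_classes, 1, rng=rng, name="dec.head")

    def params(self) -> list[Param]:
        out = [p for layer in self.transition for p in layer.params()]
        for step in self.steps:
            for layer in step:
                out.extend(layer.params())
        out.extend(self.head.params())
        return out

    def forward(self, skips: list[np.ndarray], train: bool = True
                ) -> tuple[FeaturePyramid, np.ndarray]:
        f = skips[4]
        for layer in self.transition:
            f = layer.forward(f, train)
        taps = [f]  # coarse (1/16) first, internally
        d = f
        for i, (up, c1, r1, c2, r2) in enumerate(self.steps):
            u = up.forward(d, train)
            skip = skips[3 - i]
            if u.shape[2:] != skip.shape[2:]:
                raise ValueError("up-sampled map and skip feature disagree "
                                 f"in geometry: {u.shape} vs {skip.shape}")
            cat = np.concatenate([u, skip], axis=1)
            if not train:
                skips[3 - i] = None  # release memory during inference
            del u
            d = r2.forward(c2.forward(r1.forward(c1.forward(cat, train), train),
                                      train), train)
            taps.append(d)
        aux = self.head.forward(taps[-1], train)
        pyramid = FeaturePyramid(maps=list(reversed(taps)))
        pyramid.validate()
        return pyramid, aux

    def backward(self, dpyramid: list[np.ndarray] | None,
                 daux: np.ndarray) -> list[np.ndarray]:
        dtaps = ([None] * 5 if dpyramid is None else list(reversed(dpyramid)))
        dskips: list[np.ndarray] = [None] * 5
        d = self.head.backward(daux)
        if dtaps[4] is not None:
            d = d + dtaps[4]
        for i in reversed(range(4)):
            up, c1, r1, c2, r2 = self.steps[i]
            g = c1.backward(r1.backward(c2.backward(r2.backward(d))))
            out_w = up.cout
            dskips[3 - i] = g[:, out_w:]
            d = up.backward(np.ascontiguousarray(g[:, :out_w]))
            if dtaps[i] is not None:
                d = d + dtaps[i]
        for layer in reversed(self.transition):
            d = layer.backward(d)
        dskips[4] = d
        return dskips


class MSFE(Module):
    """Per-scale residual refinement, 1x1 projection to M, upsample to full.

    Each decoder tap is refined by a channel-preserving 3x3 conv + ReLU whose
    output is added back to the tap (the residual "add" fusion), projected to
    M channels, and bilinearly upsampled to the full input resolution.  The
    full-resolution tap is projected only.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator) -> None:
        self.config = config
        self.widths = _TAP_WIDTHS
        self.res = [Conv2d(c, c, 3, rng=rng, name=f"msfe{i}.res")
                    for i, c in enumerate(self.widths)]
        self.relus = [ReLU() for _ in self.widths]
        self.proj = [Conv2d(c, config.n_classes, 1, rng=rng, name=f"msfe{i}.proj")
                     for i, c in enumerate(self.widths)]
        self._ups: list[BilinearUpsample | None] = [None] * 5

    def params(self) -> list[Param]:
        return [p for conv in (*self.res, *self.proj) for p in conv.params()]

    def _upsampler(self, i: int, out_hw: tuple[int, int]) -> BilinearUpsample:
        if self._ups[i] is None or self._ups[i].out_hw != out_hw:
            self._ups[i] = BilinearUpsample(out_hw)
        return self._ups[i]

    def forward(self, pyramid: FeaturePyramid, train: bool = True
                ) -> list[np.ndarray]:
        maps = pyramid.maps if isinstance(pyramid, FeaturePyramid) else pyramid
        if len(maps) != 5:
            raise ValueError("expected 5 decoder taps")
        out_hw = maps[0].shape[2:]
        outs = []
        for i, a in enumerate(maps):
            if a.shape[1] != self.widths[i]:
                raise ValueError(f"tap {i} has {a.shape[1]} channels, "
                                 f"expected {self.widths[i]}")
            refined = a + self.relus[i].forward(self.res[i].forward(a, train),
                                                train)
            p = self.proj[i].forward(refined, train)
            if i > 0:
                p = self._upsampler(i, out_hw).forward(p, train)
            outs.append(p)
        return outs

    def backward(self, dmaps: list[np.ndarray]) -> list[np.ndarray]:
        dpyr = []
        for i, dm in enumerate(dmaps):
            if i > 0:
                dm = self._ups[i].backward(dm)
            dref = self.proj[i].backward(dm)
            da = dref + self.res[i].backward(self.relus[i].backward(dref))
            dpyr.append(da)
        return dpyr


def mlff_rearrange(maps: Sequence[np.ndarray]) -> np.ndarray:
    """Cross-block, category-major channel rearrangement (a pure permutation).

    Given five maps of shape (N, M, H, W) — blocks 1..5 — the output stacks
    all five blocks of category 0 first, then category 1, and so on: output
    channel ``k*5 + (b-1)`` holds category ``k`` of block ``b``.
    """
    if len(maps) != 5:
        raise ValueError("expected 5 block maps")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("block maps must share shape")
    n, m, h, w = shape
    stk = np.stack(maps, axis=2)  # (N, M, 5, H, W)
    return stk.reshape(n, m * 5, h, w)


def mlff_split_blocks(rearranged: np.ndarray, n_classes: int) -> list[np.ndarray]:
    """Inverse of :func:`mlff_rearrange`: recover the 5 block-major maps."""
    n, c, h, w = rearranged.shape
    if c != 5 * n_classes:
        raise ValueError(f"channel count {c} is not 5*{n_classes}")
    stk = rearranged.reshape(n, n_classes, 5, h, w)
    return [np.ascontiguousarray(stk[:, :, b]) for b in range(5)]


class MSLFNet(Module):
    """The full network; ``forward`` returns (main logits, deep-supervision logits)."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = Encoder(config, rng)
        self.decoder = Decoder(config, rng)
        self.needs_msfe = config.use_msfe or config.use_mlff
        self.msfe = MSFE(config, rng) if self.needs_msfe else None
        self.mlff = (CategoryGroupedConv1x1(config.n_classes, 5, rng=rng,
                                            name="mlff")
                     if config.use_mlff else None)
        self._mode: str | None = None

    def params(self) -> list[Param]:
        out = self.encoder.params() + self.decoder.params()
        if self.msfe is not None:
            out += self.msfe.params()
        if self.mlff is not None:
            out += self.mlff.params()
        return out

    def forward(self, x: np.ndarray, train: bool = True
                ) -> tuple[np.ndarray, np.ndarray]:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N,3,H,W) input, got {x.shape}")
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("input H and W must be divisible by 16")
        skips, _ = self.encoder.forward(x, train)
        pyramid, aux = self.decoder.forward(skips, train)
        if self.config.use_mlff:
            maps = self.msfe.forward(pyramid, train)
            main = self.mlff.forward(mlff_rearrange(maps), train)
            self._mode = "mlff"
        elif self.config.use_msfe:
            maps = self.msfe.forward(pyramid, train)
            main = sum(maps) / 5.0
            self._mode = "mean"
        else:
            main = aux
            self._mode = "baseline"
        return main, aux

    def backward(self, dmain: np.ndarray, daux: np.ndarray) -> None:
        if self._mode == "mlff":
            dre = self.mlff.backward(dmain)
            dmaps = mlff_split_blocks(dre, self.config.n_classes)
            dpyr = self.msfe.backward(dmaps)
        elif self._mode == "mean":
            dmaps = [dmain / 5.0] * 5
            dpyr = self.msfe.backward(dmaps)
        elif self._mode == "baseline":
            dpyr = None
            daux = daux + dmain
        else:
            raise RuntimeError("backward called before forward")
        dskips = self.decoder.backward(dpyr, daux)
        self.encoder.backward(dskips)
        self._mode = None

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (softmax over the main output)."""
        main, _ = self.forward(x, train=False)
        return softmax(main, axis=1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class index map (argmax of the main probabilities)."""
        return np.argmax(self.predict_proba(x), axis=1)

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.params()):
            state[f"{i:04d}:{p.name}"] = p.value
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError(f"checkpoint has {len(state)} arrays, "
                             f"model has {len(params)} parameters")
        for key in sorted(state):
            i = int(key.split(":", 1)[0])
            if params[i].value.shape != state[key].shape:
                raise ValueError(f"shape mismatch for parameter {key}")
            params[i].value[...] = state[key]


def build_encoder(config: ModelConfig,
                  rng: np.random.Generator | None = None) -> Encoder:
    """Build the VGG16-style encoder (spec'd stage widths, pool after 1-4)."""
    return Encoder(config, rng or np.random.default_rng(config.seed))


def build_decoder(config: ModelConfig,
                  rng: np.random.Generator | None = None) -> Decoder:
    """Build the decoder with transition block, up-steps and 1x1 head."""
    return Decoder(config, rng or np.random.default_rng(config.seed))
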