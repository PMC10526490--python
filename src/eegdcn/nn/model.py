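"""The assembled classifier: residual backbone with channel attention and
deformable convolution, bottom-up feature-pyramid fusion, and a BiGRU head.

The backbone is a four-stage residual network adapted to small spatial
inputs: a 3x3 stride-1 stem with no max-pool and stage strides (1, 2, 2, 2),
so a 9x9 grid passes through as 9 -> 9 -> 5 -> 3 -> 2. Every residual block
carries a channel-attention gate; both 3x3 convolutions of each block in the
configured stage are deformable, with zero-initialized offset branches so
training starts from the standard-convolution solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat
from . import functional as F
from .layers import BatchNorm2d, BiGRU, Conv2d, DeformableConv2d, ECABlock, ECAConfig, Linear, Module

__all__ = ["ModelConfig", "BasicBlock", "DCNABackbone", "BottomUpFPN", "EmotionClassifier"]


@dataclass
class ModelConfig:
    input_shape: tuple[int, int, int] = (9, 9, 4)  # (h, w, bands)
    stage_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    blocks_per_stage: int = 2
    dcn_block_index: int = 4  # which residual stage (1..4) uses deformable conv
    lateral_channels: int = 128
    gru_hidden: int = 64
    gru_sequence_mode: str = "spatial"  # or "temporal"
    temporal_group: int = 4  # sequence length for temporal mode
    n_classes: int = 2
    eca_gamma: float = 2.0
    eca_b: float = 1.0
    eca_residual: bool = True
    seed: int = 0

    def __post_init__(self):
        self.input_shape = tuple(self.input_shape)
        self.stage_widths = tuple(self.stage_widths)
        if self.dcn_block_index not in (1, 2, 3, 4):
            raise ValueError(f"dcn_block_index must be in 1..4, got {self.dcn_block_index}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.gru_sequence_mode not in ("spatial", "temporal"):
            raise ValueError(f"unknown gru_sequence_mode {self.gru_sequence_mode!r}")
        if len(self.stage_widths) != 4:
            raise ValueError("stage_widths must have 4 entries")
        # the stage strides (1,2,2,2) need four distinct pyramid scales
        h, w, _ = self.input_shape
        if h < 8 or w < 8:
            raise ValueError(
                f"input spatial dims {self.input_shape[:2]} too small for the stage strides "
                "(need >= 8 for four distinct scales)"
            )

    @property
    def eca(self) -> ECAConfig:
        return ECAConfig(gamma=self.eca_gamma, b=self.eca_b, residual=self.eca_residual)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_shape"] = list(self.input_shape)
        d["stage_widths"] = list(self.stage_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class BasicBlock(Module):
    """conv-BN-ReLU-conv-BN -> channel attention -> + shortcut -> ReLU."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: int,
        rng: np.random.Generator,
        deformable: bool = False,
        eca: ECAConfig = ECAConfig(),
    ):
        super().__init__()

        def make_conv(cin, cout, s):
            if deformable:
                return DeformableConv2d(cin, cout, rng, stride=s, pad=1, bias=False)
            return Conv2d(cin, cout, 3, rng, stride=s, pad=1, bias=False)

        self.conv1 = make_conv(in_channels, out_channels, stride)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = make_conv(out_channels, out_channels, 1)
        self.bn2 = BatchNorm2d(out_channels)
        self.attention = ECABlock(out_channels, rng, eca)
        if stride != 1 or in_channels != out_channels:
            self.shortcut_conv = Conv2d(in_channels, out_channels, 1, rng, stride=stride, pad=0, bias=False)
            self.shortcut_bn = BatchNorm2d(out_channels)
        else:
            self.shortcut_conv = None
            self.shortcut_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        out = self.attention(out)
        shortcut = x
        if self.shortcut_conv is not None:
            shortcut = self.shortcut_bn(self.shortcut_conv(x))
        return (out + shortcut).relu()


class DCNABackbone(Module):
    """Four residual stages; emits the per-stage maps C2..C5."""

    STAGE_STRIDES = (1, 2, 2, 2)

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        h, w, d = cfg.input_shape
        widths = cfg.stage_widths
        self.stem_conv = Conv2d(d, widths[0], 3, rng, stride=1, pad=1, bias=False)
        self.stem_bn = BatchNorm2d(widths[0])
        self.stages: list[list[BasicBlock]] = []
        in_ch = widths[0]
        for idx, (width, stride) in enumerate(zip(widths, self.STAGE_STRIDES), start=1):
            deformable = idx == cfg.dcn_block_index
            blocks = []
            for b in range(cfg.blocks_per_stage):
                blocks.append(
                    BasicBlock(in_ch, width, stride if b == 0 else 1, rng, deformable=deformable, eca=cfg.eca)
                )
                in_ch = width
            self.stages.append(blocks)

    def _children(self):
        yield from super()._children()
        for i, stage in enumerate(self.stages):
            for j, block in enumerate(stage):
                yield f"stages.{i}.{j}", block

    def forward(self, x: Tensor) -> list[Tensor]:
        out = self.stem_bn(self.stem_conv(x)).relu()
        features = []
        for stage in self.stages:
            for block in stage:
                out = block(out)
            features.append(out)
        return features  # [C2, C3, C4, C5]

    def set_use_offsets(self, enabled: bool) -> None:
        for stage in self.stages:
            for block in stage:
                for conv in (block.conv1, block.conv2):
                    if isinstance(conv, DeformableConv2d):
                        conv.use_offsets = enabled


class BottomUpFPN(Module):
    """1x1 lateral projections to a common width, then iterative stride-2
    downsample-and-add fusion (T2 -> D3 -> D4 -> D5) and a final 3x3 conv
    producing the enriched small map P5. All convolutions are bias-free so an
    all-zero pyramid maps to an all-zero P5."""

    def __init__(self, stage_widths: tuple[int, int, int, int], lateral_channels: int, rng: np.random.Generator):
        super().__init__()
        self.laterals = [Conv2d(w, lateral_channels, 1, rng, stride=1, pad=0, bias=False) for w in stage_widths]
        self.downsamples = [
            Conv2d(lateral_channels, lateral_channels, 3, rng, stride=2, pad=1, bias=False) for _ in range(3)
        ]
        self.out_conv = Conv2d(lateral_channels, lateral_channels, 3, rng, stride=1, pad=1, bias=False)
        self.lateral_channels = lateral_channels

    def forward(self, features: list[Tensor]) -> Tensor:
        if len(features) != 4:
            raise ValueError(f"expected 4 pyramid levels, got {len(features)}")
        laterals = [conv(f) for conv, f in zip(self.laterals, features)]  # T2..T5
        fused = laterals[0]
        for level, (down, target) in enumerate(zip(self.downsamples, laterals[1:]), start=3):
            fused = down(fused)
            if fused.data.shape != target.data.shape:
                raise ValueError(
                    f"shape mismatch fusing level D{level}: downsampled {fused.data.shape} "
                    f"vs lateral {target.data.shape}"
                )
            fused = fused + target  # D3, D4, D5
        return self.out_conv(fused)  # P5


class EmotionClassifier(Module):
    """backbone -> bottom-up pyramid -> feature sequence -> BiGRU -> linear -> softmax."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = DCNABackbone(cfg, rng)
        self.fpn = BottomUpFPN(cfg.stage_widths, cfg.lateral_channels, rng)
        self.bigru = BiGRU(cfg.lateral_channels, cfg.gru_hidden, rng)
        self.head = Linear(2 * cfg.gru_hidden, cfg.n_classes, rng)
        # optional input standardization fitted on training data; applied to
        # occupied (nonzero) grid cells only so structural zeros stay zero
        self.norm: tuple[float, float] | None = None

    def set_normalizer(self, mean: float, sd: float) -> None:
        if sd <= 0:
            raise ValueError("normalizer sd must be positive")
        self.norm = (float(mean), float(sd))

    def normalize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if self.norm is None:
            return x
        mean, sd = self.norm
        return np.where(x != 0, (x - mean) / sd, 0.0)

    def forward_logits(self, x: Tensor) -> Tensor:
        if x.data.ndim != 4:
            raise ValueError("expected a (batch, h, w, bands) input")
        if x.data.shape[1:] != self.cfg.input_shape:
            raise ValueError(f"input shape {x.data.shape[1:]} does not match {self.cfg.input_shape}")
        x = x.transpose((0, 3, 1, 2))  # to NCHW
        p5 = self.fpn(self.backbone(x))
        B, C, Hp, Wp = p5.data.shape
        if self.cfg.gru_sequence_mode == "spatial":
            # unroll the P5 spatial positions row-major as the sequence
            seq = p5.reshape(B, C, Hp * Wp)
            steps = [seq[:, :, t] for t in range(Hp * Wp)]
            state = self.bigru.final_state(steps)
            return self.head(state)
        # temporal mode: pool P5 per segment, group T consecutive segments
        T = self.cfg.temporal_group
        if B % T != 0:
            raise ValueError(f"batch size {B} not divisible by temporal group {T}")
        pooled = p5.mean(axis=(2, 3))  # (B, C)
        grouped = pooled.reshape(B // T, T, C)
        steps = [grouped[:, t, :] for t in range(T)]
        outs = self.bigru(steps)  # per-step (B//T, 2H)
        logits = [self.head(o) for o in outs]
        stacked = concat([l.reshape(B // T, 1, self.cfg.n_classes) for l in logits], axis=1)
        return stacked.reshape(B, self.cfg.n_classes)

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_logits(x)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a (batch, h, w, bands) array; rows sum to 1."""
        was_training = self.training
        self.eval()
        try:
            logits = self.forward_logits(Tensor(self.normalize(x)))
        finally:
            self.train(was_training)
        return F.softmax(logits.data, axis=1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def parameter_audit(self) -> dict[str, int]:
        """Parameter counts by component; 'offset' counts the offset branches."""
        offset = 0
        for stage in self.backbone.stages:
            for block in stage:
                for conv in (block.conv1, block.conv2):
                    if isinstance(conv, DeformableConv2d):
                        offset += conv.offset_parameter_count()
        counts = {
            "backbone": self.backbone.n_parameters(),  # includes offset branches
            "offset": offset,
            "fpn": self.fpn.n_parameters(),
            "gru": self.bigru.n_parameters(),
            "head": self.head.n_parameters(),
        }
        counts["total"] = counts["backbone"] + counts["fpn"] + counts["gru"] + counts["head"]
        return counts
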