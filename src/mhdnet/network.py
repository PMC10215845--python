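"""Self-Attention MHDNet: encoder/decoder 1D segmentation network.

The network maps a 3-lead, fixed-length ECG window to a per-sample logit for
"this sample lies inside an R-peak pulse". Structure:

* encoder — per level one operational block (Self-ONN or plain conv,
  then instance norm and tanh/relu), followed by 2x max pooling; filter
  counts double per level (16, 32, 64, 128 at the default depth);
* bottleneck — one operational block at ``base_filters * 2**levels``
  filters (256 by default);
* decoder — per level 2x linear upsampling, an attention-gated (or plain)
  skip concatenation, and one operational block;
* head — feature-pyramid fusion: decoder maps of the three shallowest
  levels are linearly interpolated to full length, concatenated, and passed
  through a kernel-1 operational layer producing one logit channel.

The attention gate projects encoder and (coarser) decoder features to the
encoder width with kernel-1 operational layers, sums them after upsampling
the decoder branch, squashes with tanh, reduces to a single channel, and
applies a sigmoid to give a multiplicative mask in (0, 1) over the skip.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

from . import autodiff as ad
from .exceptions import ContractError
from .selfonn import SelfOnn1d, SelfOnnSpec

VARIANTS = ("fpn_cnn", "self_fpn", "self_attention_mhdnet")


@dataclass(frozen=True)
class ModelConfig:
    levels: int = 4
    base_filters: int = 16
    bottleneck_filters: int = 256
    kernel_size: int = 11
    q: int = 3
    use_attention: bool = True
    layer_kind: str = "selfonn"  # {"selfonn", "cnn"}
    activation: str = "tanh"  # {"tanh", "relu"}
    in_channels: int = 3
    out_channels: int = 1

    def __post_init__(self):
        if self.layer_kind not in ("selfonn", "cnn"):
            raise ValueError(f"unknown layer_kind {self.layer_kind!r}")
        if self.activation not in ("tanh", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.bottleneck_filters != self.base_filters * 2**self.levels:
            raise ValueError(
                "bottleneck_filters must equal base_filters * 2**levels "
                f"({self.base_filters * 2 ** self.levels}), got "
                f"{self.bottleneck_filters}"
            )
        if self.layer_kind == "cnn" and self.q != 1:
            raise ValueError("cnn layer_kind requires q == 1")

    @property
    def encoder_filters(self) -> tuple[int, ...]:
        return tuple(self.base_filters * 2**i for i in range(self.levels))

    @property
    def head_levels(self) -> int:
        """Number of shallow decoder levels fused by the FPN head."""
        return min(3, self.levels)


def build_variant(name: str) -> ModelConfig:
    """Named ablation variants (baseline conv FPN, Self-FPN, full model)."""
    if name == "fpn_cnn":
        return ModelConfig(layer_kind="cnn", activation="relu", use_attention=False, q=1)
    if name == "self_fpn":
        return ModelConfig(layer_kind="selfonn", activation="tanh", use_attention=False)
    if name == "self_attention_mhdnet":
        return ModelConfig()
    raise ValueError(f"unknown variant {name!r}; expected one of {VARIANTS}")


class _OpBlock:
    """Operational layer + instance norm + activation."""

    def __init__(self, cfg: ModelConfig, c_in: int, c_out: int, kernel: int, rng, dtype):
        self.layer = SelfOnn1d(
            SelfOnnSpec(c_in, c_out, kernel, q=cfg.q), rng=rng, dtype=dtype
        )
        self.gamma = ad.parameter(np.ones(c_out, dtype=dtype))
        self.beta = ad.parameter(np.zeros(c_out, dtype=dtype))
        self.act = ad.tanh if cfg.activation == "tanh" else ad.relu

    def parameters(self):
        return self.layer.parameters() + [self.gamma, self.beta]

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        return self.act(ad.instance_norm(self.layer(x), self.gamma, self.beta))


class AttentionGate:
    """Multiplicative attention over one skip connection.

    ``enc`` has C channels at length L; ``dec`` is the coarser decoder
    signal with 2C channels at length L/2. Both are projected to C channels
    (kernel-1 operational layer + instance norm); the decoder branch is
    upsampled 2x; their sum passes tanh, a kernel-1 reduction to one
    channel, instance norm and sigmoid, yielding a gate in (0,1) of length
    L that multiplies the encoder signal.
    """

    def __init__(self, cfg: ModelConfig, enc_channels: int, rng, dtype):
        c = enc_channels
        k = 1
        q = cfg.q
        self.theta = SelfOnn1d(SelfOnnSpec(c, c, k, q=q), rng=rng, dtype=dtype)
        self.theta_gamma = ad.parameter(np.ones(c, dtype=dtype))
        self.theta_beta = ad.parameter(np.zeros(c, dtype=dtype))
        self.phi = SelfOnn1d(SelfOnnSpec(2 * c, c, k, q=q), rng=rng, dtype=dtype)
        self.phi_gamma = ad.parameter(np.ones(c, dtype=dtype))
        self.phi_beta = ad.parameter(np.zeros(c, dtype=dtype))
        self.psi = SelfOnn1d(SelfOnnSpec(c, 1, k, q=q), rng=rng, dtype=dtype)
        self.psi_gamma = ad.parameter(np.ones(1, dtype=dtype))
        self.psi_beta = ad.parameter(np.zeros(1, dtype=dtype))

    def parameters(self):
        return (
            self.theta.parameters()
            + [self.theta_gamma, self.theta_beta]
            + self.phi.parameters()
            + [self.phi_gamma, self.phi_beta]
            + self.psi.parameters()
            + [self.psi_gamma, self.psi_beta]
        )

    def __call__(self, enc: ad.Tensor, dec: ad.Tensor) -> ad.Tensor:
        if dec.shape[-1] * 2 != enc.shape[-1]:
            raise ContractError(
                f"decoder length {dec.shape[-1]} must be half of encoder "
                f"length {enc.shape[-1]}"
            )
        e = ad.instance_norm(self.theta(enc), self.theta_gamma, self.theta_beta)
        d = ad.instance_norm(self.phi(dec), self.phi_gamma, self.phi_beta)
        d = ad.upsample_linear(d, 2)
        s = ad.tanh(e + d)
        g = ad.instance_norm(self.psi(s), self.psi_gamma, self.psi_beta)
        gate = ad.sigmoid(g)  # (N, 1, L), broadcast over channels
        return enc * gate


class MhdNet:
    """The assembled segmentation model; owns all learnable parameters."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        cfg = config
        filt = cfg.encoder_filters
        k = cfg.kernel_size

        self.enc_blocks: list[_OpBlock] = []
        c_prev = cfg.in_channels
        for f in filt:
            self.enc_blocks.append(_OpBlock(cfg, c_prev, f, k, rng, dtype))
            c_prev = f
        self.bottleneck = _OpBlock(cfg, filt[-1], cfg.bottleneck_filters, k, rng, dtype)

        self.gates: list[AttentionGate | None] = []
        self.dec_blocks: list[_OpBlock] = []
        # decoder level i (0-based, shallowest first); built deepest-first below
        for i in reversed(range(cfg.levels)):
            f = filt[i]
            self.gates.insert(
                0, AttentionGate(cfg, f, rng, dtype) if cfg.use_attention else None
            )
            self.dec_blocks.insert(0, _OpBlock(cfg, 3 * f, f, k, rng, dtype))

        head_in = sum(filt[: cfg.head_levels])
        self.head = SelfOnn1d(
            SelfOnnSpec(head_in, cfg.out_channels, 1, q=cfg.q), rng=rng, dtype=dtype
        )

    def parameters(self) -> list[ad.Tensor]:
        ps: list[ad.Tensor] = []
        for b in self.enc_blocks:
            ps += b.parameters()
        ps += self.bottleneck.parameters()
        for g, b in zip(self.gates, self.dec_blocks):
            if g is not None:
                ps += g.parameters()
            ps += b.parameters()
        ps += self.head.parameters()
        return ps

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def _check_length(self, L: int) -> None:
        div = 2**self.config.levels
        if L % div:
            raise ContractError(
                f"input length {L} must be divisible by {div} "
                f"(2**levels with levels={self.config.levels})"
            )

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        """Batched forward: (N, in_channels, L) -> logits (N, 1, L)."""
        if x.data.ndim != 3 or x.data.shape[1] != self.config.in_channels:
            raise ContractError(
                f"expected (N, {self.config.in_channels}, L) input, got {x.shape}"
            )
        self._check_length(x.data.shape[-1])
        skips: list[ad.Tensor] = []
        h = x
        for blk in self.enc_blocks:
            h = blk(h)
            skips.append(h)
            h = ad.maxpool2(h)
        h = self.bottleneck(h)
        dec_maps: list[ad.Tensor | None] = [None] * self.config.levels
        for i in reversed(range(self.config.levels)):
            coarse = h
            up = ad.upsample_linear(coarse, 2)
            skip = skips[i]
            if self.gates[i] is not None:
                skip = self.gates[i](skip, coarse)
            h = self.dec_blocks[i](ad.concat_channels([up, skip]))
            dec_maps[i] = h
        fused = [dec_maps[0]]
        for i in range(1, self.config.head_levels):
            fused.append(ad.upsample_linear(dec_maps[i], 2**i))
        return self.head(ad.concat_channels(fused))

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        """Inference forward on plain arrays; returns logits (N, L) or (L,)."""
        x = np.asarray(x, dtype=self.dtype)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        out = self.forward(ad.Tensor(x)).data[:, 0, :]
        return out[0] if squeeze else out

    # --- checkpointing -------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ContractError(
                f"state has {len(arrays)} arrays, model expects {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ContractError(f"state shape {a.shape} != {p.data.shape}")
            p.data[...] = a


def save_checkpoint(model: MhdNet, path) -> None:
    """Single-file archive: config as a YAML text block + all arrays."""
    cfg_yaml = yaml.safe_dump(asdict(model.config))
    arrays = {f"param_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    with open(path, "wb") as fh:
        np.savez(fh, config_yaml=np.array(cfg_yaml), **arrays)


def load_checkpoint(path) -> MhdNet:
    with np.load(path, allow_pickle=False) as npz:
        cfg = ModelConfig(**yaml.safe_load(str(npz["config_yaml"])))
        keys = sorted(k for k in npz.files if k.startswith("param_"))
        arrays = [npz[k] for k in keys]
    model = MhdNet(cfg, seed=0, dtype=arrays[0].dtype if arrays else np.float32)
    model.set_state(arrays)
    return model


def attention_gate(enc: np.ndarray, dec: np.ndarray, params: AttentionGate) -> np.ndarray:
    """Functional attention gate on plain arrays: (C, L), (2C, L/2) -> (C, L)."""
    enc = np.asarray(enc)
    dec = np.asarray(dec)
    squeeze = enc.ndim == 2
    if squeeze:
        enc, dec = enc[None], dec[None]
    out = params(ad.Tensor(enc), ad.Tensor(dec)).data
    return out[0] if squeeze else out


def mhdnet_forward(
    segment: np.ndarray, config: ModelConfig | None, params: MhdNet
) -> np.ndarray:
    """Forward one (3, L) segment to a length-L logit vector."""
    if config is not None and config != params.config:
        raise ContractError("config does not match the supplied model parameters")
    return params.forward_np(np.asarray(segment))


def config_to_yaml(config: ModelConfig) -> str:
    return yaml.safe_dump(asdict(config))


def scaled_config(config: ModelConfig, levels: int, base_filters: int) -> ModelConfig:
    """Resize a config's depth/width, keeping the filter-doubling invariant."""
    return replace(
        config,
        levels=levels,
        base_filters=base_filters,
        bottleneck_filters=base_filters * 2**levels,
    )
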