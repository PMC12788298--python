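"""The five fusion architectures on a shared recurrent backbone.

Variants: ``audio_only`` / ``imu_only`` (single encoder), ``early_concat``
(per-timestep concatenation, D = 2H), ``gated_early`` (concatenation
re-weighted by a learned sigmoid gate per timestep and channel) and
``mid_xattn`` (audio queries a linear projection of the IMU embedding
through 4-head attention, residual + layer norm, D = H).  The temporal
model (1-layer BiGRU, 128 units per direction), mean pooling and the
256 -> 128 -> 1 classifier head are identical across variants so that
capacity is matched and differences are attributable to the fusion block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.core import DEFAULT_DTYPE

VARIANTS = ("audio_only", "imu_only", "early_concat", "gated_early", "mid_xattn")
N_MELS = 56
N_IMU = 6


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "gated_early"
    H: int = 96
    H_gru: int = 128
    heads: int = 4
    conv_kernel: int = 5
    dropout_head: float = 0.20
    dropout_fusion: float = 0.10

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.H % self.heads != 0:
            raise ValueError("H must be divisible by heads")
        if min(self.H, self.H_gru, self.heads) <= 0:
            raise ValueError("widths must be positive")

    @property
    def d_head(self) -> int:
        return self.H // self.heads

    @property
    def fused_dim(self) -> int:
        return 2 * self.H if self.variant in ("early_concat", "gated_early") else self.H


class FusionModel(nn.Module):
    """Assembled network for one variant; forward (B,T,56)/(B,T,6) -> (B,) logits."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE):
        super().__init__()
        config.validate()
        self.config = config
        self.dtype = dtype
        v = config.variant
        H = config.H

        self.uses_audio = v != "imu_only"
        self.uses_imu = v != "audio_only"
        if self.uses_audio:
            self.a_conv1 = self.add_child(
                "a_conv1", nn.Conv1dSame(N_MELS, H, config.conv_kernel, rng, dtype))
            self.a_relu1 = self.add_child("a_relu1", nn.ReLU())
            self.a_conv2 = self.add_child(
                "a_conv2", nn.Conv1dSame(H, H, config.conv_kernel, rng, dtype))
            self.a_relu2 = self.add_child("a_relu2", nn.ReLU())
        if self.uses_imu:
            self.i_lin1 = self.add_child("i_lin1", nn.Linear(N_IMU, H, rng, dtype))
            self.i_relu = self.add_child("i_relu", nn.ReLU())
            self.i_lin2 = self.add_child("i_lin2", nn.Linear(H, H, rng, dtype))

        if v == "gated_early":
            self.gate_l1 = self.add_child("gate_l1", nn.Linear(2 * H, H, rng, dtype))
            self.gate_relu = self.add_child("gate_relu", nn.ReLU())
            self.gate_drop = self.add_child("gate_drop", nn.Dropout(config.dropout_fusion))
            self.gate_l2 = self.add_child("gate_l2", nn.Linear(H, 2 * H, rng, dtype))
            self.force_gate_one = False  # diagnostic hook: bypass the gate
        elif v == "mid_xattn":
            self.phi = self.add_child("phi", nn.Linear(H, H, rng, dtype))
            self.mha = self.add_child(
                "mha", nn.MultiheadAttention(H, config.heads, config.dropout_fusion,
                                             rng, dtype))
            self.ln = self.add_child("ln", nn.LayerNorm(H, dtype))

        D = config.fused_dim
        self.bigru = self.add_child("bigru", nn.BiGRU(D, config.H_gru, rng, dtype))
        self.head_l1 = self.add_child(
            "head_l1", nn.Linear(2 * config.H_gru, config.H_gru, rng, dtype))
        self.head_relu = self.add_child("head_relu", nn.ReLU())
        self.head_drop = self.add_child("head_drop", nn.Dropout(config.dropout_head))
        self.head_l2 = self.add_child("head_l2", nn.Linear(config.H_gru, 1, rng, dtype))

        self.last_pooled: np.ndarray | None = None
        self.last_gate: np.ndarray | None = None

    # -- encoders ----------------------------------------------------------
    def encode_audio(self, xa, training=False):
        if xa.shape[-1] != N_MELS:
            raise ValueError(f"audio input must have {N_MELS} features")
        h = self.a_relu1.forward(self.a_conv1.forward(xa, training), training)
        h = self.a_relu2.forward(self.a_conv2.forward(h, training), training)
        pe = nn.positional_encoding(h.shape[1], self.config.H, h.dtype)
        return h + pe

    def encode_imu(self, xi, training=False):
        if xi.shape[-1] != N_IMU:
            raise ValueError(f"IMU input must have {N_IMU} channels")
        h = self.i_relu.forward(self.i_lin1.forward(xi, training), training)
        h = self.i_lin2.forward(h, training)
        pe = nn.positional_encoding(h.shape[1], self.config.H, h.dtype)
        return h + pe

    # -- fusion ------------------------------------------------------------
    def fuse(self, A, I, training=False, rng=None):
        v = self.config.variant
        if v == "audio_only":
            return A
        if v == "imu_only":
            return I
        if A.shape[1] != I.shape[1]:
            raise ValueError("modalities must share T")
        if v == "early_concat":
            return np.concatenate([A, I], axis=2)
        if v == "gated_early":
            z = np.concatenate([A, I], axis=2)
            u = self.gate_drop.forward(
                self.gate_relu.forward(self.gate_l1.forward(z, training), training),
                training, rng)
            g = nn.sigmoid(self.gate_l2.forward(u, training))
            self.last_gate = g
            self._gated_cache = (z, g)
            if self.force_gate_one:
                return z
            return g * z
        # mid_xattn
        kv = self.phi.forward(I, training)
        att = self.mha.forward(A, kv, training, rng)
        out = self.ln.forward(A + att, training)
        return out

    def _fuse_backward(self, dZ):
        v = self.config.variant
        H = self.config.H
        if v == "audio_only":
            return dZ, None
        if v == "imu_only":
            return None, dZ
        if v == "early_concat":
            return dZ[:, :, :H], dZ[:, :, H:]
        if v == "gated_early":
            z, g = self._gated_cache
            if self.force_gate_one:
                dz, dg = dZ, np.zeros_like(g)
            else:
                dz = dZ * g
                dg = dZ * z
            du = self.gate_l2.backward(dg * g * (1.0 - g))
            du = self.gate_relu.backward(self.gate_drop.backward(du))
            dz = dz + self.gate_l1.backward(du)
            return dz[:, :, :H], dz[:, :, H:]
        # mid_xattn
        dres = self.ln.backward(dZ)
        dq, dkv = self.mha.backward(dres)
        dA = dres + dq
        dI = self.phi.backward(dkv)
        return dA, dI

    # -- backbone + head ---------------------------------------------------
    def backbone_and_head(self, Z, training=False, rng=None):
        Hseq = self.bigru.forward(Z, training)
        h_bar = Hseq.mean(axis=1)  # (B, 2*H_gru)
        self.last_pooled = h_bar
        self._T = Z.shape[1]
        h = self.head_relu.forward(self.head_l1.forward(h_bar, training), training)
        h = self.head_drop.forward(h, training, rng)
        logit = self.head_l2.forward(h, training)[:, 0]
        return logit

    def _backbone_backward(self, dlogit):
        dh = self.head_l2.backward(dlogit[:, None])
        dh = self.head_relu.backward(self.head_drop.backward(dh))
        dh_bar = self.head_l1.backward(dh)
        B, D = dh_bar.shape
        dH = np.broadcast_to(dh_bar[:, None, :] / self._T, (B, self._T, D)).astype(dh_bar.dtype)
        return self.bigru.backward(dH)

    # -- full passes -------------------------------------------------------
    def forward(self, xa, xi, training=False, rng=None):
        if self.uses_audio and xa is None:
            raise ValueError(f"{self.config.variant} requires audio input")
        if self.uses_imu and xi is None:
            raise ValueError(f"{self.config.variant} requires IMU input")
        A = self.encode_audio(xa, training) if self.uses_audio else None
        I = self.encode_imu(xi, training) if self.uses_imu else None
        Z = self.fuse(A if A is not None else I,
                      I if I is not None else A, training, rng) \
            if (A is not None and I is not None) else (A if A is not None else I)
        self._single = not (A is not None and I is not None)
        return self.backbone_and_head(Z, training, rng)

    def backward(self, dlogit):
        dZ = self._backbone_backward(dlogit)
        if self._single:
            if self.uses_audio:
                dA, dI = dZ, None
            else:
                dA, dI = None, dZ
        else:
            dA, dI = self._fuse_backward(dZ)
        if dA is not None and self.uses_audio:
            d = self.a_conv2.backward(self.a_relu2.backward(dA))
            self.a_conv1.backward(self.a_relu1.backward(d))
        if dI is not None and self.uses_imu:
            d = self.i_lin2.backward(dI)
            self.i_lin1.backward(self.i_relu.backward(d))

    def backbone_head_param_count(self) -> int:
        n = self.bigru.n_parameters()
        for lyr in (self.head_l1, self.head_l2):
            n += lyr.n_parameters()
        return n


def build_model(config: ModelConfig, rng: np.random.Generator,
                dtype=DEFAULT_DTYPE) -> FusionModel:
    """Construct a fusion model; raises for unknown variant names."""
    return FusionModel(config, rng, dtype)


def weighted_bce_with_logits(logits: np.ndarray, labels: np.ndarray,
                             weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Class-weighted binary cross-entropy on raw logits.

    Returns (mean loss, gradient wrt logits).  ``weights`` is one weight per
    sample (its class weight).
    """
    logits = logits.astype(np.float64)
    y = labels.astype(np.float64)
    w = weights.astype(np.float64)
    # stable softplus(logit) - y*logit
    loss_i = np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))
    loss = float(np.mean(w * loss_i))
    p = 1.0 / (1.0 + np.exp(-logits))
    dlogits = w * (p - y) / len(y)
    return loss, dlogits
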