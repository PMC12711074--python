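"""Encoder/decoder contracts, reparameterization, and the β-VAE objective.

The encoder q_phi maps a z-stack x (planes, H, W) to a diagonal Gaussian
posterior over a d-dimensional latent code; the decoder p_theta maps a latent
vector back to a reconstructed stack of the same shape. Training minimizes

    L_beta-VAE = 1/2 MSE(x, x_hat) + beta * KL(q_phi(z|x) || N(0, I_d))

with the MSE taken as the per-element mean, so the default loss weights are
interpreted against mean-scaled components. Two backbones share the same
contract: ``small`` (four stride-2 convolution blocks, total stride 16,
CPU-fast) and ``resnet18`` (the standard 18-layer residual network with an
input convolution widened to the number of focal planes, total stride 32).
The decoder mirrors the encoder with nearest-neighbour-upsample + convolution
stages; its final layer is linear by default (inputs are normalized but not
strictly bounded), with a configurable sigmoid alternative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np

from . import nn
from .autodiff import Tensor, no_grad

__all__ = ["VaeModel", "LatentCode", "encode", "reparameterize",
           "reconstruction_loss", "kl_divergence", "beta_vae_loss",
           "save_checkpoint", "load_checkpoint"]

ArrayLike = Union[np.ndarray, Tensor]


@dataclass
class LatentCode:
    """Diagonal Gaussian posterior for a batch of crops."""

    mu: np.ndarray        # (n, d)
    log_var: np.ndarray   # (n, d)
    z: Optional[np.ndarray] = None  # present only after reparameterization

    def __post_init__(self):
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.log_var))):
            raise ValueError("latent code must be finite")


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------

class _BasicBlock(nn.Module):
    """Residual basic block: two 3x3 convolutions with batch norm."""

    def __init__(self, cin, cout, rng, stride=1):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng, stride=stride, padding=1)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, stride=1, padding=1)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down_conv = nn.Conv2d(cin, cout, 1, rng, stride=stride)
            self.down_bn = nn.BatchNorm2d(cout)
        else:
            self.down_conv = None

    def forward(self, x):
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        skip = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + skip).relu()


class _ResNet18Encoder(nn.Module):
    stride = 32

    def __init__(self, n_planes, rng):
        super().__init__()
        self.stem = nn.Sequential(
            nn.Conv2d(n_planes, 64, 7, rng, stride=2, padding=3),
            nn.BatchNorm2d(64), nn.ReLU(), nn.MaxPool2d(3, 2, 1))
        blocks = []
        cin = 64
        for cout, stride in [(64, 1), (64, 1), (128, 2), (128, 1),
                             (256, 2), (256, 1), (512, 2), (512, 1)]:
            blocks.append(_BasicBlock(cin, cout, rng, stride))
            cin = cout
        self.blocks = nn.Sequential(*blocks)
        self.out_channels = 512

    def forward(self, x):
        h = self.blocks(self.stem(x))
        return h.mean(axis=(2, 3))  # global average pool -> (N, 512)


class _SmallEncoder(nn.Module):
    stride = 16

    def __init__(self, n_planes, rng):
        super().__init__()
        chans = [n_planes, 12, 24, 48, 96]
        layers = []
        for cin, cout in zip(chans[:-1], chans[1:]):
            layers += [nn.Conv2d(cin, cout, 3, rng, stride=2, padding=1),
                       nn.ReLU()]
        self.body = nn.Sequential(*layers)
        self.out_channels = 96

    def forward(self, x):
        h = self.body(x)
        n = h.shape[0]
        return h.reshape(n, int(np.prod(h.shape[1:])))


def _upconv(cin, cout, rng, norm=False):
    layers = [nn.Upsample(2), nn.Conv2d(cin, cout, 3, rng, padding=1)]
    if norm:
        layers.append(nn.BatchNorm2d(cout))
    layers.append(nn.ReLU())
    return layers


class _Decoder(nn.Module):
    def __init__(self, n_planes, image_size, latent_dim, backbone, rng,
                 output_activation="linear"):
        super().__init__()
        if backbone == "small":
            self.h0 = image_size // 16
            self.c0 = 96
            body = _upconv(96, 48, rng) + _upconv(48, 24, rng) \
                + _upconv(24, 12, rng) + _upconv(12, 12, rng)
        else:
            self.h0 = image_size // 32
            self.c0 = 512
            body = _upconv(512, 256, rng, norm=True) \
                + _upconv(256, 128, rng, norm=True) \
                + _upconv(128, 64, rng, norm=True) \
                + _upconv(64, 32, rng, norm=True) + _upconv(32, 16, rng)
        self.fc = nn.Linear(latent_dim, self.c0 * self.h0 * self.h0, rng)
        self.body = nn.Sequential(*body)
        head_in = 12 if backbone == "small" else 16
        self.head = nn.Conv2d(head_in, n_planes, 3, rng, padding=1)
        self.output_activation = output_activation

    def forward(self, z):
        n = z.shape[0]
        h = self.fc(z).relu().reshape(n, self.c0, self.h0, self.h0)
        out = self.head(self.body(h))
        if self.output_activation == "sigmoid":
            out = out.sigmoid()
        return out


class VaeModel(nn.Module):
    """Encoder, decoder and the linear reporter-intensity head.

    The intensity head predicts the (standardized) mean red and green
    PIP-FUCCI intensities from a latent vector with a single affine layer.
    """

    BACKBONES = ("small", "resnet18")

    def __init__(self, latent_dim: int = 256, n_planes: int = 5,
                 image_size: int = 32, backbone: str = "small",
                 output_activation: str = "linear", seed: int = 0):
        super().__init__()
        if latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if backbone not in self.BACKBONES:
            raise ValueError(f"unknown backbone {backbone!r}")
        enc_cls = _SmallEncoder if backbone == "small" else _ResNet18Encoder
        if image_size % enc_cls.stride != 0:
            raise ValueError(f"image_size must be divisible by "
                             f"{enc_cls.stride} for backbone {backbone!r}")
        rng = np.random.default_rng(seed)
        self.latent_dim = latent_dim
        self.n_planes = n_planes
        self.image_size = image_size
        self.backbone = backbone
        self.output_activation = output_activation
        self.encoder = enc_cls(n_planes, rng)
        feat = self.encoder.out_channels
        if backbone == "small":
            feat *= (image_size // enc_cls.stride) ** 2
        self.mu_head = nn.Linear(feat, latent_dim, rng)
        self.logvar_head = nn.Linear(feat, latent_dim, rng)
        self.logvar_head.weight.data *= 0.01  # start near the prior scale
        self.decoder = _Decoder(n_planes, image_size, latent_dim, backbone,
                                rng, output_activation)
        self.intensity_head = nn.Linear(latent_dim, 2, rng)
        # training-split standardization constants for the intensity targets
        self.intensity_mean = np.zeros(2)
        self.intensity_std = np.ones(2)

    @property
    def contract(self) -> Dict:
        return {"latent_dim": self.latent_dim, "n_planes": self.n_planes,
                "image_size": self.image_size, "backbone": self.backbone,
                "output_activation": self.output_activation}

    # differentiable paths used by the trainer -----------------------------
    def encode_t(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        feats = self.encoder(x)
        return self.mu_head(feats), self.logvar_head(feats)

    def decode_t(self, z: Tensor) -> Tensor:
        return self.decoder(z)

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 3
        if single:
            x = x[None]
        if x.ndim != 4 or x.shape[1] != self.n_planes:
            raise ValueError(f"expected (n, {self.n_planes}, H, W) stack, "
                             f"got shape {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("input stack contains non-finite values")
        return x

    def encode_np(self, x: np.ndarray) -> LatentCode:
        x = self._check_input(x)
        mode = self.training
        self.eval()
        try:
            with no_grad():
                mu, logvar = self.encode_t(Tensor(x))
        finally:
            self.train(mode)
        return LatentCode(mu=mu.data, log_var=logvar.data)

    def decode_np(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        mode = self.training
        self.eval()
        try:
            with no_grad():
                out = self.decode_t(Tensor(z))
        finally:
            self.train(mode)
        return out.data


def encode(model: VaeModel, x: np.ndarray) -> LatentCode:
    """Deterministic posterior parameters (mu, log_var) for a stack or batch."""
    return model.encode_np(x)


def reparameterize(code: LatentCode, rng: np.random.Generator) -> np.ndarray:
    """Draw z = mu + exp(log_var / 2) * eps with eps ~ N(0, I)."""
    eps = rng.standard_normal(code.mu.shape)
    z = code.mu + np.exp(0.5 * code.log_var) * eps
    code.z = z
    return z


# ---------------------------------------------------------------------------
# losses (accept numpy arrays or autodiff tensors)
# ---------------------------------------------------------------------------

def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def reconstruction_loss(x: ArrayLike, x_hat: ArrayLike):
    """Half the per-element mean squared error between stack and reconstruction."""
    tensor_mode = _is_tensor(x, x_hat)
    xt, ht = Tensor.as_tensor(x), Tensor.as_tensor(x_hat)
    if xt.shape != ht.shape:
        raise ValueError(f"shape mismatch {xt.shape} vs {ht.shape}")
    out = ((xt - ht) ** 2.0).mean() * 0.5
    return out if tensor_mode else out.item()


def kl_divergence(code: Union[LatentCode, Tuple[ArrayLike, ArrayLike]]):
    """KL(q || N(0, I)) = 1/2 sum_i (mu_i^2 + sigma_i^2 - 1 - log sigma_i^2),
    averaged over the batch."""
    if isinstance(code, LatentCode):
        mu, log_var = code.mu, code.log_var
    else:
        mu, log_var = code
    tensor_mode = _is_tensor(mu, log_var)
    mt, lt = Tensor.as_tensor(mu), Tensor.as_tensor(log_var)
    if not np.all(np.isfinite(lt.data)):
        raise ValueError("log_var must be finite")
    if mt.ndim == 1:
        mt, lt = mt.reshape(1, -1), lt.reshape(1, -1)
    per_item = (mt ** 2.0 + lt.exp() - 1.0 - lt).sum(axis=1) * 0.5
    out = per_item.mean()
    return out if tensor_mode else out.item()


def beta_vae_loss(x: ArrayLike, x_hat: ArrayLike,
                  code, beta: float):
    """Total β-VAE loss and its components."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    tensor_mode = _is_tensor(x, x_hat)
    rec = reconstruction_loss(x, x_hat)
    kl = kl_divergence(code)
    total = rec + beta * kl
    if tensor_mode:
        return total, {"rec": rec.item() if isinstance(rec, Tensor) else rec,
                       "kl": kl.item() if isinstance(kl, Tensor) else kl}
    return total, {"rec": rec, "kl": kl}


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: VaeModel, path: str,
                    extras: Optional[Dict] = None) -> None:
    """Persist parameters plus the model contract and any extra metadata."""
    meta = {"contract": model.contract, "extras": extras or {},
            "intensity_mean": model.intensity_mean.tolist(),
            "intensity_std": model.intensity_std.tolist()}
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str, expect: Optional[Dict] = None) -> VaeModel:
    """Rebuild a model from a checkpoint; refuse a contract mismatch."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    contract = meta["contract"]
    if expect:
        bad = {k: (v, contract.get(k)) for k, v in expect.items()
               if contract.get(k) != v}
        if bad:
            raise ValueError(f"checkpoint contract mismatch: {bad}")
    model = VaeModel(**contract)
    model.load_state_dict(state)
    model.intensity_mean = np.array(meta["intensity_mean"])
    model.intensity_std = np.array(meta["intensity_std"])
    model.eval()
    return model
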