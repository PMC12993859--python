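"""Multitask patch-transformer regression on whole 10-channel plant images.

The high-complexity state-estimation tier: an image is split into patches,
each patch linearly embedded, and a stack of pre-norm transformer encoder
layers (multi-head self-attention + MLP, residual connections) mixes
spatial and spectral structure.  Token-averaged features pass through a
two-layer ReLU head predicting all 8 response variables at once.  The
full-scale configuration (256-dim embedding, 16 heads, 6 layers, MLP 1024,
head 256->128->8, batch 32, initial learning rate 1e-4, 100 epochs) is
supported but intended for GPU runs; ``ViTConfig.desk()`` shrinks every
dimension for CPU-scale exercises of the same architecture and data
splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor, layer_norm, relu, softmax

__all__ = ["ViTConfig", "MultispectralViT", "ViTResults"]


@dataclass(frozen=True)
class ViTConfig:
    """Architecture and training settings for the multispectral ViT."""

    channels: int = 10
    image_size: int = 128
    patch_size: int = 16
    dim: int = 256
    heads: int = 16
    depth: int = 6
    mlp_dim: int = 1024
    head_hidden: int = 128
    n_outputs: int = 8
    batch_size: int = 32
    learning_rate: float = 1e-4
    epochs: int = 100
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.dim % self.heads:
            raise ValueError("embedding dim must be divisible by the head count")
        if self.image_size % self.patch_size:
            raise ValueError("image size must be divisible by the patch size")

    @classmethod
    def desk(cls, image_size: int = 32, epochs: int = 30, **kw) -> "ViTConfig":
        """Desk-scale variant: same architecture, small dimensions."""
        defaults = dict(
            image_size=image_size, patch_size=image_size // 4, dim=32, heads=4,
            depth=2, mlp_dim=64, head_hidden=16, batch_size=16,
            learning_rate=1e-3, epochs=epochs,
        )
        defaults.update(kw)
        return cls(**defaults)

    @property
    def n_patches(self) -> int:
        return (self.image_size // self.patch_size) ** 2


class MultispectralViT:
    """Patch-transformer multitask regressor mapping (B, 10, H, W) -> (B, 8)."""

    def __init__(self, config: ViTConfig | None = None):
        self.config = config or ViTConfig()
        self._rng = np.random.default_rng(self.config.seed)
        self.params: list[Tensor] = []
        self.layers: list[dict] = []
        self._build()

    def _tensor(self, *shape, fan_in=None) -> Tensor:
        scale = np.sqrt(1.0 / (fan_in or shape[0]))
        t = Tensor(self._rng.normal(0.0, scale, shape), requires_grad=True)
        self.params.append(t)
        return t

    def _zeros(self, *shape) -> Tensor:
        t = Tensor(np.zeros(shape), requires_grad=True)
        self.params.append(t)
        return t

    def _ones(self, *shape) -> Tensor:
        t = Tensor(np.ones(shape), requires_grad=True)
        self.params.append(t)
        return t

    def _build(self):
        c = self.config
        patch_dim = c.channels * c.patch_size**2
        self.w_embed = self._tensor(patch_dim, c.dim)
        self.b_embed = self._zeros(c.dim)
        self.pos = self._zeros(c.n_patches, c.dim)
        for _ in range(c.depth):
            self.layers.append({
                "ln1_g": self._ones(c.dim), "ln1_b": self._zeros(c.dim),
                "wq": self._tensor(c.dim, c.dim), "wk": self._tensor(c.dim, c.dim),
                "wv": self._tensor(c.dim, c.dim), "wo": self._tensor(c.dim, c.dim),
                "ln2_g": self._ones(c.dim), "ln2_b": self._zeros(c.dim),
                "w1": self._tensor(c.dim, c.mlp_dim), "b1": self._zeros(c.mlp_dim),
                "w2": self._tensor(c.mlp_dim, c.dim), "b2": self._zeros(c.dim),
            })
        self.ln_f_g, self.ln_f_b = self._ones(c.dim), self._zeros(c.dim)
        self.w_h1 = self._tensor(c.dim, c.head_hidden)
        self.b_h1 = self._zeros(c.head_hidden)
        self.w_h2 = self._tensor(c.head_hidden, c.n_outputs)
        self.b_h2 = self._zeros(c.n_outputs)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    # -- forward ------------------------------------------------------------

    def _patchify(self, images: np.ndarray) -> np.ndarray:
        c = self.config
        b, ch, h, w = images.shape
        if ch != c.channels:
            raise ValueError(f"expected {c.channels}-channel input, got {ch}")
        if h != c.image_size or w != c.image_size:
            raise ValueError(f"expected {c.image_size}x{c.image_size} images, got {h}x{w}")
        p = c.patch_size
        x = images.reshape(b, ch, h // p, p, w // p, p)
        x = x.transpose(0, 2, 4, 1, 3, 5)  # (B, gh, gw, C, p, p)
        return x.reshape(b, c.n_patches, ch * p * p)

    def _attention(self, layer: dict, x: Tensor, batch: int) -> Tensor:
        c = self.config
        dh = c.dim // c.heads
        n = c.n_patches

        def split(t):  # (B, N, D) -> (B, heads, N, dh)
            return t.reshape(batch, n, c.heads, dh).transpose(0, 2, 1, 3)

        q, k, v = (split(x @ layer[w]) for w in ("wq", "wk", "wv"))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        out = softmax(scores) @ v
        out = out.transpose(0, 2, 1, 3).reshape(batch, n, c.dim)
        return out @ layer["wo"]

    def forward(self, images: np.ndarray) -> Tensor:
        patches = self._patchify(np.asarray(images, dtype=np.float64))
        b = patches.shape[0]
        x = Tensor(patches) @ self.w_embed + self.b_embed + self.pos
        for layer in self.layers:
            h = layer_norm(x, layer["ln1_g"], layer["ln1_b"])
            x = x + self._attention(layer, h, b)
            h = layer_norm(x, layer["ln2_g"], layer["ln2_b"])
            h = relu(h @ layer["w1"] + layer["b1"]) @ layer["w2"] + layer["b2"]
            x = x + h
        x = layer_norm(x, self.ln_f_g, self.ln_f_b).mean(axis=1)
        h = relu(x @ self.w_h1 + self.b_h1)
        return h @ self.w_h2 + self.b_h2

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.forward(images).data

    # -- training -----------------------------------------------------------

    def fit(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        val: tuple[np.ndarray, np.ndarray] | None = None,
        rv_names: list[str] | None = None,
    ) -> "ViTResults":
        """Train with per-RV standardized MSE and reduce-on-plateau LR.

        ``labels`` is (n, 8); standardization statistics come from the
        training labels only.  The plateau rule halves the learning rate
        when the monitored loss (validation when given, else training) has
        not improved for ``plateau_patience`` epochs.
        """
        c = self.config
        labels = np.asarray(labels, dtype=np.float64)
        mu, sd = labels.mean(axis=0), labels.std(axis=0)
        sd[sd == 0] = 1.0
        y = (labels - mu) / sd
        self._label_mu, self._label_sd = mu, sd

        opt = Adam(self.params, lr=c.learning_rate)
        rng = np.random.default_rng(c.seed + 1)
        n = len(images)
        curve, monitor_curve = [], []
        best, since_best = np.inf, 0
        for _ in range(c.epochs):
            perm = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, c.batch_size):
                sel = perm[start:start + c.batch_size]
                pred = self.forward(images[sel])
                diff = pred - Tensor(y[sel])
                loss = (diff * diff).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(sel)
            curve.append(epoch_loss / n)
            if val is not None:
                v_pred = self.predict(val[0])
                v_y = (np.asarray(val[1], float) - mu) / sd
                monitored = float(((v_pred - v_y) ** 2).mean())
            else:
                monitored = curve[-1]
            monitor_curve.append(monitored)
            if monitored < best - 1e-12:
                best, since_best = monitored, 0
            else:
                since_best += 1
                if since_best >= c.plateau_patience:
                    opt.lr *= c.plateau_factor
                    since_best = 0
        return ViTResults(
            model=self, loss_curve=np.asarray(curve),
            monitor_curve=np.asarray(monitor_curve),
            rv_names=rv_names, label_mu=mu, label_sd=sd,
        )


@dataclass
class ViTResults:
    """Training diagnostics and evaluation for a fitted multispectral ViT."""

    model: MultispectralViT
    loss_curve: np.ndarray
    monitor_curve: np.ndarray
    label_mu: np.ndarray
    label_sd: np.ndarray
    rv_names: list[str] | None = None

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Predictions on the original label scale."""
        z = self.model.predict(images)
        return z * self.label_sd + self.label_mu

    def evaluate(self, images: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
        """Per-RV R2 and RMSE on a held-out set."""
        from sklearn.metrics import mean_squared_error, r2_score

        pred = self.predict(images)
        labels = np.asarray(labels, dtype=np.float64)
        names = self.rv_names or [f"rv{i}" for i in range(labels.shape[1])]
        rows = []
        for j, name in enumerate(names):
            rows.append({
                "rv": name,
                "r2": r2_score(labels[:, j], pred[:, j]),
                "rmse": float(np.sqrt(mean_squared_error(labels[:, j], pred[:, j]))),
            })
        return pd.DataFrame(rows).set_index("rv")

    def summary(self) -> str:
        c = self.model.config
        return "\n".join([
            "Multispectral patch-transformer regressor",
            f"  image / patch     : {c.image_size} / {c.patch_size} "
            f"({c.n_patches} tokens)",
            f"  dim/heads/depth   : {c.dim}/{c.heads}/{c.depth} (MLP {c.mlp_dim})",
            f"  parameters        : {self.model.n_parameters():,}",
            f"  epochs            : {len(self.loss_curve)}",
            f"  final train loss  : {self.loss_curve[-1]:.4f}",
            f"  final monitored   : {self.monitor_curve[-1]:.4f}",
        ])
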