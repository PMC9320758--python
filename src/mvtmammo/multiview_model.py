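"""The four-view mammogram transformer.

One shared patch/class/position embedding maps each of the LCC, RCC, LMLO
and RMLO views into a token sequence of length N+1.  A stack of L_local
blocks — one set of weights, applied to every view — models
within-mammogram patch relationships; the four output sequences are then
concatenated (LCC, RCC, LMLO, RMLO order, length 4N+4) and a stack of
L_global blocks attends across them, modelling bilateral asymmetry and
ipsilateral correspondence.  L_local + L_global equals the total depth
(12 in the DeiT presets).  The class token of the last global block feeds
a one-layer head with two outputs (benign / malignant).

Checkpoints in the standard single-stack ViT/DeiT schema import directly:
source blocks 0..L_local-1 become local blocks and the remainder become
global blocks, so pretrained weights need no surgery.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._tensor import Tensor, concat, layer_norm
from .transformer_core import BlockParams, transformer_block_forward
from .preprocessing import VIEWS

__all__ = [
    "MVTConfig", "SharedEmbeddings", "CasePrediction", "MultiViewTransformer",
    "count_parameters", "parameter_count_formula",
    "save_checkpoint", "load_checkpoint", "load_pretrained_deit",
    "IncompatibleCheckpointError", "PRESETS",
]


class IncompatibleCheckpointError(ValueError):
    """Raised when a checkpoint tensor cannot be mapped onto the model."""


@dataclass
class MVTConfig:
    """Architecture hyperparameters.

    `n_views=4` is the study architecture; `n_views=1` builds the
    single-image ablation with the identical core (no concatenation
    across views), used for fusion-benefit comparisons.
    """

    image_side: int = 224
    patch_size: int = 16
    channels: int = 3
    d_embed: int = 192
    n_heads: int = 3
    depth_total: int = 12
    n_local: int = 2
    n_global: int = 10
    mlp_ratio: int = 4
    n_classes: int = 2
    n_views: int = 4
    head_token: str = "first"  # "first" | "mean" over the four class tokens
    view_order: tuple[str, ...] = VIEWS

    def __post_init__(self) -> None:
        if self.n_local + self.n_global != self.depth_total:
            raise ValueError(f"n_local + n_global must equal depth_total "
                             f"({self.n_local}+{self.n_global}!={self.depth_total})")
        if self.image_side % self.patch_size != 0:
            raise ValueError("image_side must be divisible by patch_size")
        if self.d_embed % self.n_heads != 0:
            raise ValueError("d_embed must be divisible by n_heads")
        if self.n_views not in (1, 4):
            raise ValueError("n_views must be 4 (full model) or 1 (ablation)")
        if self.head_token not in ("first", "mean"):
            raise ValueError("head_token must be 'first' or 'mean'")

    @property
    def n_patches(self) -> int:
        """N = (H/P) * (W/P); 196 for 224x224 images with 16x16 patches."""
        return (self.image_side // self.patch_size) ** 2

    @property
    def seq_len(self) -> int:
        return self.n_patches + 1


PRESETS: dict[str, dict] = {
    # DeiT-tiny / DeiT-small backbones, depth 12.
    "tiny": dict(d_embed=192, n_heads=3, depth_total=12),
    "small": dict(d_embed=384, n_heads=6, depth_total=12),
    # CPU-scale configuration for tests and desk experiments.
    "toy": dict(d_embed=32, n_heads=2, depth_total=4, n_local=1, n_global=3,
                image_side=32, patch_size=8),
}


def make_config(preset: str, **overrides) -> MVTConfig:
    base = dict(PRESETS[preset])
    base.update(overrides)
    return MVTConfig(**base)


@dataclass
class SharedEmbeddings:
    """Patch projection, class token and position embeddings — one copy
    shared by all four views."""

    w_patch: Tensor  # (C*P*P, d): the P-stride conv expressed as a linear map
    b_patch: Tensor  # (d,)
    cls_token: Tensor  # (d,)
    pos_embed: Tensor  # (N+1, d)

    @classmethod
    def initialize(cls, rng: np.random.Generator, cfg: MVTConfig,
                   init_std: float = 0.02) -> "SharedEmbeddings":
        cpp = cfg.channels * cfg.patch_size ** 2
        return cls(
            w_patch=Tensor(rng.normal(0, init_std, (cpp, cfg.d_embed)).astype(np.float32),
                           requires_grad=True),
            b_patch=Tensor(np.zeros(cfg.d_embed, dtype=np.float32), requires_grad=True),
            cls_token=Tensor(rng.normal(0, init_std, cfg.d_embed).astype(np.float32),
                             requires_grad=True),
            pos_embed=Tensor(rng.normal(0, init_std,
                                        (cfg.seq_len, cfg.d_embed)).astype(np.float32),
                             requires_grad=True),
        )


@dataclass
class CasePrediction:
    logits: np.ndarray          # (2,): [benign, malignant]
    probabilities: np.ndarray   # softmax of logits
    predicted_class: str        # 'malignant' iff p(malignant) > p(benign)


def extract_patches(images: np.ndarray, patch: int) -> np.ndarray:
    """(..., H, W, C) -> (..., N, C*P*P), row-major patch order.

    The flattening order (C, P, P) matches how a conv weight of shape
    (d, C, P, P) flattens, so ViT checkpoints import as a plain copy.
    """
    *lead, H, W, C = images.shape
    gh, gw = H // patch, W // patch
    x = images.reshape(*lead, gh, patch, gw, patch, C)
    n = x.ndim
    # (..., gh, gw, C, P, P)
    x = np.moveaxis(x, (n - 4, n - 1), (n - 2, n - 3))
    return x.reshape(*lead, gh * gw, C * patch * patch)


class MultiViewTransformer:
    """Shared embeddings + local stack + concatenation + global stack + head."""

    def __init__(self, config: MVTConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.embeddings = SharedEmbeddings.initialize(rng, config)
        self.local_blocks = [BlockParams.initialize(rng, config.d_embed, config.n_heads,
                                                    config.mlp_ratio)
                             for _ in range(config.n_local)]
        self.global_blocks = [BlockParams.initialize(rng, config.d_embed, config.n_heads,
                                                     config.mlp_ratio)
                              for _ in range(config.n_global)]
        self.norm_g = Tensor(np.ones(config.d_embed, dtype=np.float32), requires_grad=True)
        self.norm_b = Tensor(np.zeros(config.d_embed, dtype=np.float32), requires_grad=True)
        self.w_head = Tensor(rng.normal(0, 0.02, (config.d_embed, config.n_classes))
                             .astype(np.float32), requires_grad=True)
        self.b_head = Tensor(np.zeros(config.n_classes, dtype=np.float32),
                             requires_grad=True)

    # ------------------------------------------------------------- parameters

    def named_parameters(self) -> dict[str, Tensor]:
        out = {
            "embed.w_patch": self.embeddings.w_patch,
            "embed.b_patch": self.embeddings.b_patch,
            "embed.cls_token": self.embeddings.cls_token,
            "embed.pos_embed": self.embeddings.pos_embed,
            "norm.g": self.norm_g, "norm.b": self.norm_b,
            "head.w": self.w_head, "head.b": self.b_head,
        }
        for kind, blocks in (("local", self.local_blocks), ("global", self.global_blocks)):
            for i, blk in enumerate(blocks):
                for name, t in blk.tensors().items():
                    out[f"{kind}.{i}.{name}"] = t
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    # ---------------------------------------------------------------- forward

    def embed_views(self, images: np.ndarray) -> Tensor:
        """(B, V, H, W, C) pixel array -> (B, V, N+1, d) token sequences."""
        cfg = self.config
        patches = extract_patches(np.asarray(images, dtype=np.float32), cfg.patch_size)
        x = Tensor(patches) @ self.embeddings.w_patch + self.embeddings.b_patch
        lead = x.shape[:-2]
        cls = self.embeddings.cls_token.reshape(1, cfg.d_embed)
        cls = cls.broadcast_to((*lead, 1, cfg.d_embed))
        x = concat([cls, x], axis=-2)
        return x + self.embeddings.pos_embed

    def forward_local(self, seqs: Tensor) -> Tensor:
        """Apply the shared local blocks to each view independently.

        `seqs` is (B, V, T, d); weight sharing across views makes the
        batched evaluation identical to processing views one at a time.
        An empty local stack is the identity.
        """
        for blk in self.local_blocks:
            seqs = transformer_block_forward(seqs, blk)
        return seqs

    @staticmethod
    def concat_views(seqs: Tensor) -> Tensor:
        """(B, V, T, d) -> (B, V*T, d) in view order (LCC, RCC, LMLO, RMLO)."""
        B, V, T, d = seqs.shape
        return seqs.reshape(B, V * T, d)

    def forward_global(self, seq: Tensor) -> Tensor:
        for blk in self.global_blocks:
            seq = transformer_block_forward(seq, blk)
        return seq

    def _head_input(self, seq: Tensor) -> Tensor:
        """Select the class-token representation that feeds the head.

        Position 0 of the concatenated sequence (the LCC-slot class token)
        by default; 'mean' averages the V class-token positions.  With no
        global blocks the four views never mix, so the mean is forced —
        the minimal symmetric fusion rule.
        """
        cfg = self.config
        T = cfg.seq_len
        use_mean = cfg.head_token == "mean" or (cfg.n_global == 0 and cfg.n_views > 1)
        if use_mean and cfg.n_views > 1:
            tokens = [seq[:, v * T, :] for v in range(cfg.n_views)]
            out = tokens[0]
            for t in tokens[1:]:
                out = out + t
            return out * (1.0 / cfg.n_views)
        return seq[:, 0, :]

    def forward_batch(self, images: np.ndarray) -> Tensor:
        """(B, V, H, W, C) preprocessed pixels -> (B, n_classes) logits."""
        images = np.asarray(images, dtype=np.float32)
        if images.ndim != 5 or images.shape[1] != self.config.n_views:
            raise ValueError(f"expected (B, {self.config.n_views}, H, W, C) input, "
                             f"got shape {images.shape}")
        x = self.embed_views(images)
        x = self.forward_local(x)
        x = self.concat_views(x)
        x = self.forward_global(x)
        x = layer_norm(x, self.norm_g, self.norm_b)
        h = self._head_input(x)
        return h @ self.w_head + self.b_head

    def predict_case(self, images: np.ndarray) -> CasePrediction:
        """Classify one case; ties go to benign ('greater than' rule)."""
        logits = self.forward_batch(images[None]).data[0]
        p = np.exp(logits - logits.max())
        p = p / p.sum()
        label = "malignant" if p[1] > p[0] else "benign"
        return CasePrediction(logits=logits, probabilities=p, predicted_class=label)


# ------------------------------------------------------------------ counting

def parameter_count_formula(cfg: MVTConfig) -> int:
    """Closed-form trainable-scalar count.

    embeddings: C*P^2*d + d (patch proj)  +  d (class token)  +  (N+1)*d
    per block:  d*3d + 3d  +  d*d + d  (attention, fused QKV + output proj)
              + 2*(2d)                 (two layer norms)
              + d*rd + rd + rd*d + d   (MLP)
    plus a final layer norm (2d) and the head (d*n_classes + n_classes).
    The count is independent of the local/global split: local and global
    blocks are architecturally identical and the total depth is fixed.
    """
    d, r, c = cfg.d_embed, cfg.mlp_ratio, cfg.n_classes
    emb = cfg.channels * cfg.patch_size ** 2 * d + d + d + cfg.seq_len * d
    block = (d * 3 * d + 3 * d) + (d * d + d) + 4 * d + (d * r * d + r * d) + (r * d * d + d)
    return emb + cfg.depth_total * block + 2 * d + (d * c + c)


def count_parameters(model_or_config: "MultiViewTransformer | MVTConfig") -> int:
    """Count trainable scalars by enumerating the actual parameter tensors."""
    model = (model_or_config if isinstance(model_or_config, MultiViewTransformer)
             else MultiViewTransformer(model_or_config))
    return int(sum(p.data.size for p in model.parameters()))


# --------------------------------------------------------------- checkpoints

def save_checkpoint(model: MultiViewTransformer, path: str | Path) -> None:
    """Serialize as an .npz tensor map with a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {name: t.data for name, t in model.named_parameters().items()}
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(model.config), indent=2))


def load_checkpoint(path: str | Path) -> MultiViewTransformer:
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    cfg_dict = json.loads(path.with_suffix(".json").read_text())
    cfg_dict["view_order"] = tuple(cfg_dict["view_order"])
    model = MultiViewTransformer(MVTConfig(**cfg_dict))
    with np.load(npz_path) as data:
        for name, t in model.named_parameters().items():
            t.data = data[name].astype(np.float32)
    return model


_DEIT_BLOCK_MAP = {
    # (our BlockParams field, source suffix, transpose?)
    "w_qkv": ("attn.qkv.weight", True),
    "b_qkv": ("attn.qkv.bias", False),
    "w_out": ("attn.proj.weight", True),
    "b_out": ("attn.proj.bias", False),
    "ln1_g": ("norm1.weight", False),
    "ln1_b": ("norm1.bias", False),
    "ln2_g": ("norm2.weight", False),
    "ln2_b": ("norm2.bias", False),
    "w_fc1": ("mlp.fc1.weight", True),
    "b_fc1": ("mlp.fc1.bias", False),
    "w_fc2": ("mlp.fc2.weight", True),
    "b_fc2": ("mlp.fc2.bias", False),
}


def _interp_pos_embed(pos: np.ndarray, n_target: int) -> np.ndarray:
    """Bilinearly resample the grid part of a (N+1, d) position table."""
    from PIL import Image

    cls_row, grid = pos[:1], pos[1:]
    side_src = int(round(np.sqrt(grid.shape[0])))
    side_dst = int(round(np.sqrt(n_target - 1)))
    d = grid.shape[1]
    grid = grid.reshape(side_src, side_src, d)
    out = np.empty((side_dst, side_dst, d), dtype=np.float32)
    for j in range(d):
        im = Image.fromarray(grid[:, :, j].astype(np.float32), mode="F")
        out[:, :, j] = np.asarray(im.resize((side_dst, side_dst), Image.BILINEAR))
    return np.concatenate([cls_row, out.reshape(side_dst * side_dst, d)], axis=0)


def load_pretrained_deit(state: dict[str, np.ndarray],
                         config: MVTConfig, seed: int = 0) -> MultiViewTransformer:
    """Initialize from a single-stack ViT/DeiT checkpoint (timm naming).

    Source blocks 0..L_local-1 map onto the local stack and blocks
    L_local..depth-1 onto the global stack.  Embeddings map onto the
    shared embeddings.  The classification head is NOT imported — it is
    re-initialized fresh for the 2-class task.  Position tables whose
    length differs are bilinearly resampled (with a warning); every other
    shape mismatch raises IncompatibleCheckpointError naming the tensor.
    """
    model = MultiViewTransformer(config, seed=seed)

    def fetch(name: str) -> np.ndarray:
        if name not in state:
            raise IncompatibleCheckpointError(f"checkpoint is missing tensor {name!r}")
        return np.asarray(state[name], dtype=np.float32)

    def assign(target: Tensor, name: str, value: np.ndarray) -> None:
        if value.shape != target.data.shape:
            raise IncompatibleCheckpointError(
                f"tensor {name!r} has shape {value.shape}, model expects "
                f"{target.data.shape}")
        target.data = value.copy()

    cfg = model.config
    emb = model.embeddings
    assign(emb.cls_token, "cls_token", fetch("cls_token").reshape(-1))
    pos = fetch("pos_embed").reshape(-1, cfg.d_embed)
    if pos.shape[0] != cfg.seq_len:
        warnings.warn(f"resampling position embeddings {pos.shape[0]} -> {cfg.seq_len}")
        pos = _interp_pos_embed(pos, cfg.seq_len)
    assign(emb.pos_embed, "pos_embed", pos)
    w = fetch("patch_embed.proj.weight")  # (d, C, P, P)
    assign(emb.w_patch, "patch_embed.proj.weight",
           w.reshape(w.shape[0], -1).T.copy())
    assign(emb.b_patch, "patch_embed.proj.bias", fetch("patch_embed.proj.bias"))

    all_blocks = model.local_blocks + model.global_blocks
    for i, blk in enumerate(all_blocks):
        for field_name, (suffix, transpose) in _DEIT_BLOCK_MAP.items():
            name = f"blocks.{i}.{suffix}"
            value = fetch(name)
            if transpose:
                value = value.T.copy()
            assign(getattr(blk, field_name), name, value)
    assign(model.norm_g, "norm.weight", fetch("norm.weight"))
    assign(model.norm_b, "norm.bias", fetch("norm.bias"))
    # head.w / head.b stay freshly initialized (2 outputs).
    return model
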