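"""Pair-biased transformer encoder and the three pretraining heads.

The backbone is a standard multi-head self-attention stack with two twists:

* the pair representation ``z`` is projected to one scalar per head per atom
  pair and **added to the attention logits** before the softmax, so invariant
  geometry steers which atoms attend to each other;
* the raw attention logits of each layer are projected back into pair space
  and **added onto z**, so the pair representation is refined layer by layer
  alongside the single representation.

With the pair bias identically zero, each layer reduces exactly to a vanilla
transformer layer — a property the tests rely on.

Pretraining attaches three heads to the encoder output: a classification
head over atom types (for masked-type recovery), a symmetric distance head
on ``z`` (to recover the clean distance matrix) and a residual coordinate
head (to displace the noisy coordinates back toward the clean ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

from . import vocab
from .geometry import BinningScheme, PairFeatures
from .nn import (
    ParamInit, cross_entropy_logits, embedding, gelu, init_embedding,
    init_layer_norm, init_linear, layer_norm, linear, smooth_l1, softmax,
    softplus,
)

__all__ = [
    "EncoderConfig", "init_encoder_params", "init_pretrain_head_params",
    "embed_pair_bins", "encoder_layer", "encode_batch", "pretrain_heads",
    "pretrain_loss", "collate_molecules",
]

NEG_INF = -1e9


@dataclass
class EncoderConfig:
    """Hyperparameters of the pair-biased transformer.

    The full-scale pretraining configuration is 15 layers of width 512 with
    4 attention heads and a 2048-wide feed-forward; desk-scale presets shrink
    this to run on one CPU.
    """

    n_layers: int = 15
    d_model: int = 512
    n_heads: int = 4
    d_ffn: int = 2048
    d_pair: int = 64
    d_bin_embed: int = 16
    dropout: float = 0.0
    max_len: int = 512
    seed: int = 0
    binning: BinningScheme = field(default_factory=BinningScheme)

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        for name in ("n_layers", "d_model", "n_heads", "d_ffn", "d_pair", "d_bin_embed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if isinstance(self.binning, dict):
            self.binning = BinningScheme.from_dict(self.binning)

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["binning"] = self.binning.to_dict()
        return d

    @classmethod
    def tiny(cls, **kw) -> "EncoderConfig":
        """2-layer / 64-dim configuration for desk-scale runs and tests."""
        base = dict(n_layers=2, d_model=64, n_heads=4, d_ffn=256, d_pair=16,
                    d_bin_embed=8)
        base.update(kw)
        return cls(**base)

    @classmethod
    def protein_tiny(cls, **kw) -> "EncoderConfig":
        """Desk-scale configuration with protein-sized binning.

        Residue chains span tens of Å, so the pair-feature grid widens to
        1 Å distance bins over [0, 32) and 2 Å position bins over [−16, 16)
        — the same bin counts as the ligand grid, covering the larger
        extent at coarser resolution.
        """
        base = dict(n_layers=2, d_model=64, n_heads=4, d_ffn=256, d_pair=16,
                    d_bin_embed=8,
                    binning=BinningScheme(dist_width=1.0, dist_max=32.0,
                                          pos_width=2.0, pos_max=16.0))
        base.update(kw)
        return cls(**base)


def _init_layer(init: ParamInit, cfg: EncoderConfig) -> dict:
    d = cfg.d_model
    return {
        "ln1": init_layer_norm(d),
        "wq": init_linear(init, d, d),
        "wk": init_linear(init, d, d),
        "wv": init_linear(init, d, d),
        "wo": init_linear(init, d, d),
        "pair_bias": init_linear(init, cfg.d_pair, cfg.n_heads),
        "z_proj": init_linear(init, cfg.n_heads, cfg.d_pair),
        "ln2": init_layer_norm(d),
        "ffn1": init_linear(init, d, cfg.d_ffn),
        "ffn2": init_linear(init, cfg.d_ffn, d),
    }


def init_encoder_params(cfg: EncoderConfig, n_tokens: int | None = None) -> dict:
    """Seeded parameter tree for the encoder (atom vocabulary by default)."""
    init = ParamInit(cfg.seed)
    n_tokens = n_tokens or len(vocab.ATOM_TOKENS)
    nb = cfg.binning
    return {
        "token_embed": init_embedding(init, n_tokens, cfg.d_model),
        "pair": {
            "dist": init_embedding(init, nb.n_dist_bins, cfg.d_bin_embed),
            "pos": [init_embedding(init, nb.n_pos_bins, cfg.d_bin_embed)
                    for _ in range(3)],
            "lin1": init_linear(init, 4 * cfg.d_bin_embed, cfg.d_pair),
            "lin2": init_linear(init, cfg.d_pair, cfg.d_pair),
        },
        "layers": [_init_layer(init, cfg) for _ in range(cfg.n_layers)],
        "ln_out": init_layer_norm(cfg.d_model),
    }


def init_pretrain_head_params(cfg: EncoderConfig, seed_offset: int = 1) -> dict:
    init = ParamInit(cfg.seed + seed_offset)
    d, p = cfg.d_model, cfg.d_pair
    return {
        "type": init_linear(init, d, vocab.N_ATOM_CLASSES),
        "dist": {"l1": init_linear(init, p, p), "l2": init_linear(init, p, 1)},
        "coord": {"l1": init_linear(init, d, d), "l2": init_linear(init, d, 3)},
    }


def embed_pair_bins(params: dict, D_bins: np.ndarray, P_bins: np.ndarray):
    """Initial pair representation from discretized geometry.

    Bin indices are looked up in learned tables (one for distances, one per
    signed position axis), concatenated and passed through
    ``Linear -> GELU -> Linear``.
    """
    pp = params["pair"]
    parts = [embedding(pp["dist"], D_bins)]
    for ax in range(3):
        parts.append(embedding(pp["pos"][ax], P_bins[..., ax]))
    h = anp.concatenate(parts, axis=-1)
    return linear(pp["lin2"], gelu(linear(pp["lin1"], h)))


def encoder_layer(lp: dict, cfg: EncoderConfig, s, z, mask=None, pair_bias_on: bool = True):
    """One pair-biased transformer layer (pre-norm residual form).

    Returns ``(s_next, z_next, logits)`` where ``logits`` are the raw
    per-head attention logits (query-key scores plus pair bias, before the
    padding mask and softmax) that also drive the pair update.
    """
    B, T, d = s.shape
    H, dk = cfg.n_heads, cfg.d_head
    h = layer_norm(lp["ln1"], s)
    q = anp.transpose(anp.reshape(linear(lp["wq"], h), (B, T, H, dk)), (0, 2, 1, 3))
    k = anp.transpose(anp.reshape(linear(lp["wk"], h), (B, T, H, dk)), (0, 2, 1, 3))
    v = anp.transpose(anp.reshape(linear(lp["wv"], h), (B, T, H, dk)), (0, 2, 1, 3))
    logits = anp.matmul(q, anp.transpose(k, (0, 1, 3, 2))) / np.sqrt(dk)
    if pair_bias_on:
        bias = anp.transpose(linear(lp["pair_bias"], z), (0, 3, 1, 2))
        logits = logits + bias
    att_logits = logits
    if mask is not None:
        att_logits = att_logits + (1.0 - mask[:, None, None, :]) * NEG_INF
    a = softmax(att_logits, axis=-1)
    o = anp.reshape(anp.transpose(anp.matmul(a, v), (0, 2, 1, 3)), (B, T, d))
    s = s + linear(lp["wo"], o)
    h2 = layer_norm(lp["ln2"], s)
    s = s + linear(lp["ffn2"], gelu(linear(lp["ffn1"], h2)))
    z_next = z + linear(lp["z_proj"], anp.transpose(logits, (0, 2, 3, 1)))
    return s, z_next, logits


def encode_batch(
    params: dict,
    cfg: EncoderConfig,
    token_idx: np.ndarray,
    z0,
    mask: np.ndarray | None = None,
    pair_bias_on: bool = True,
    pair_update_on: bool = True,
):
    """Run the full encoder on a padded batch.

    ``token_idx`` is ``(B, T)`` int (row 0 of each sequence is the [CLS]
    token), ``z0`` is ``(B, T, T, d_pair)`` and ``mask`` is ``(B, T)`` with 1
    on real tokens.  Returns the final single representation ``(B, T,
    d_model)`` and pair representation ``(B, T, T, d_pair)``.
    """
    if token_idx.shape[1] > cfg.max_len:
        raise ValueError(f"sequence length {token_idx.shape[1]} exceeds max_len")
    s = embedding(params["token_embed"], token_idx)
    z = z0
    for lp in params["layers"]:
        s, z_new, _ = encoder_layer(lp, cfg, s, z, mask, pair_bias_on)
        if pair_update_on:
            z = z_new
    s = layer_norm(params["ln_out"], s)
    return s, z


def pretrain_heads(head_params: dict, s, z, noisy_coords):
    """Apply the three denoising heads to an encoder output.

    * type logits ``(B, m, n_classes)`` from the atom rows of ``s``;
    * predicted distances ``(B, T, T)``, symmetrized by averaging ``z[i, j]``
      and ``z[j, i]`` before a small MLP with a softplus output (distances
      are non-negative);
    * predicted coordinates ``(B, m, 3)`` as noisy coordinates plus a learned
      displacement (residual parameterization).
    """
    type_logits = linear(head_params["type"], s[:, 1:, :])
    zs = 0.5 * (z + anp.transpose(z, (0, 2, 1, 3)))
    dh = head_params["dist"]
    dist_pred = softplus(linear(dh["l2"], gelu(linear(dh["l1"], zs)))[..., 0])
    ch = head_params["coord"]
    delta = linear(ch["l2"], gelu(linear(ch["l1"], s[:, 1:, :])))
    coord_pred = noisy_coords + delta
    return type_logits, dist_pred, coord_pred


def pretrain_loss(
    enc_params: dict,
    head_params: dict,
    cfg: EncoderConfig,
    batch: dict,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    return_parts: bool = False,
):
    """Three-task loss of one corrupted batch against its clean targets.

    Masked-type cross-entropy on masked positions, smooth-L1 on the clean
    distance matrix over real-atom pairs, smooth-L1 on clean coordinates
    over real atoms.
    """
    z0 = embed_pair_bins(enc_params, batch["D_bins"], batch["P_bins"])
    s, z = encode_batch(enc_params, cfg, batch["token_idx"], z0, batch["mask"])
    type_logits, dist_pred, coord_pred = pretrain_heads(
        head_params, s, z, batch["noisy_coords"])
    l_type = cross_entropy_logits(type_logits, batch["target_types"],
                                  batch["mask_weight"])
    atom_mask = batch["mask"][:, 1:]
    pair_mask = atom_mask[:, :, None] * atom_mask[:, None, :]
    d_err = smooth_l1(dist_pred[:, 1:, 1:], batch["clean_D"])
    l_dist = anp.sum(d_err * pair_mask) / max(pair_mask.sum(), 1.0)
    c_err = smooth_l1(coord_pred, batch["clean_coords"])
    l_coord = anp.sum(c_err * atom_mask[:, :, None]) / max(3 * atom_mask.sum(), 1.0)
    total = weights[0] * l_type + weights[1] * l_dist + weights[2] * l_coord
    if return_parts:
        return total, (l_type, l_dist, l_coord)
    return total


def collate_molecules(samples: list[dict], scheme: BinningScheme) -> dict:
    """Pad a list of featurized (possibly corrupted) molecules into a batch.

    Each sample dict carries ``token_idx`` (length m+1 with [CLS] first),
    ``pair`` (:class:`PairFeatures` of the *input* coordinates),
    ``noisy_coords``/``clean_coords`` ``(m, 3)``, ``target_types`` (length m
    int) and ``mask_indices``.
    """
    B = len(samples)
    T = max(len(s["token_idx"]) for s in samples)
    token_idx = np.zeros((B, T), dtype=int)
    mask = np.zeros((B, T))
    D_bins = np.zeros((B, T, T), dtype=int)
    P_bins = np.zeros((B, T, T, 3), dtype=int)
    clean_D = np.zeros((B, T - 1, T - 1))
    noisy = np.zeros((B, T - 1, 3))
    clean = np.zeros((B, T - 1, 3))
    targets = np.zeros((B, T - 1), dtype=int)
    mask_w = np.zeros((B, T - 1))
    for b, smp in enumerate(samples):
        t = len(smp["token_idx"])
        m = t - 1
        token_idx[b, :t] = smp["token_idx"]
        mask[b, :t] = 1.0
        pf: PairFeatures = smp["pair"]
        D_bins[b, :t, :t] = pf.D_bins
        P_bins[b, :t, :t] = pf.P_bins
        clean_D[b, :m, :m] = smp["clean_D"]
        noisy[b, :m] = smp["noisy_coords"]
        clean[b, :m] = smp["clean_coords"]
        targets[b, :m] = smp["target_types"]
        if len(smp["mask_indices"]):
            mask_w[b, np.asarray(smp["mask_indices"], dtype=int)] = 1.0
    return {
        "token_idx": token_idx, "mask": mask, "D_bins": D_bins,
        "P_bins": P_bins, "clean_D": clean_D, "noisy_coords": noisy,
        "clean_coords": clean, "target_types": targets, "mask_weight": mask_w,
    }
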