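"""Protein encoding, complex assembly and the affinity / binding-site model.

A complex is represented by concatenating independently encoded ligand and
protein tracks.  The single representations are stacked ([CLS]-first for
each molecule); the pair representation is block-diagonal, with zero blocks
standing in for the *unknown* ligand–protein interactions — the model never
sees the relative pose of the two molecules and must infer interaction
patterns from each side's internal structure.  A pair-biased transformer
trunk then updates the joint representation; the two [CLS] rows feed the
affinity head and the updated protein rows feed the per-residue binding-site
head.

The protein side is pluggable: any encoder mapping ``n`` residues to an
``(n+1) × d`` single and ``(n+1) × (n+1) × d_pair`` pair representation
([CLS]-first) can be dropped in.  The bundled default is a lightweight
geometric encoder that embeds residue types and runs the same pair-biased
transformer over invariant Cα-trace features, mirroring the ligand encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

from . import vocab
from .encoder import (
    EncoderConfig, embed_pair_bins, encode_batch, encoder_layer,
    init_encoder_params,
)
from .geometry import BinningScheme, Molecule, compute_distance_matrix, featurize
from .nn import ParamInit, bce_logits, gelu, init_linear, linear, sigmoid, softplus

__all__ = [
    "ProteinInput", "ComplexConfig", "init_complex_params",
    "featurize_protein", "encode_protein", "assemble_complex",
    "complex_forward", "affinity_forward", "binding_site_forward",
    "complex_losses", "collate_complexes",
]


@dataclass
class ProteinInput:
    """A protein chain: residue types, heavy-atom coordinates, Cα trace.

    ``heavy_atom_coords[i]`` is an ``(k_i, 3)`` array of residue *i*'s heavy
    atoms (used for binding-site labeling); ``ca_coords`` is the ``(n, 3)``
    Cα trace consumed by the bundled geometric encoder.
    """

    residue_types: list[str]
    heavy_atom_coords: list[np.ndarray]
    ca_coords: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        n = len(self.residue_types)
        if n < 1:
            raise ValueError("protein must contain at least one residue")
        if self.ca_coords.shape != (n, 3):
            raise ValueError("ca_coords must be (n, 3)")
        if len(self.heavy_atom_coords) != n:
            raise ValueError("heavy_atom_coords length mismatch")
        self.heavy_atom_coords = [np.asarray(c, dtype=float).reshape(-1, 3)
                                  for c in self.heavy_atom_coords]
        for i, c in enumerate(self.heavy_atom_coords):
            if c.shape[0] < 1:
                raise ValueError(f"residue {i} has no heavy atoms")

    @property
    def n_residues(self) -> int:
        return len(self.residue_types)


@dataclass
class ComplexConfig:
    """Configuration of the downstream affinity/site model.

    Ligand and protein encoders share width with the trunk by default; if
    they differ, learned linear adapters map both onto the trunk width.  The
    ``use_distance`` / ``use_positions`` switches implement the structure
    ablations by zeroing the corresponding bin channels at featurization
    time.
    """

    ligand: EncoderConfig = field(default_factory=EncoderConfig.tiny)
    protein: EncoderConfig = field(default_factory=EncoderConfig.protein_tiny)
    trunk_layers: int = 4
    d_model: int = 64
    d_pair: int = 16
    n_heads: int = 4
    d_ffn: int = 256
    lambda_site: float = 1.0
    use_distance: bool = True
    use_positions: bool = True
    freeze_encoders: bool = False
    head_hidden: int | None = None  # hidden width of both heads (default d_model)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.ligand, dict):
            self.ligand = EncoderConfig(**self.ligand)
        if isinstance(self.protein, dict):
            self.protein = EncoderConfig(**self.protein)
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.ligand.d_pair != self.d_pair or self.protein.d_pair != self.d_pair:
            raise ValueError("ligand/protein d_pair must match trunk d_pair")

    @property
    def trunk_encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            n_layers=self.trunk_layers, d_model=self.d_model,
            n_heads=self.n_heads, d_ffn=self.d_ffn, d_pair=self.d_pair,
            d_bin_embed=self.ligand.d_bin_embed, seed=self.seed,
            binning=self.ligand.binning,
        )

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ligand"] = self.ligand.to_dict()
        d["protein"] = self.protein.to_dict()
        return d


def adapt_encoder_for_protein(pretrained: dict, cfg: EncoderConfig,
                              seed_offset: int = 23) -> dict:
    """Warm-start the protein encoder from a pretrained ligand encoder.

    Transformer layers, output norm and pair-bin embeddings carry over (the
    two encoders share their architecture and bin counts by design); the
    token embedding is freshly initialized for the residue vocabulary.
    """
    from copy import deepcopy

    from .nn import ParamInit, init_embedding

    params = deepcopy(pretrained)
    init = ParamInit(cfg.seed + seed_offset)
    params["token_embed"] = init_embedding(init, len(vocab.RESIDUE_TOKENS),
                                           cfg.d_model)
    return params


def init_complex_params(cfg: ComplexConfig, ligand_params: dict | None = None,
                        protein_params: dict | None = None) -> dict:
    """Parameter tree of the full complex model.

    ``ligand_params`` transplants a pretrained ligand encoder; otherwise the
    ligand encoder is freshly initialized (the from-scratch ablation).
    ``protein_params`` does the same for the protein encoder (see
    :func:`adapt_encoder_for_protein`).
    """
    init = ParamInit(cfg.seed + 17)
    trunk_cfg = cfg.trunk_encoder_config
    params = {
        "ligand": ligand_params if ligand_params is not None
        else init_encoder_params(cfg.ligand),
        "protein": protein_params if protein_params is not None
        else init_encoder_params(cfg.protein, n_tokens=len(vocab.RESIDUE_TOKENS)),
        "trunk": init_encoder_params(trunk_cfg)["layers"],
        "adapters": {},
        "affinity": {
            "l1": init_linear(init, 2 * cfg.d_model, cfg.head_hidden or cfg.d_model),
            "l2": init_linear(init, cfg.head_hidden or cfg.d_model, 1),
        },
        "site": {
            "l1": init_linear(init, cfg.d_model, cfg.head_hidden or cfg.d_model),
            "l2": init_linear(init, cfg.head_hidden or cfg.d_model, 1),
        },
    }
    if cfg.ligand.d_model != cfg.d_model:
        params["adapters"]["ligand"] = init_linear(init, cfg.ligand.d_model, cfg.d_model)
    if cfg.protein.d_model != cfg.d_model:
        params["adapters"]["protein"] = init_linear(init, cfg.protein.d_model, cfg.d_model)
    return params


def featurize_protein(protein: ProteinInput, scheme: BinningScheme | None = None,
                      use_distance: bool = True, use_positions: bool = True):
    """Invariant pair features of the Cα trace, [CLS]-first.

    The residue chain order plays the role of the atom order in the ligand
    featurizer, so the same local-frame construction applies.
    """
    mol = Molecule(atom_types=["C"] * protein.n_residues,
                   coords=protein.ca_coords, id=protein.id)
    pf = featurize(mol, scheme=scheme, include_cls=True)
    if not use_distance:
        pf.D_bins = np.zeros_like(pf.D_bins)
    if not use_positions:
        pf.P_bins = np.zeros_like(pf.P_bins)
    return pf


def encode_protein(params: dict, cfg: EncoderConfig, token_idx, z0, mask=None):
    """Run the bundled geometric protein encoder (plug-in default).

    ``token_idx`` indexes :data:`pairbind.vocab.RESIDUE_TOKENS`.  Any
    external encoder with the same output contract can replace this.
    """
    return encode_batch(params, cfg, token_idx, z0, mask)


def assemble_complex(s_lig, z_lig, s_pro, z_pro):
    """Concatenate ligand and protein tracks into one complex representation.

    Singles are stacked ligand-first; the pair tensor is block-diagonal with
    exactly zero off-diagonal blocks (the unknown cross interactions).
    Returns ``(s, z, ligand_tokens)`` where ``ligand_tokens`` is the offset
    of the protein block.
    """
    if s_lig.shape[-1] != s_pro.shape[-1]:
        raise ValueError("ligand/protein single widths differ")
    if z_lig.shape[-1] != z_pro.shape[-1]:
        raise ValueError("ligand/protein pair widths differ")
    B, Tl, _ = s_lig.shape
    Tp = s_pro.shape[1]
    p = z_lig.shape[-1]
    s = anp.concatenate([s_lig, s_pro], axis=1)
    top = anp.concatenate([z_lig, np.zeros((B, Tl, Tp, p))], axis=2)
    bottom = anp.concatenate([np.zeros((B, Tp, Tl, p)), z_pro], axis=2)
    z = anp.concatenate([top, bottom], axis=1)
    return s, z, Tl


def complex_forward(params: dict, cfg: ComplexConfig, batch: dict):
    """Full forward pass: encoders → assembly → trunk.

    Returns ``(s_updated, ligand_tokens)``; downstream heads slice the
    [CLS] and protein rows out of ``s_updated``.
    """
    lig_cfg, pro_cfg = cfg.ligand, cfg.protein
    z0_lig = embed_pair_bins(params["ligand"], batch["lig_D_bins"], batch["lig_P_bins"])
    s_lig, z_lig = encode_batch(params["ligand"], lig_cfg, batch["lig_tokens"],
                                z0_lig, batch["lig_mask"])
    z0_pro = embed_pair_bins(params["protein"], batch["pro_D_bins"], batch["pro_P_bins"])
    s_pro, z_pro = encode_protein(params["protein"], pro_cfg, batch["pro_tokens"],
                                  z0_pro, batch["pro_mask"])
    adapters = params.get("adapters", {})
    if "ligand" in adapters:
        s_lig = linear(adapters["ligand"], s_lig)
    if "protein" in adapters:
        s_pro = linear(adapters["protein"], s_pro)
    s, z, Tl = assemble_complex(s_lig, z_lig, s_pro, z_pro)
    mask = np.concatenate([batch["lig_mask"], batch["pro_mask"]], axis=1)
    trunk_cfg = cfg.trunk_encoder_config
    for lp in params["trunk"]:
        s, z, _ = encoder_layer(lp, trunk_cfg, s, z, mask)
    return s, Tl


def affinity_forward(params: dict, cfg: ComplexConfig, batch: dict,
                     s_updated=None, ligand_tokens=None):
    """Predicted pK per complex: both [CLS] rows → Linear → GELU → Linear."""
    if s_updated is None:
        s_updated, ligand_tokens = complex_forward(params, cfg, batch)
    h = anp.concatenate([s_updated[:, 0, :], s_updated[:, ligand_tokens, :]], axis=-1)
    ah = params["affinity"]
    return linear(ah["l2"], gelu(linear(ah["l1"], h)))[:, 0]


def binding_site_forward(params: dict, cfg: ComplexConfig, batch: dict,
                         s_updated=None, ligand_tokens=None,
                         return_logits: bool = False):
    """Per-residue binding-site probabilities (protein [CLS] excluded)."""
    if s_updated is None:
        s_updated, ligand_tokens = complex_forward(params, cfg, batch)
    s_res = s_updated[:, ligand_tokens + 1:, :]
    sh = params["site"]
    logits = linear(sh["l2"], gelu(linear(sh["l1"], s_res)))[..., 0]
    if return_logits:
        return logits
    return sigmoid(logits)


def complex_losses(params: dict, cfg: ComplexConfig, batch: dict,
                   task: str = "both", return_parts: bool = False):
    """MSE affinity loss + λ · BCE site loss on one padded batch."""
    s_upd, Tl = complex_forward(params, cfg, batch)
    zero = 0.0
    l_mse = zero
    l_bce = zero
    if task in ("affinity", "both"):
        yhat = affinity_forward(params, cfg, batch, s_upd, Tl)
        l_mse = anp.mean((yhat - batch["pk"]) ** 2)
    if task in ("site", "both"):
        logits = binding_site_forward(params, cfg, batch, s_upd, Tl,
                                      return_logits=True)
        res_mask = batch["pro_mask"][:, 1:]
        l_bce = bce_logits(logits, batch["site_labels"], res_mask)
    total = l_mse + cfg.lambda_site * l_bce
    if return_parts:
        return total, (l_mse, l_bce)
    return total


def mse_site_losses(y, yhat, site_labels, site_probs, eps: float = 1e-7):
    """Plain-array loss evaluation used for reporting.

    ``L_MSE`` is the batch-mean squared error of predicted pK; ``L_BCE`` the
    residue-mean binary cross-entropy of clipped probabilities.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("affinity label/prediction length mismatch")
    l_mse = float(np.mean((yhat - y) ** 2))
    lab = np.asarray(site_labels, dtype=float).ravel()
    p = np.clip(np.asarray(site_probs, dtype=float).ravel(), eps, 1 - eps)
    if lab.shape != p.shape:
        raise ValueError("site label/prediction length mismatch")
    l_bce = float(-np.mean(lab * np.log(p) + (1 - lab) * np.log(1 - p)))
    return l_mse, l_bce


def collate_complexes(items: list[dict], cfg: ComplexConfig) -> dict:
    """Pad a list of complexes into one batch.

    Each item carries ``ligand`` (:class:`~pairbind.geometry.Molecule`),
    ``protein`` (:class:`ProteinInput`) and optional ``pk`` /
    ``site_labels``.
    """
    from .vocab import ATOM_INDEX, CLS, RESIDUE_INDEX, encode_atom_types, encode_residue_types

    B = len(items)
    scheme = cfg.ligand.binning
    lig_feats, pro_feats = [], []
    for it in items:
        # features are deterministic per item+config; cache them on the item
        # so repeated collation across epochs costs only the padding
        if "_lig_feat" not in it:
            pf = featurize(it["ligand"], scheme=scheme, include_cls=True)
            if not cfg.use_distance:
                pf.D_bins = np.zeros_like(pf.D_bins)
            if not cfg.use_positions:
                pf.P_bins = np.zeros_like(pf.P_bins)
            it["_lig_feat"] = pf
            it["_pro_feat"] = featurize_protein(
                it["protein"], scheme=cfg.protein.binning,
                use_distance=cfg.use_distance, use_positions=cfg.use_positions)
        lig_feats.append(it["_lig_feat"])
        pro_feats.append(it["_pro_feat"])
    Tl = max(f.n_tokens for f in lig_feats)
    Tp = max(f.n_tokens for f in pro_feats)
    batch = {
        "lig_tokens": np.zeros((B, Tl), dtype=int),
        "lig_mask": np.zeros((B, Tl)),
        "lig_D_bins": np.zeros((B, Tl, Tl), dtype=int),
        "lig_P_bins": np.zeros((B, Tl, Tl, 3), dtype=int),
        "pro_tokens": np.zeros((B, Tp), dtype=int),
        "pro_mask": np.zeros((B, Tp)),
        "pro_D_bins": np.zeros((B, Tp, Tp), dtype=int),
        "pro_P_bins": np.zeros((B, Tp, Tp, 3), dtype=int),
        "pk": np.zeros(B),
        "site_labels": np.zeros((B, Tp - 1)),
        "ids": [it.get("id", "") for it in items],
    }
    for b, (it, lf, pf) in enumerate(zip(items, lig_feats, pro_feats)):
        tl, tp = lf.n_tokens, pf.n_tokens
        batch["lig_tokens"][b, 0] = ATOM_INDEX[CLS]
        batch["lig_tokens"][b, 1:tl] = encode_atom_types(it["ligand"].atom_types)
        batch["lig_mask"][b, :tl] = 1.0
        batch["lig_D_bins"][b, :tl, :tl] = lf.D_bins
        batch["lig_P_bins"][b, :tl, :tl] = lf.P_bins
        batch["pro_tokens"][b, 0] = RESIDUE_INDEX[CLS]
        batch["pro_tokens"][b, 1:tp] = encode_residue_types(it["protein"].residue_types)
        batch["pro_mask"][b, :tp] = 1.0
        batch["pro_D_bins"][b, :tp, :tp] = pf.D_bins
        batch["pro_P_bins"][b, :tp, :tp] = pf.P_bins
        if "pk" in it and it["pk"] is not None:
            batch["pk"][b] = it["pk"]
        if "site_labels" in it and it["site_labels"] is not None:
            batch["site_labels"][b, :tp - 1] = it["site_labels"]
    return batch
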