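"""Pretraining and fine-tuning loops.

Both loops use Adam (β₁ = 0.9, β₂ = 0.99) with decoupled weight decay, a
linear warmup followed by linear decay to zero, and gradient clipping at
global norm 1.  Every source of randomness — corruption draws, batch order —
derives from the run seed through per-epoch seed sequences, so loss curves
reproduce exactly and a run resumed from a checkpoint at an epoch boundary
continues identically.

The full-scale reference settings (peak learning rate 1e-4 with 10,000 warmup steps
for pretraining; batch size 8 and learning rate 3e-4 for fine-tuning) are
the defaults; desk-scale presets shrink widths and epochs to single-CPU
budgets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from autograd import value_and_grad

from .complexes import (
    ComplexConfig, collate_complexes, complex_losses, init_complex_params,
)
from .encoder import (
    EncoderConfig, collate_molecules, init_encoder_params,
    init_pretrain_head_params, pretrain_loss,
)
from .geometry import Molecule, featurize
from .metrics import evaluate_affinity, evaluate_sites
from .nn import AdamState, adam_step, clip_global_norm, linear_warmup_decay
from .physics import LJParams, corrupt
from .vocab import ATOM_INDEX, CLS, encode_atom_types

__all__ = [
    "TrainConfig", "pretrain", "finetune", "evaluate_complex_model",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Optimization settings shared by the pretraining/fine-tuning loops."""

    batch_size: int = 128
    epochs: int = 20
    lr: float = 1e-4
    warmup_steps: int = 10_000
    weight_decay: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.99)
    grad_clip: float = 1.0
    seed: int = 0
    mask_ratio_range: tuple[float, float] = (0.1, 0.3)
    eta_range: tuple[float, float] = (0.1, 0.5)
    xi_std: float = 0.05
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lambda_site: float = 1.0
    task: str = "both"
    ema_decay: float = 0.0  # 0 disables Polyak weight averaging
    swa_start_frac: float = 0.0  # >0: average epoch-end weights from this fraction of training on

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("lr must be non-negative (0 freezes parameters)")
        if self.warmup_steps < 0:
            raise ValueError("warmup_steps must be non-negative")

    @classmethod
    def desk(cls, **kw) -> "TrainConfig":
        """Small-batch single-CPU preset."""
        base = dict(batch_size=16, epochs=20, lr=1e-3, warmup_steps=30)
        base.update(kw)
        return cls(**base)


def _corrupted_batch(molecules, cfg: EncoderConfig, tc: TrainConfig,
                     rng: np.random.Generator, lj: LJParams) -> dict:
    samples = []
    for mol in molecules:
        cs = corrupt(mol, rng, mask_ratio_range=tc.mask_ratio_range,
                     eta_range=tc.eta_range, xi_std=tc.xi_std, params=lj)
        noisy_mol = Molecule(atom_types=cs.input_types, coords=cs.noisy_coords,
                             id=mol.id)
        pf = featurize(noisy_mol, scheme=cfg.binning, include_cls=True)
        clean_D = np.linalg.norm(
            cs.clean_coords[:, None, :] - cs.clean_coords[None, :, :], axis=-1)
        samples.append({
            "token_idx": [ATOM_INDEX[CLS]] + encode_atom_types(cs.input_types),
            "pair": pf,
            "clean_D": clean_D,
            "noisy_coords": cs.noisy_coords,
            "clean_coords": cs.clean_coords,
            "target_types": encode_atom_types(cs.target_types),
            "mask_indices": cs.mask_indices,
        })
    return collate_molecules(samples, cfg.binning)


def pretrain(
    molecules: list[Molecule],
    cfg: EncoderConfig | None = None,
    train_cfg: TrainConfig | None = None,
    lj_params: LJParams | None = None,
    state: dict | None = None,
    progress: bool = False,
) -> dict:
    """Self-supervised pretraining on a corpus of clean conformers.

    Each epoch reshuffles the corpus, corrupts every molecule afresh
    (mask + gradient-directed noise), featurizes the *noisy* coordinates and
    minimizes the three-head loss against the clean targets.  Returns a
    state dict (parameters, heads, optimizer, loss history) that can be
    passed back in to resume training.
    """
    if not molecules:
        raise ValueError("empty pretraining dataset")
    cfg = cfg or EncoderConfig.tiny()
    tc = train_cfg or TrainConfig.desk()
    lj = lj_params or LJParams()
    if state is None:
        params = {"enc": init_encoder_params(cfg),
                  "heads": init_pretrain_head_params(cfg)}
        opt = AdamState(params)
        start_epoch = 0
        history: list[dict] = []
    else:
        params = state["params"]
        opt = state["opt"]
        start_epoch = state["epoch"]
        history = list(state["history"])
    n_batches = int(np.ceil(len(molecules) / tc.batch_size))
    total_steps = tc.epochs * n_batches

    def loss_fn(p, batch):
        return pretrain_loss(p["enc"], p["heads"], cfg, batch,
                             weights=tc.loss_weights)

    vag = value_and_grad(loss_fn)
    iterator = range(start_epoch, tc.epochs)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="pretrain")
    for epoch in iterator:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=tc.seed, spawn_key=(epoch,)))
        order = rng.permutation(len(molecules))
        epoch_losses = []
        for b in range(n_batches):
            idx = order[b * tc.batch_size:(b + 1) * tc.batch_size]
            batch = _corrupted_batch([molecules[i] for i in idx], cfg, tc, rng, lj)
            step = epoch * n_batches + b
            lr = linear_warmup_decay(step, tc.lr, tc.warmup_steps, total_steps)
            loss, grads = vag(params, batch)
            grads = clip_global_norm(grads, tc.grad_clip)
            params = adam_step(params, grads, opt, lr, tc.betas,
                               weight_decay=tc.weight_decay)
            epoch_losses.append(float(loss))
        history.append({"epoch": epoch, "loss": float(np.mean(epoch_losses))})
    return {"params": params, "opt": opt, "epoch": tc.epochs,
            "history": history, "config": cfg}


def finetune(
    train_items: list[dict],
    cfg: ComplexConfig | None = None,
    train_cfg: TrainConfig | None = None,
    ligand_params: dict | None = None,
    protein_params: dict | None = None,
    val_items: list[dict] | None = None,
    progress: bool = False,
) -> dict:
    """Supervised training of the complex model on labeled complexes.

    ``ligand_params`` transplants a pretrained ligand encoder (omit for the
    from-scratch ablation); ``protein_params`` warm-starts the protein
    encoder.  If validation items are given, the epoch with the best
    validation affinity RMSE is kept as ``best_params``.
    """
    if not train_items:
        raise ValueError("empty fine-tuning dataset")
    cfg = cfg or ComplexConfig()
    tc = train_cfg or TrainConfig.desk(batch_size=8, lr=3e-4)
    if tc.task in ("affinity", "both") and any(
            it.get("pk") is None for it in train_items):
        raise ValueError("affinity task enabled but pK labels missing")
    if tc.task in ("site", "both") and any(
            it.get("site_labels") is None for it in train_items):
        raise ValueError("site task enabled but site labels missing")
    cfg.lambda_site = tc.lambda_site
    params = init_complex_params(cfg, ligand_params=ligand_params,
                                 protein_params=protein_params)
    if tc.task in ("affinity", "both"):
        # start the affinity head at the training-label mean so the early
        # MSE reflects label variance, not an arbitrary offset (a large
        # initial error would dominate the clipped gradient budget)
        pk_mean = float(np.mean([it["pk"] for it in train_items]))
        params["affinity"]["l2"]["b"] = params["affinity"]["l2"]["b"] + pk_mean
    opt = AdamState(params)
    n_batches = int(np.ceil(len(train_items) / tc.batch_size))
    total_steps = tc.epochs * n_batches

    frozen = {}
    if cfg.freeze_encoders:
        frozen = {"ligand": params["ligand"], "protein": params["protein"]}

    def loss_fn(p, batch):
        if frozen:
            p = dict(p, **frozen)
        return complex_losses(p, cfg, batch, task=tc.task)

    vag = value_and_grad(loss_fn)
    history: list[dict] = []
    best = {"params": params, "val_rmse": np.inf, "epoch": -1}
    from autograd.misc import flatten as _flatten
    ema_flat, unflatten_ema = _flatten(params)
    ema_flat = ema_flat.copy()
    swa_sum, swa_count = None, 0
    swa_start = int(np.ceil(tc.swa_start_frac * tc.epochs)) if tc.swa_start_frac > 0 else None
    iterator = range(tc.epochs)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="finetune")
    for epoch in iterator:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=tc.seed, spawn_key=(epoch,)))
        order = rng.permutation(len(train_items))
        epoch_losses = []
        for b in range(n_batches):
            idx = order[b * tc.batch_size:(b + 1) * tc.batch_size]
            batch = collate_complexes([train_items[i] for i in idx], cfg)
            step = epoch * n_batches + b
            lr = linear_warmup_decay(step, tc.lr, tc.warmup_steps, total_steps)
            loss, grads = vag(params, batch)
            if frozen:
                for k in frozen:
                    grads[k] = _zero_like_tree(grads[k])
            grads = clip_global_norm(grads, tc.grad_clip)
            params = adam_step(params, grads, opt, lr, tc.betas,
                               weight_decay=tc.weight_decay)
            if tc.ema_decay > 0:
                flat_now, _ = _flatten(params)
                ema_flat = tc.ema_decay * ema_flat + (1 - tc.ema_decay) * flat_now
            epoch_losses.append(float(loss))
        if swa_start is not None and epoch >= swa_start:
            flat_now, _ = _flatten(params)
            swa_sum = flat_now.copy() if swa_sum is None else swa_sum + flat_now
            swa_count += 1
        rec = {"epoch": epoch, "loss": float(np.mean(epoch_losses))}
        if val_items:
            rep = evaluate_complex_model(params, cfg, val_items, task=tc.task)
            rec["val"] = {k: v for k, v in rep.items()
                          if isinstance(v, (int, float))}
            val_rmse = rep.get("rmse", np.nan)
            if np.isfinite(val_rmse) and val_rmse < best["val_rmse"]:
                best = {"params": params, "val_rmse": val_rmse, "epoch": epoch}
        history.append(rec)
    result = {"params": params, "config": cfg, "history": history}
    if tc.ema_decay > 0:
        result["ema_params"] = unflatten_ema(ema_flat)
    if swa_count:
        result["swa_params"] = unflatten_ema(swa_sum / swa_count)
    if val_items:
        result["best_params"] = best["params"]
        result["best_epoch"] = best["epoch"]
    return result


def _zero_like_tree(tree):
    if isinstance(tree, dict):
        return {k: _zero_like_tree(v) for k, v in tree.items()}
    if isinstance(tree, list):
        return [_zero_like_tree(v) for v in tree]
    return np.zeros_like(tree)


def evaluate_complex_model(params: dict, cfg: ComplexConfig, items: list[dict],
                           task: str = "both", batch_size: int = 16) -> dict:
    """Predict over a dataset and report affinity and/or site metrics."""
    from .complexes import affinity_forward, binding_site_forward, complex_forward

    y, yhat = [], []
    labels, probs = [], []
    per_complex = []
    for i in range(0, len(items), batch_size):
        chunk = items[i:i + batch_size]
        batch = collate_complexes(chunk, cfg)
        s_upd, Tl = complex_forward(params, cfg, batch)
        if task in ("affinity", "both"):
            pred = np.asarray(affinity_forward(params, cfg, batch, s_upd, Tl))
            y.extend(batch["pk"])
            yhat.extend(pred)
        if task in ("site", "both"):
            p = np.asarray(binding_site_forward(params, cfg, batch, s_upd, Tl))
            for b, it in enumerate(chunk):
                n = it["protein"].n_residues
                labels.extend(np.asarray(it["site_labels"])[:n])
                probs.extend(p[b, :n])
        for b, it in enumerate(chunk):
            rec = {"id": it.get("id", "")}
            if task in ("affinity", "both"):
                rec["predicted_pk"] = float(pred[b])
            per_complex.append(rec)
    out: dict = {"n": len(items), "per_complex": per_complex}
    if y:
        rep = evaluate_affinity(np.array(y), np.array(yhat))
        out.update(rmse=rep.rmse, pearson=rep.pearson, spearman=rep.spearman)
        out["y"] = np.array(y)
        out["yhat"] = np.array(yhat)
    if labels:
        rep = evaluate_sites(np.array(labels), np.array(probs))
        out.update(roc_auc=rep.roc_auc, f1=rep.f1)
        out["site_labels"] = np.array(labels)
        out["site_probs"] = np.array(probs)
    return out


# --- checkpoint serialization -------------------------------------------------

def _flatten_tree(tree, prefix="") -> dict:
    out = {}
    if isinstance(tree, dict):
        for k, v in tree.items():
            out.update(_flatten_tree(v, f"{prefix}{k}/"))
    elif isinstance(tree, list):
        for i, v in enumerate(tree):
            out.update(_flatten_tree(v, f"{prefix}{i}/"))
    else:
        out[prefix[:-1]] = np.asarray(tree)
    return out


def _unflatten_tree(flat: dict):
    root: dict = {}
    for key, val in flat.items():
        parts = key.split("/")
        node = root
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = val

    def restore(node):
        if not isinstance(node, dict):
            return node
        keys = list(node.keys())
        if keys and all(k.isdigit() for k in keys):
            return [restore(node[str(i)]) for i in range(len(keys))]
        return {k: restore(v) for k, v in node.items()}

    return restore(root)


CHECKPOINT_VERSION = 1


def save_checkpoint(path, params: dict, config=None, extra: dict | None = None) -> None:
    """Serialize a parameter tree (plus config metadata) to one ``.npz``."""
    flat = _flatten_tree(params)
    meta = {"version": CHECKPOINT_VERSION, "extra": extra or {}}
    if config is not None:
        meta["config"] = config.to_dict() if hasattr(config, "to_dict") else config
    np.savez(path, __meta__=json.dumps(meta, default=_json_default),
             **{f"p:{k}": v for k, v in flat.items()})


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_checkpoint(path) -> tuple[dict, dict]:
    """Inverse of :func:`save_checkpoint`: returns ``(params, meta)``."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        flat = {k[2:]: npz[k] for k in npz.files if k.startswith("p:")}
    return _unflatten_tree(flat), meta
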