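"""Pair-biased transformer: reduction, recycling, heads, equivariance."""

import autograd.numpy as anp
import numpy as np
import pytest
from autograd import grad
from autograd.misc import flatten

from pairbind.encoder import (
    EncoderConfig, NEG_INF, collate_molecules, embed_pair_bins, encode_batch,
    encoder_layer, init_encoder_params, init_pretrain_head_params,
    pretrain_heads, pretrain_loss,
)
from pairbind.geometry import Molecule, featurize
from pairbind.nn import gelu, layer_norm, linear, softmax
from pairbind.physics import corrupt
from pairbind.vocab import ATOM_INDEX, CLS, N_ATOM_CLASSES, encode_atom_types

from conftest import random_molecule, random_rigid_motion


def vanilla_layer_reference(lp, cfg, s):
    """Independent plain transformer layer (no pair bias), same weights."""
    B, T, d = s.shape
    H, dk = cfg.n_heads, cfg.d_head
    h = layer_norm(lp["ln1"], s)
    def split(x):
        return np.transpose(np.reshape(x, (B, T, H, dk)), (0, 2, 1, 3))
    q, k, v = (split(linear(lp[w], h)) for w in ("wq", "wk", "wv"))
    att = softmax(q @ np.transpose(k, (0, 1, 3, 2)) / np.sqrt(dk), axis=-1)
    o = np.reshape(np.transpose(att @ v, (0, 2, 1, 3)), (B, T, d))
    s = s + linear(lp["wo"], o)
    h2 = layer_norm(lp["ln2"], s)
    return s + linear(lp["ffn2"], gelu(linear(lp["ffn1"], h2)))


def featurized_batch(cfg, molecules):
    samples = []
    for mol in molecules:
        pf = featurize(mol, scheme=cfg.binning)
        clean_D = np.linalg.norm(
            mol.coords[:, None, :] - mol.coords[None, :, :], axis=-1)
        samples.append({
            "token_idx": [ATOM_INDEX[CLS]] + encode_atom_types(mol.atom_types),
            "pair": pf, "clean_D": clean_D, "noisy_coords": mol.coords,
            "clean_coords": mol.coords,
            "target_types": encode_atom_types(mol.atom_types),
            "mask_indices": np.array([0]),
        })
    return collate_molecules(samples, cfg.binning)


@pytest.fixture(scope="module")
def cfg():
    return EncoderConfig.tiny(seed=0)


@pytest.fixture(scope="module")
def params(cfg):
    return init_encoder_params(cfg)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            EncoderConfig(d_model=65, n_heads=4)
        with pytest.raises(ValueError):
            EncoderConfig(n_layers=0)

    def test_paper_scale_defaults(self):
        c = EncoderConfig()
        assert (c.n_layers, c.d_model, c.n_heads, c.d_ffn) == (15, 512, 4, 2048)


class TestPairBiasedAttention:
    def test_zero_bias_reduces_to_vanilla_transformer(self, cfg, params, rng):
        s = rng.normal(size=(2, 5, cfg.d_model))
        z = np.zeros((2, 5, 5, cfg.d_pair))
        lp = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in params["layers"][0].items()}
        lp["pair_bias"] = {"w": np.zeros_like(lp["pair_bias"]["w"]),
                           "b": np.zeros_like(lp["pair_bias"]["b"])}
        s_out, _, _ = encoder_layer(lp, cfg, s, z)
        ref = vanilla_layer_reference(lp, cfg, s)
        assert np.abs(s_out - ref).max() < 1e-6

    def test_masked_column_gets_no_attention(self, cfg, params, rng):
        s = rng.normal(size=(1, 6, cfg.d_model))
        z = rng.normal(size=(1, 6, 6, cfg.d_pair))
        mask = np.ones((1, 6))
        mask[0, 3] = 0.0
        _, _, logits = encoder_layer(params["layers"][0], cfg, s, z, mask)
        att = softmax(logits + (1.0 - mask[:, None, None, :]) * NEG_INF, axis=-1)
        assert att[0, :, :, 3].max() < 1e-6

    def test_determinism(self, cfg, params, rng):
        s = rng.normal(size=(1, 4, cfg.d_model))
        z = rng.normal(size=(1, 4, 4, cfg.d_pair))
        a1 = encoder_layer(params["layers"][0], cfg, s, z)
        a2 = encoder_layer(params["layers"][0], cfg, s, z)
        assert np.array_equal(np.asarray(a1[0]), np.asarray(a2[0]))
        assert np.array_equal(np.asarray(a1[1]), np.asarray(a2[1]))


class TestPairUpdate:
    def test_zero_projection_keeps_pair_representation(self, cfg, params, rng):
        lp = dict(params["layers"][0])
        lp["z_proj"] = {"w": np.zeros_like(lp["z_proj"]["w"]),
                        "b": np.zeros_like(lp["z_proj"]["b"])}
        s = rng.normal(size=(1, 4, cfg.d_model))
        z = rng.normal(size=(1, 4, 4, cfg.d_pair))
        _, z_out, _ = encoder_layer(lp, cfg, s, z)
        assert np.array_equal(np.asarray(z_out), z)

    def test_residual_form(self, cfg, params, rng):
        """z_next − z_prev equals the projected attention logits."""
        lp = params["layers"][0]
        s = rng.normal(size=(1, 4, cfg.d_model))
        z = rng.normal(size=(1, 4, 4, cfg.d_pair))
        _, z_out, logits = encoder_layer(lp, cfg, s, z)
        expected = linear(lp["z_proj"], np.transpose(np.asarray(logits), (0, 2, 3, 1)))
        assert np.abs(np.asarray(z_out) - z - expected).max() < 1e-12

    def test_freezing_pair_update_changes_output(self, cfg, params, rng):
        mol = random_molecule(rng, 6)
        batch = featurized_batch(cfg, [mol])
        z0 = embed_pair_bins(params, batch["D_bins"], batch["P_bins"])
        s_on, _ = encode_batch(params, cfg, batch["token_idx"], z0, batch["mask"])
        s_off, _ = encode_batch(params, cfg, batch["token_idx"], z0, batch["mask"],
                                pair_update_on=False)
        assert np.abs(np.asarray(s_on) - np.asarray(s_off)).max() > 1e-8


class TestEncode:
    def test_permutation_equivariance(self, cfg, params, rng):
        mol = random_molecule(rng, 7)
        batch = featurized_batch(cfg, [mol])
        z0 = embed_pair_bins(params, batch["D_bins"], batch["P_bins"])
        s, _ = encode_batch(params, cfg, batch["token_idx"], z0, batch["mask"])
        # permute atoms (keep [CLS] row 0 fixed), permuting features consistently
        perm = np.r_[0, 1 + rng.permutation(7)]
        token_p = batch["token_idx"][:, perm]
        Db = batch["D_bins"][:, perm][:, :, perm]
        Pb = batch["P_bins"][:, perm][:, :, perm]
        z0p = embed_pair_bins(params, Db, Pb)
        sp, _ = encode_batch(params, cfg, token_p, z0p, batch["mask"])
        assert np.abs(np.asarray(sp) - np.asarray(s)[:, perm]).max() < 1e-5

    def test_single_atom_molecule(self, cfg, params):
        mol = Molecule(["C"], np.zeros((1, 3)))
        batch = featurized_batch(cfg, [mol])
        z0 = embed_pair_bins(params, batch["D_bins"], batch["P_bins"])
        s, z = encode_batch(params, cfg, batch["token_idx"], z0, batch["mask"])
        assert np.asarray(s).shape == (1, 2, cfg.d_model)

    def test_rigid_motion_leaves_output_unchanged(self, cfg, params, rng):
        mol = random_molecule(rng, 6)
        R, t = random_rigid_motion(rng)
        moved = Molecule(mol.atom_types, mol.coords @ R.T + t)
        outs = []
        for m in (mol, moved):
            batch = featurized_batch(cfg, [m])
            z0 = embed_pair_bins(params, batch["D_bins"], batch["P_bins"])
            s, _ = encode_batch(params, cfg, batch["token_idx"], z0, batch["mask"])
            outs.append(np.asarray(s))
        assert np.abs(outs[0] - outs[1]).max() < 1e-5

    def test_max_len_guard(self, cfg, params):
        cfg_small = EncoderConfig.tiny(seed=0, max_len=4)
        mol = Molecule(["C"] * 6, np.arange(18).reshape(6, 3) * 1.5)
        batch = featurized_batch(cfg_small, [mol])
        z0 = embed_pair_bins(params, batch["D_bins"], batch["P_bins"])
        with pytest.raises(ValueError):
            encode_batch(params, cfg_small, batch["token_idx"], z0, batch["mask"])

    def test_pair_embedding_determinism_and_shape(self, cfg, params, rng):
        mol = random_molecule(rng, 5)
        batch = featurized_batch(cfg, [mol])
        z1 = embed_pair_bins(params, batch["D_bins"], batch["P_bins"])
        z2 = embed_pair_bins(params, batch["D_bins"], batch["P_bins"])
        assert np.array_equal(np.asarray(z1), np.asarray(z2))
        assert np.asarray(z1).shape == (1, 6, 6, cfg.d_pair)


class TestPretrainHeads:
    def test_distance_head_symmetric_nonnegative(self, cfg, params, rng):
        heads = init_pretrain_head_params(cfg)
        mol = random_molecule(rng, 6)
        batch = featurized_batch(cfg, [mol])
        z0 = embed_pair_bins(params, batch["D_bins"], batch["P_bins"])
        s, z = encode_batch(params, cfg, batch["token_idx"], z0, batch["mask"])
        type_logits, dist, coord = pretrain_heads(heads, s, z, batch["noisy_coords"])
        dist = np.asarray(dist)
        assert np.abs(dist - np.transpose(dist, (0, 2, 1))).max() < 1e-12
        assert dist.min() >= 0
        assert np.asarray(type_logits).shape == (1, 6, N_ATOM_CLASSES)

    def test_zeroed_coordinate_head_returns_noisy_input(self, cfg, params, rng):
        heads = init_pretrain_head_params(cfg)
        heads["coord"]["l2"] = {"w": np.zeros_like(heads["coord"]["l2"]["w"]),
                                "b": np.zeros_like(heads["coord"]["l2"]["b"])}
        mol = random_molecule(rng, 5)
        batch = featurized_batch(cfg, [mol])
        z0 = embed_pair_bins(params, batch["D_bins"], batch["P_bins"])
        s, z = encode_batch(params, cfg, batch["token_idx"], z0, batch["mask"])
        _, _, coord = pretrain_heads(heads, s, z, batch["noisy_coords"])
        assert np.array_equal(np.asarray(coord), batch["noisy_coords"])

    def test_gradient_flows_to_all_parameter_arrays(self, cfg, rng):
        """No dead subgraphs: every parameter array receives gradient."""
        params = init_encoder_params(cfg)
        heads = init_pretrain_head_params(cfg)
        mols = [random_molecule(rng, 6) for _ in range(2)]
        samples = []
        for mol in mols:
            cs = corrupt(mol, seed=3)
            noisy = Molecule(cs.input_types, cs.noisy_coords)
            pf = featurize(noisy, scheme=cfg.binning)
            clean_D = np.linalg.norm(
                cs.clean_coords[:, None] - cs.clean_coords[None, :], axis=-1)
            samples.append({
                "token_idx": [ATOM_INDEX[CLS]] + encode_atom_types(cs.input_types),
                "pair": pf, "clean_D": clean_D, "noisy_coords": cs.noisy_coords,
                "clean_coords": cs.clean_coords,
                "target_types": encode_atom_types(cs.target_types),
                "mask_indices": cs.mask_indices,
            })
        batch = collate_molecules(samples, cfg.binning)
        g = grad(lambda p: pretrain_loss(p["enc"], p["heads"], cfg, batch))(
            {"enc": params, "heads": heads})

        def check(tree, path=""):
            if isinstance(tree, dict):
                for k, v in tree.items():
                    check(v, f"{path}/{k}")
            elif isinstance(tree, list):
                for i, v in enumerate(tree):
                    check(v, f"{path}/{i}")
            else:
                assert np.abs(tree).max() > 0, f"dead gradient at {path}"

        check(g)
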