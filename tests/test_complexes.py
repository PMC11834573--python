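"""Complex assembly, affinity/site heads and their losses."""

import numpy as np
import pytest

from pairbind.complexes import (
    ComplexConfig, ProteinInput, affinity_forward, assemble_complex,
    binding_site_forward, collate_complexes, complex_forward, complex_losses,
    encode_protein, featurize_protein, init_complex_params, mse_site_losses,
)
from pairbind.encoder import EncoderConfig, embed_pair_bins, encode_batch
from pairbind.geometry import Molecule
from pairbind.vocab import RESIDUE_INDEX, RESIDUE_TOKENS, CLS

from conftest import random_rigid_motion


def toy_protein(rng, n=4) -> ProteinInput:
    ca = np.cumsum(rng.normal(0, 1, (n, 3)) + np.array([3.8, 0, 0]), axis=0)
    heavy = [np.vstack([ca[i], ca[i] + rng.normal(0, 1, 3)]) for i in range(n)]
    types = list(rng.choice(list("ARNDC"), size=n))
    return ProteinInput(types, heavy, ca)


@pytest.fixture(scope="module")
def cfg():
    return ComplexConfig(ligand=EncoderConfig.tiny(seed=0),
                         protein=EncoderConfig.tiny(seed=1),
                         trunk_layers=2, seed=0)


@pytest.fixture(scope="module")
def params(cfg):
    return init_complex_params(cfg)


def one_item(rng, cfg, n=5, m=4):
    lig = Molecule(list(np.random.default_rng(0).choice(["C", "N", "O"], m)),
                   np.cumsum(rng.normal(0, 1, (m, 3)) + np.array([1.5, 0, 0]), axis=0))
    prot = toy_protein(rng, n)
    labels = np.zeros(n)
    labels[0] = 1
    return {"id": "t", "ligand": lig, "protein": prot, "pk": 6.5,
            "site_labels": labels}


class TestAssembly:
    def test_shapes_and_zero_blocks(self, rng):
        d, p = 8, 4
        s_lig = rng.normal(size=(1, 3, d))   # m=2 + [CLS]
        z_lig = rng.normal(size=(1, 3, 3, p))
        s_pro = rng.normal(size=(1, 4, d))   # n=3 + [CLS]
        z_pro = rng.normal(size=(1, 4, 4, p))
        s, z, Tl = assemble_complex(s_lig, z_lig, s_pro, z_pro)
        assert s.shape == (1, 7, d)
        assert z.shape == (1, 7, 7, p)
        assert Tl == 3
        assert np.all(np.asarray(z)[:, :3, 3:] == 0)
        assert np.all(np.asarray(z)[:, 3:, :3] == 0)
        assert np.array_equal(np.asarray(z)[:, :3, :3], z_lig)
        assert np.array_equal(np.asarray(z)[:, 3:, 3:], z_pro)

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            assemble_complex(rng.normal(size=(1, 3, 8)), rng.normal(size=(1, 3, 3, 4)),
                             rng.normal(size=(1, 4, 6)), rng.normal(size=(1, 4, 4, 4)))

    def test_relative_pose_invisible_to_model(self, rng, cfg):
        """Translating the ligand relative to the protein changes nothing:
        the assembled input carries no cross-molecule geometry."""
        item = one_item(rng, cfg)
        moved = dict(item)
        moved.pop("_lig_feat", None)
        moved = {k: v for k, v in item.items() if not k.startswith("_")}
        moved["ligand"] = Molecule(item["ligand"].atom_types,
                                   item["ligand"].coords + 250.0)
        b1 = collate_complexes([{k: v for k, v in item.items()
                                 if not k.startswith("_")}], cfg)
        b2 = collate_complexes([moved], cfg)
        for key in ("lig_D_bins", "lig_P_bins", "pro_D_bins", "pro_P_bins",
                    "lig_tokens", "pro_tokens"):
            assert np.array_equal(b1[key], b2[key])


class TestProteinEncoder:
    def test_single_residue_shapes(self, cfg):
        prot = ProteinInput(["A"], [np.zeros((1, 3))], np.zeros((1, 3)))
        pf = featurize_protein(prot, scheme=cfg.protein.binning)
        assert pf.D.shape == (2, 2)
        params = init_complex_params(cfg)
        tokens = np.array([[RESIDUE_INDEX[CLS], RESIDUE_INDEX["A"]]])
        z0 = embed_pair_bins(params["protein"], pf.D_bins[None], pf.P_bins[None])
        s, z = encode_protein(params["protein"], cfg.protein, tokens, z0)
        assert np.asarray(s).shape == (1, 2, cfg.protein.d_model)
        assert np.asarray(z).shape == (1, 2, 2, cfg.protein.d_pair)

    def test_rigid_motion_invariance(self, rng, cfg, params):
        prot = toy_protein(rng, 6)
        R, t = random_rigid_motion(rng)
        moved = ProteinInput(prot.residue_types,
                             [a @ R.T + t for a in prot.heavy_atom_coords],
                             prot.ca_coords @ R.T + t)
        outs = []
        for p in (prot, moved):
            pf = featurize_protein(p, scheme=cfg.protein.binning)
            tokens = np.array([[RESIDUE_INDEX[CLS]]
                               + [RESIDUE_INDEX[x] for x in p.residue_types]])
            z0 = embed_pair_bins(params["protein"], pf.D_bins[None], pf.P_bins[None])
            s, _ = encode_protein(params["protein"], cfg.protein, tokens, z0)
            outs.append(np.asarray(s))
        assert np.abs(outs[0] - outs[1]).max() < 1e-5

    def test_determinism(self, rng, cfg, params):
        prot = toy_protein(rng, 5)
        pf = featurize_protein(prot, scheme=cfg.protein.binning)
        tokens = np.array([[RESIDUE_INDEX[CLS]]
                           + [RESIDUE_INDEX[x] for x in prot.residue_types]])
        z0 = embed_pair_bins(params["protein"], pf.D_bins[None], pf.P_bins[None])
        s1, _ = encode_protein(params["protein"], cfg.protein, tokens, z0)
        s2, _ = encode_protein(params["protein"], cfg.protein, tokens, z0)
        assert np.array_equal(np.asarray(s1), np.asarray(s2))


class TestForwardHeads:
    def test_zeroed_affinity_head_predicts_zero(self, rng, cfg, params):
        p = dict(params)
        p["affinity"] = {
            "l1": params["affinity"]["l1"],
            "l2": {"w": np.zeros_like(params["affinity"]["l2"]["w"]),
                   "b": np.zeros_like(params["affinity"]["l2"]["b"])},
        }
        batch = collate_complexes([one_item(rng, cfg)], cfg)
        yhat = np.asarray(affinity_forward(p, cfg, batch))
        assert np.all(yhat == 0.0)

    def test_zeroed_site_head_gives_half_probabilities(self, rng, cfg, params):
        p = dict(params)
        p["site"] = {
            "l1": params["site"]["l1"],
            "l2": {"w": np.zeros_like(params["site"]["l2"]["w"]),
                   "b": np.zeros_like(params["site"]["l2"]["b"])},
        }
        item = one_item(rng, cfg, n=5)
        batch = collate_complexes([item], cfg)
        probs = np.asarray(binding_site_forward(p, cfg, batch))
        assert probs.shape == (1, 5)
        assert np.all(probs == 0.5)

    def test_site_output_length_matches_residues(self, rng, cfg, params):
        for n, m in ((3, 2), (7, 5)):
            batch = collate_complexes([one_item(rng, cfg, n=n, m=m)], cfg)
            probs = np.asarray(binding_site_forward(params, cfg, batch))
            assert probs.shape == (1, n)
            assert np.all((probs > 0) & (probs < 1))

    def test_batch_of_one_equals_padded_batch(self, rng, cfg, params):
        small = one_item(rng, cfg, n=4, m=3)
        big = one_item(rng, cfg, n=8, m=6)
        solo = collate_complexes([{k: v for k, v in small.items()
                                   if not k.startswith("_")}], cfg)
        padded = collate_complexes([{k: v for k, v in small.items()
                                     if not k.startswith("_")},
                                    {k: v for k, v in big.items()
                                     if not k.startswith("_")}], cfg)
        y_solo = np.asarray(affinity_forward(params, cfg, solo))
        y_pad = np.asarray(affinity_forward(params, cfg, padded))
        assert abs(y_solo[0] - y_pad[0]) < 1e-5
        p_solo = np.asarray(binding_site_forward(params, cfg, solo))
        p_pad = np.asarray(binding_site_forward(params, cfg, padded))
        assert np.abs(p_solo[0, :4] - p_pad[0, :4]).max() < 1e-5

    def test_block_extraction_bookkeeping(self, rng, cfg, params):
        item = one_item(rng, cfg, n=6, m=4)
        batch = collate_complexes([item], cfg)
        s_upd, Tl = complex_forward(params, cfg, batch)
        s_upd = np.asarray(s_upd)
        assert Tl == 5  # m + [CLS]
        s_protein = s_upd[:, Tl:, :]
        rebuilt = np.concatenate([s_upd[:, :Tl, :], s_protein], axis=1)
        assert np.array_equal(rebuilt, s_upd)

    def test_end_to_end_rigid_motion_invariance(self, rng, cfg, params):
        item = one_item(rng, cfg)
        R, t = random_rigid_motion(rng)
        moved = {k: v for k, v in item.items() if not k.startswith("_")}
        moved["ligand"] = Molecule(item["ligand"].atom_types,
                                   item["ligand"].coords @ R.T + t)
        R2, t2 = random_rigid_motion(rng)
        moved["protein"] = ProteinInput(
            item["protein"].residue_types,
            [a @ R2.T + t2 for a in item["protein"].heavy_atom_coords],
            item["protein"].ca_coords @ R2.T + t2)
        y1 = np.asarray(affinity_forward(params, cfg, collate_complexes(
            [{k: v for k, v in item.items() if not k.startswith("_")}], cfg)))
        y2 = np.asarray(affinity_forward(params, cfg,
                                         collate_complexes([moved], cfg)))
        assert abs(y1[0] - y2[0]) < 1e-5


class TestLosses:
    def test_perfect_predictions(self):
        l_mse, l_bce = mse_site_losses([5.0, 6.0], [5.0, 6.0],
                                       [1, 0, 1], [1.0, 0.0, 1.0])
        assert l_mse == 0.0
        assert l_bce == pytest.approx(0.0, abs=1e-6)

    def test_unit_offset_gives_unit_mse(self):
        y = np.array([4.0, 5.0, 9.0])
        l_mse, _ = mse_site_losses(y, y + 1, [1], [0.5])
        assert l_mse == pytest.approx(1.0, abs=1e-12)

    def test_half_probabilities_give_log_two(self):
        _, l_bce = mse_site_losses([1.0], [1.0], [0, 1, 1, 0], [0.5] * 4)
        assert l_bce == pytest.approx(np.log(2), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_site_losses([1.0, 2.0], [1.0], [1], [0.5])

    def test_joint_loss_composition(self, rng, cfg, params):
        item = one_item(rng, cfg)
        batch = collate_complexes([item], cfg)
        total, (l_mse, l_bce) = complex_losses(params, cfg, batch,
                                               return_parts=True)
        assert float(total) == pytest.approx(
            float(l_mse) + cfg.lambda_site * float(l_bce), abs=1e-12)


class TestProteinInputValidation:
    def test_rejects_empty_and_mismatched(self):
        with pytest.raises(ValueError):
            ProteinInput([], [], np.zeros((0, 3)))
        with pytest.raises(ValueError):
            ProteinInput(["A", "G"], [np.zeros((1, 3))], np.zeros((2, 3)))
        with pytest.raises(ValueError):
            ProteinInput(["A"], [np.zeros((0, 3))], np.zeros((1, 3)))
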