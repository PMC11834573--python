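"""Synthetic molecules, toy complexes and benchmark datasets.

Everything in this package is testable without downloads because this module
generates desk-scale stand-ins for the real corpora:

* **conformers** — self-avoiding 3D random walks with ~1.5 Å steps and
  element types drawn from a drug-like composition, giving physically
  plausible interatomic distances for the Lennard-Jones machinery;
* **toy complexes** — a random-walk Cα trace (3.8 Å steps) decorated with
  1–4 pseudo heavy atoms per residue, plus a ligand placed into a "pocket";
  binding-site labels follow the 6 Å heavy-atom rule by construction, and
  the pK label is a known linear function of residue–ligand contacts plus
  Gaussian noise, so parameter recovery can be checked exactly;
* **benchmarks** — complexes written out as SDF/PDB/CSV/split files in the
  formats the I/O module reads.

The pocket sits at the protein's core: the ligand centroid lands on the Cα
centroid (falling back to the most-central residue's Cα when the coil's
centroid lies in empty space) and the ligand is oriented by aligning its
principal axes to those of the core neighbourhood.  This makes the planted
signal inferable in principle: the model never sees the ligand-protein pose
(the assembled pair representation is block-diagonal with zero cross
blocks), so a learnable benchmark must tie both the pocket location and the
contact count to features each molecule carries on its own — here, the
protein's internal geometry and the ligand's size and shape.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .complexes import ProteinInput
from .data import (
    count_contacts, label_binding_sites, write_labels_csv, write_ligand_sdf,
    write_protein_pdb, write_split_file,
)
from .geometry import Molecule
from .vocab import AMINO_ACIDS

__all__ = ["SyntheticSpec", "generate_conformer", "generate_toy_complex",
           "generate_dataset", "make_benchmark"]

#: drug-like heavy-atom-dominated element composition for generated ligands
DEFAULT_ATOM_PROBS: dict[str, float] = {
    "C": 0.42, "H": 0.18, "N": 0.11, "O": 0.14, "S": 0.03, "P": 0.01,
    "F": 0.04, "Cl": 0.04, "Br": 0.01, "I": 0.005, "B": 0.005,
    "Na": 0.005, "Zn": 0.005,
}


@dataclass
class SyntheticSpec:
    """Study conditions of the synthetic benchmark.

    The affinity rule is ``pK = a * contacts + b + N(0, noise_std)`` clipped
    to [0, 14], where ``contacts`` counts (residue, ligand atom) pairs with
    any heavy atom strictly within ``contact_cutoff`` Å.  With the defaults
    the contact count varies enough across complexes that a noise-free
    linear fit on it reaches a held-out Pearson ceiling of about 0.97.
    """

    n_molecules: int = 300
    n_complexes: int = 100
    atom_count_range: tuple[int, int] = (6, 16)
    atom_type_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATOM_PROBS))
    bond_length: float = 1.5
    bond_length_std: float = 0.1
    min_atom_dist: float = 1.0
    residue_range: tuple[int, int] = (20, 60)
    ca_step: float = 3.8
    min_ca_dist: float = 3.0
    pocket_radius: float = 2.0
    contact_cutoff: float = 6.0
    affinity_a: float = 0.05
    affinity_b: float = 4.0
    noise_std: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules <= 0 or self.n_complexes <= 0:
            raise ValueError("counts must be positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")
        total = sum(self.atom_type_probs.values())
        self.atom_type_probs = {k: v / total for k, v in self.atom_type_probs.items()}

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["atom_count_range"] = list(self.atom_count_range)
        d["residue_range"] = list(self.residue_range)
        return d


def _self_avoiding_walk(rng: np.random.Generator, n: int, step: float,
                        step_std: float, min_dist: float,
                        max_tries: int = 2000) -> np.ndarray:
    """3D random walk whose points stay at least ``min_dist`` apart."""
    pts = [np.zeros(3)]
    tries = 0
    while len(pts) < n:
        d = rng.normal(0, 1, 3)
        d /= np.linalg.norm(d)
        cand = pts[-1] + d * max(rng.normal(step, step_std), 0.5 * step)
        dists = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1) if len(pts) > 1 else np.array([np.inf])
        if dists.min() >= min_dist:
            pts.append(cand)
            tries = 0
        else:
            tries += 1
            if tries > max_tries:
                raise RuntimeError("self-avoiding walk rejection budget exceeded")
    return np.array(pts)


def generate_conformer(spec: SyntheticSpec, seed: int | np.random.Generator,
                       mol_id: str = "") -> Molecule:
    """One random ligand conformer; deterministic per seed.

    Built as a self-avoiding walk with ~``bond_length`` steps; any failed
    walk retries with a fresh sub-seed a few times before raising.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.atom_count_range
    m = int(rng.integers(lo, hi + 1))
    symbols = list(spec.atom_type_probs)
    probs = np.array([spec.atom_type_probs[s] for s in symbols])
    types = [str(t) for t in rng.choice(symbols, size=m, p=probs)]
    for attempt in range(5):
        try:
            coords = _self_avoiding_walk(rng, m, spec.bond_length,
                                         spec.bond_length_std, spec.min_atom_dist)
            break
        except RuntimeError:
            if attempt == 4:
                raise
    mol = Molecule(atom_types=types, coords=coords, id=mol_id or f"mol{seed}")
    mol.validate_geometry(min_dist=0.5)
    return mol


def _principal_axes(x: np.ndarray) -> np.ndarray:
    """Deterministic principal-axis frame of a point cloud.

    Columns are eigenvectors of the centred covariance in descending
    eigenvalue order; each axis's sign is fixed by the skew of the points
    along it, and the frame is made right-handed.
    """
    xc = x - x.mean(axis=0)
    _, v = np.linalg.eigh(xc.T @ xc)
    R = v[:, ::-1].copy()
    for k in range(3):
        if (xc @ R[:, k]).sum() < 0:
            R[:, k] = -R[:, k]
    if np.linalg.det(R) < 0:
        R[:, 2] = -R[:, 2]
    return R


def _pocket_residue(ca: np.ndarray) -> int:
    """Index of the residue whose Cα is nearest the protein centroid."""
    centroid = ca.mean(axis=0)
    return int(np.argmin(np.linalg.norm(ca - centroid, axis=1)))


def generate_toy_complex(spec: SyntheticSpec, seed: int | np.random.Generator,
                         complex_id: str = ""):
    """One toy complex: ``(protein, ligand, site_labels, pk, info)``.

    The protein is a self-avoiding Cα walk with 1–4 heavy atoms per residue
    (the Cα plus pseudo side-chain atoms within ~2 Å).  The ligand is a
    conformer recentred onto the pocket residue's Cα plus a random offset
    shorter than ``pocket_radius``, then randomly rotated.  Site labels and
    the contact count are recomputed from the final geometry, so the labels
    are consistent with the 6 Å rule by construction.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(spec.residue_range[0], spec.residue_range[1] + 1))
    ca = _self_avoiding_walk(rng, n, spec.ca_step, 0.1 * spec.ca_step,
                             spec.min_ca_dist)
    residue_types = [str(t) for t in rng.choice(AMINO_ACIDS, size=n)]
    heavy = []
    for i in range(n):
        extra = int(rng.integers(0, 4))  # Cα + up to 3 pseudo heavy atoms
        side = [ca[i]]
        for _ in range(extra):
            offset = rng.normal(0, 1, 3)
            offset *= rng.uniform(1.2, 2.2) / np.linalg.norm(offset)
            side.append(ca[i] + offset)
        heavy.append(np.array(side))
    protein = ProteinInput(residue_types=residue_types, heavy_atom_coords=heavy,
                           ca_coords=ca, id=complex_id or "prot")

    ligand = generate_conformer(spec, rng, mol_id=complex_id or "lig")
    pocket = _pocket_residue(ca)
    centroid = ca.mean(axis=0)
    # docked-style pose: the ligand sits in the pocket at the protein's
    # core — its centroid lands on the Cα centroid (within the pocket
    # radius of the most-central residue's neighbourhood) and its
    # principal axes are aligned onto those of that neighbourhood.  The
    # pose — and hence the contact count — is thus a deterministic
    # function of the two structures rather than an unlearnable random
    # draw; only the small placement offset is random.
    neighbourhood = ca[np.linalg.norm(ca - centroid, axis=1) < 10.0]
    R_pocket = _principal_axes(neighbourhood if len(neighbourhood) >= 3 else ca)
    R_lig = _principal_axes(ligand.coords)
    coords = (ligand.coords - ligand.coords.mean(axis=0)) @ R_lig @ R_pocket.T
    offset = rng.normal(0, 1, 3)
    offset *= rng.uniform(0, spec.pocket_radius) / np.linalg.norm(offset)
    ligand = Molecule(atom_types=ligand.atom_types,
                      coords=coords + centroid + offset, id=ligand.id)
    if label_binding_sites(protein, ligand, spec.contact_cutoff).sum() == 0:
        # an extended coil can leave its centroid in empty space; anchor
        # the ligand on the pocket residue instead so a contact exists
        ligand = Molecule(atom_types=ligand.atom_types,
                          coords=coords + ca[pocket] + offset, id=ligand.id)

    site_labels = label_binding_sites(protein, ligand, spec.contact_cutoff)
    contacts = count_contacts(protein, ligand, spec.contact_cutoff)
    pk_clean = spec.affinity_a * contacts + spec.affinity_b
    pk = pk_clean + (rng.normal(0, spec.noise_std) if spec.noise_std > 0 else 0.0)
    pk = float(np.clip(pk, 0.0, 14.0))
    info = {"pocket_residue": pocket, "contacts": contacts, "pk_clean": pk_clean}
    return protein, ligand, site_labels, pk, info


def generate_dataset(spec: SyntheticSpec, seed: int | None = None,
                     n: int | None = None, prefix: str = "cpx") -> list[dict]:
    """A list of complex items ready for training/evaluation.

    Per-complex seeds are spawned from ``seed`` (default ``spec.seed``)
    through a seed sequence, so the dataset is reproducible and items are
    independent.
    """
    seed = spec.seed if seed is None else seed
    n = n if n is not None else spec.n_complexes
    children = np.random.SeedSequence(seed).spawn(n)
    items = []
    for i, ss in enumerate(children):
        cid = f"{prefix}{i:05d}"
        protein, ligand, labels, pk, info = generate_toy_complex(
            spec, np.random.default_rng(ss), complex_id=cid)
        items.append({"id": cid, "ligand": ligand, "protein": protein,
                      "site_labels": labels, "pk": pk, "info": info})
    return items


def generate_molecules(spec: SyntheticSpec, seed: int | None = None,
                       n: int | None = None) -> list[Molecule]:
    """Reproducible list of clean conformers for pretraining."""
    seed = spec.seed if seed is None else seed
    n = n if n is not None else spec.n_molecules
    children = np.random.SeedSequence(seed).spawn(n)
    return [generate_conformer(spec, np.random.default_rng(ss), mol_id=f"mol{i:05d}")
            for i, ss in enumerate(children)]


def make_benchmark(spec: SyntheticSpec, out_dir, seed: int | None = None,
                   split=(0.7, 0.15, 0.15), force: bool = False) -> dict:
    """Write a complete on-disk benchmark: SDF + PDB + labels + splits.

    Returns the manifest (also written as ``manifest.json``), which records
    the spec, seed and per-file checksums; regenerating with the same spec
    and seed is byte-identical.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    (out / "ligands").mkdir(parents=True, exist_ok=True)
    (out / "proteins").mkdir(parents=True, exist_ok=True)
    seed = spec.seed if seed is None else seed
    items = generate_dataset(spec, seed=seed)
    labels = {}
    for it in items:
        write_ligand_sdf(it["ligand"], out / "ligands" / f"{it['id']}.sdf")
        write_protein_pdb(it["protein"], out / "proteins" / f"{it['id']}.pdb")
        labels[it["id"]] = it["pk"]
    write_labels_csv(labels, out / "labels.csv")
    ids = [it["id"] for it in items]
    n_train = int(round(split[0] * len(ids)))
    n_val = int(round(split[1] * len(ids)))
    parts = {"train": ids[:n_train], "val": ids[n_train:n_train + n_val],
             "test": ids[n_train + n_val:]}
    for name, part in parts.items():
        write_split_file(part, out / f"{name}.txt")
    manifest = {
        "spec": spec.to_dict(), "seed": seed, "n_complexes": len(ids),
        "splits": {k: len(v) for k, v in parts.items()},
        "checksums": {
            "labels.csv": hashlib.sha256((out / "labels.csv").read_bytes()).hexdigest(),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
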