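"""Readers, writers, label conversions and split handling.

Ligands travel as V2000 SDF (read/written through RDKit), proteins as PDB
(read through Biopython).  Affinity labels are pK values; helpers convert
dissociation/inhibition constants (``pK = -log10(K / 1e9)``) and binding
free energies (``K = exp(-ΔG / RT)``).  Binding-site labels mark residues
with any heavy atom strictly within a cutoff (6 Å by default) of any ligand
atom.  Train/val/test splits are consumed and produced as plain-text ID
files; a balanced k-fold splitter drives cross-validation.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .complexes import ProteinInput
from .geometry import Molecule
from .vocab import ONE_TO_THREE, THREE_TO_ONE, UNK, atom_token

__all__ = [
    "SplitSpec", "read_ligand_sdf", "write_ligand_sdf", "read_protein_pdb",
    "write_protein_pdb", "pk_from_affinity", "k_from_dg", "dg_from_k",
    "label_binding_sites", "count_contacts", "make_cv_folds",
    "read_split_file", "write_split_file", "read_labels_csv",
    "write_labels_csv", "write_affinity_tsv", "write_site_tsv",
]

#: gas constant in kcal / (mol · K)
R_KCAL = 1.98720425864083e-3


@dataclass
class SplitSpec:
    """Named partitions of complex IDs (train/val/test or K folds)."""

    partitions: dict[str, list[str]]
    provenance: str = ""
    folds: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, ids in self.partitions.items():
            for i in ids:
                if i in seen:
                    raise ValueError(
                        f"ID {i!r} appears in both {seen[i]!r} and {name!r}")
                seen[i] = name

    def cv_round(self, r: int) -> dict[str, list[str]]:
        """Round ``r``: fold r tests, fold r+1 validates, the rest train."""
        k = len(self.folds)
        if k < 3:
            raise ValueError("cross-validation needs at least 3 folds")
        test = self.folds[r % k]
        val = self.folds[(r + 1) % k]
        train = [i for j, f in enumerate(self.folds)
                 if j not in (r % k, (r + 1) % k) for i in f]
        return {"train": train, "val": val, "test": test}


def read_ligand_sdf(path, index: int = 0, keep_hydrogens: bool = True) -> Molecule:
    """Read one molecule block from a V2000 SDF file.

    Element symbols outside the 26-type vocabulary map to ``[UNK]`` with a
    warning.  Coordinates are in Å as stored.
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False,
                                  strictParsing=False)
    mols = [m for m in supplier]
    if index >= len(mols) or mols[index] is None:
        raise ValueError(f"could not parse molecule {index} from {path}")
    mol = mols[index]
    conf = mol.GetConformer()
    types, coords = [], []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if not keep_hydrogens and sym == "H":
            continue
        tok = atom_token(sym)
        if tok == UNK:
            warnings.warn(f"element {sym!r} not in vocabulary; using [UNK]")
        types.append(tok)
        pos = conf.GetAtomPosition(atom.GetIdx())
        coords.append([pos.x, pos.y, pos.z])
    if not types:
        raise ValueError(f"no atoms read from {path}")
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else Path(path).stem
    return Molecule(atom_types=types, coords=np.array(coords), id=name)


def write_ligand_sdf(molecule: Molecule, path) -> None:
    """Write a molecule as a bond-less V2000 SDF block (RDKit)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for t in molecule.atom_types:
        rw.AddAtom(Chem.Atom(t if t != UNK else "*"))
    conf = Chem.Conformer(molecule.n_atoms)
    for i, (x, y, z) in enumerate(molecule.coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    mol.SetProp("_Name", molecule.id or "mol")
    with Chem.SDWriter(str(path)) as w:
        w.SetKekulize(False)
        w.write(mol)


def read_protein_pdb(path, chain: str | None = None) -> ProteinInput:
    """Read a protein from PDB ATOM records (first model).

    HETATM records are skipped; hydrogens are dropped (heavy atoms only);
    residues missing a Cα are dropped with a warning; insertion-code
    residues are kept as distinct residues.  Alternate locations resolve to
    the highest-occupancy conformer (Biopython's default policy).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(Path(path).stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no models in {path}")
    types, heavy, ca = [], [], []
    for ch in models[0]:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            if res.id[0] != " ":  # skip HETATM / water
                continue
            atoms = [a for a in res if a.element != "H"]
            if not atoms:
                continue
            if "CA" not in res:
                warnings.warn(f"residue {res.get_resname()} {res.id} lacks CA; dropped")
                continue
            types.append(THREE_TO_ONE.get(res.get_resname(), "X"))
            heavy.append(np.array([a.coord for a in atoms], dtype=float))
            ca.append(np.asarray(res["CA"].coord, dtype=float))
    if not types:
        raise ValueError(f"no ATOM records read from {path}")
    return ProteinInput(residue_types=types, heavy_atom_coords=heavy,
                        ca_coords=np.array(ca), id=Path(path).stem)


def write_protein_pdb(protein: ProteinInput, path) -> None:
    """Write a toy protein as minimal PDB ATOM records.

    Each residue emits its Cα followed by its pseudo heavy atoms (named
    ``C1..``, element C).  Meant for the synthetic benchmark; it makes no
    attempt at chemically meaningful atom naming.
    """
    lines = []
    serial = 1
    for i, (rt, atoms, ca_xyz) in enumerate(
            zip(protein.residue_types, protein.heavy_atom_coords, protein.ca_coords)):
        resname = ONE_TO_THREE.get(rt, "UNK")
        entries = [("CA", ca_xyz)]
        for k, xyz in enumerate(atoms):
            if np.allclose(xyz, ca_xyz):
                continue
            entries.append((f"C{k + 1}", xyz))
        for name, (x, y, z) in entries:
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {resname:>3s} A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{'C':>2s}")
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def pk_from_affinity(k_value: float, unit_convention: str = "nM") -> float:
    """pK from a binding constant.

    ``unit_convention='nM'`` applies ``pK = -log10(K / 1e9)`` (the constant
    expressed in nanomolar numerals); ``'M'`` computes ``-log10(K)`` for a
    constant already in molar units.
    """
    if k_value <= 0:
        raise ValueError("binding constant must be positive")
    if unit_convention == "nM":
        return float(-np.log10(k_value / 1e9))
    if unit_convention == "M":
        return float(-np.log10(k_value))
    raise ValueError(f"unknown unit convention {unit_convention!r}")


def k_from_dg(delta_g: float, T: float = 298.15) -> float:
    """Binding constant from free energy: ``K = exp(-ΔG / (R·T))``."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(-delta_g / (R_KCAL * T)))


def dg_from_k(k_value: float, T: float = 298.15) -> float:
    """Inverse of :func:`k_from_dg`: ``ΔG = -R·T·ln(K)``."""
    if k_value <= 0:
        raise ValueError("binding constant must be positive")
    return float(-R_KCAL * T * np.log(k_value))


def label_binding_sites(protein: ProteinInput, ligand: Molecule,
                        cutoff: float = 6.0) -> np.ndarray:
    """Binary per-residue labels: 1 iff any heavy atom of the residue lies
    strictly within ``cutoff`` Å of any ligand atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    labels = np.zeros(protein.n_residues, dtype=int)
    lig = ligand.coords
    for i, atoms in enumerate(protein.heavy_atom_coords):
        diff = atoms[:, None, :] - lig[None, :, :]
        dmin = np.sqrt(np.sum(diff * diff, axis=-1)).min()
        labels[i] = 1 if dmin < cutoff else 0
    return labels


def count_contacts(protein: ProteinInput, ligand: Molecule,
                   cutoff: float = 6.0, granularity: str = "residue") -> int:
    """Number of protein–ligand contact pairs strictly within ``cutoff`` Å.

    ``granularity='residue'`` counts (residue, ligand atom) pairs where any
    heavy atom of the residue is within the cutoff — the quantity the
    synthetic affinity rule is built on.  ``granularity='atom'`` counts raw
    (heavy atom, ligand atom) pairs.
    """
    lig = ligand.coords
    total = 0
    for atoms in protein.heavy_atom_coords:
        diff = atoms[:, None, :] - lig[None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1))
        if granularity == "atom":
            total += int(np.sum(d < cutoff))
        elif granularity == "residue":
            total += int(np.sum(d.min(axis=0) < cutoff))
        else:
            raise ValueError(f"unknown granularity {granularity!r}")
    return total


def make_cv_folds(ids, k: int, seed: int) -> SplitSpec:
    """Shuffle IDs into ``k`` folds whose sizes differ by at most one."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate IDs")
    if k < 3:
        raise ValueError("k must be at least 3")
    if len(ids) < k:
        raise ValueError("need at least k IDs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(ids[idx])
    return SplitSpec(
        partitions={f"fold{j}": f for j, f in enumerate(folds)},
        provenance=f"make_cv_folds(k={k}, seed={seed})",
        folds=folds,
    )


def read_split_file(path) -> list[str]:
    """One complex ID per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_split_file(ids, path) -> None:
    Path(path).write_text("\n".join(ids) + "\n")


def read_labels_csv(path) -> dict[str, float]:
    """CSV with columns ``id`` and ``pk`` → mapping id → pK."""
    out = {}
    with open(path) as fh:
        for row in csv.DictReader(fh):
            out[row["id"]] = float(row["pk"])
    return out


def write_labels_csv(labels: dict[str, float], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "pk"])
        for i, v in labels.items():
            w.writerow([i, f"{v:.6f}"])


def load_benchmark(bench_dir, split: str | None = None,
                   site_cutoff: float = 6.0) -> list[dict]:
    """Read a benchmark directory written by the synthetic generator.

    Expects ``ligands/<id>.sdf``, ``proteins/<id>.pdb``, ``labels.csv`` and
    split files ``train.txt``/``val.txt``/``test.txt``.  Binding-site labels
    are recomputed from the structures with the heavy-atom cutoff rule.
    Returns complex item dicts; ``split`` restricts to one partition.
    """
    bench = Path(bench_dir)
    labels = read_labels_csv(bench / "labels.csv")
    ids = (read_split_file(bench / f"{split}.txt") if split
           else sorted(labels))
    items = []
    for cid in ids:
        ligand = read_ligand_sdf(bench / "ligands" / f"{cid}.sdf")
        protein = read_protein_pdb(bench / "proteins" / f"{cid}.pdb")
        items.append({
            "id": cid, "ligand": ligand, "protein": protein,
            "pk": labels[cid],
            "site_labels": label_binding_sites(protein, ligand, site_cutoff),
        })
    return items


def write_affinity_tsv(rows, path) -> None:
    """Rows of ``(complex_id, predicted_pk)`` as TSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["complex_id", "predicted_pK"])
        for cid, pk in rows:
            w.writerow([cid, f"{pk:.4f}"])


def write_site_tsv(rows, path) -> None:
    """Rows of ``(complex_id, residue_index, probability)`` as TSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["complex_id", "residue_index", "probability"])
        for cid, ridx, p in rows:
            w.writerow([cid, ridx, f"{p:.5f}"])
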