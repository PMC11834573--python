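"""Physics-guided corruption operators for self-supervised pretraining.

The pretraining task perturbs a clean conformer in two ways and asks the
model to undo both:

* a random fraction of atom types is replaced by ``[MASK]``;
* coordinates are displaced along the gradient of a pairwise Lennard-Jones
  potential, ``x_noisy = x + eta * grad(V)/||grad(V)|| + xi``, with the
  gradient obtained by central finite differences.  Because the displacement
  follows the interatomic forces, the corruption stays consistent with how
  atoms physically push on each other rather than being isotropic jitter.

Lennard-Jones well depths (epsilon, kcal/mol) and contact radii (sigma, Å)
come from a bundled per-element table patterned on the UFF van der Waals
parameters; pairs combine by Lorentz–Berthelot rules.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .vocab import MASK, UNK, atom_token

__all__ = [
    "LJParams",
    "CorruptedSample",
    "lj_potential",
    "total_lj_energy",
    "fd_potential_gradient",
    "apply_gradient_noise",
    "mask_atom_types",
    "corrupt",
]

#: pair distances are clamped below at this value (Å) inside the potential so
#: the r^-12 wall cannot overflow for accidentally overlapping atoms
MIN_DISTANCE_CLAMP = 0.5


def _load_default_table() -> dict[str, tuple[float, float]]:
    table = {}
    ref = resources.files("pairbind").joinpath("resources/lj_params.csv")
    with ref.open() as fh:
        for row in csv.DictReader(fh):
            table[row["type"]] = (
                float(row["sigma_angstrom"]),
                float(row["epsilon_kcal_mol"]),
            )
    return table


@dataclass
class LJParams:
    """Per-atom-type Lennard-Jones parameters with Lorentz–Berthelot mixing."""

    table: dict[str, tuple[float, float]] = field(default_factory=_load_default_table)
    combining_rule: str = "lorentz-berthelot"

    def __post_init__(self) -> None:
        for t, (sigma, eps) in self.table.items():
            if sigma <= 0 or eps <= 0:
                raise ValueError(f"non-positive LJ parameters for type {t!r}")

    def lookup(self, atom_type: str) -> tuple[float, float]:
        """(sigma, epsilon) for one atom token; unknown types use [UNK]."""
        t = atom_token(atom_type)
        if t not in self.table:
            t = UNK
        return self.table[t]

    def pair_params(self, types) -> tuple[np.ndarray, np.ndarray]:
        """(m, m) sigma and epsilon matrices under the combining rule."""
        sig = np.array([self.lookup(t)[0] for t in types])
        eps = np.array([self.lookup(t)[1] for t in types])
        sigma_ij = 0.5 * (sig[:, None] + sig[None, :])
        eps_ij = np.sqrt(eps[:, None] * eps[None, :])
        return sigma_ij, eps_ij


@dataclass
class CorruptedSample:
    """One pretraining example: corrupted inputs paired with clean targets."""

    noisy_coords: np.ndarray
    clean_coords: np.ndarray
    input_types: list[str]
    target_types: list[str]
    mask_indices: np.ndarray
    noise_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noisy_coords.shape != self.clean_coords.shape:
            raise ValueError("noisy/clean coordinate shape mismatch")
        mask_set = set(int(i) for i in np.atleast_1d(self.mask_indices))
        for i, t in enumerate(self.input_types):
            if (t == MASK) != (i in mask_set):
                raise ValueError("mask_indices inconsistent with input_types")


def lj_potential(r, epsilon, sigma):
    """Lennard-Jones pair energy ``4*eps*((sigma/r)^12 - (sigma/r)^6)``.

    Vanishes at ``r = sigma`` and reaches its minimum ``-eps`` at
    ``r = 2^(1/6) * sigma``.  ``r`` must be positive.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("LJ potential requires r > 0")
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def total_lj_energy(
    coords: np.ndarray,
    types,
    params: LJParams | None = None,
    min_dist: float = MIN_DISTANCE_CLAMP,
) -> float:
    """Sum of LJ pair energies over all unordered atom pairs.

    Distances below ``min_dist`` are clamped up to it, which keeps the energy
    (and its finite-difference gradient) bounded for clashed geometries.
    """
    params = params or LJParams()
    coords = np.asarray(coords, dtype=float)
    m = coords.shape[0]
    if m < 2:
        return 0.0
    sigma_ij, eps_ij = params.pair_params(types)
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    iu = np.triu_indices(m, k=1)
    r_pairs = np.maximum(r[iu], min_dist)
    return float(np.sum(lj_potential(r_pairs, eps_ij[iu], sigma_ij[iu])))


def fd_potential_gradient(
    coords: np.ndarray,
    types,
    params: LJParams | None = None,
    h: float = 1e-4,
    min_dist: float = MIN_DISTANCE_CLAMP,
) -> np.ndarray:
    """Central-difference gradient of the total LJ energy, shape ``(m, 3)``.

    Each Cartesian coordinate is displaced by ``±h`` and the energy
    difference divided by ``2h``; the truncation error is O(h²).  Since the
    potential only depends on interatomic distances, the per-molecule sum of
    gradients vanishes (no net force on the centre of mass).
    """
    if h <= 0:
        raise ValueError("finite-difference step must be positive")
    params = params or LJParams()
    coords = np.asarray(coords, dtype=float)
    m = coords.shape[0]
    grad = np.zeros_like(coords)
    if m < 2:
        return grad
    sigma_ij, eps_ij = params.pair_params(types)
    iu = np.triu_indices(m, k=1)
    sig_u, eps_u = sigma_ij[iu], eps_ij[iu]

    def energy(c: np.ndarray) -> float:
        diff = c[:, None, :] - c[None, :, :]
        r = np.maximum(np.sqrt(np.sum(diff * diff, axis=-1))[iu], min_dist)
        sr6 = (sig_u / r) ** 6
        return float(np.sum(4.0 * eps_u * (sr6 * sr6 - sr6)))

    for i in range(m):
        for k in range(3):
            bumped = coords.copy()
            bumped[i, k] += h
            e_plus = energy(bumped)
            bumped[i, k] -= 2 * h
            e_minus = energy(bumped)
            grad[i, k] = (e_plus - e_minus) / (2 * h)
    return grad


def apply_gradient_noise(
    coords: np.ndarray,
    gradient: np.ndarray,
    eta: float,
    xi_std: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Displace coordinates along the (normalized) potential gradient.

    ``x_noisy = x + eta * g/||g||_F + xi`` with ``xi ~ N(0, xi_std²)`` i.i.d.
    per coordinate.  The Frobenius norm makes ``eta`` the total displacement
    budget of the gradient term; a vanishing gradient drops the term.
    """
    coords = np.asarray(coords, dtype=float)
    gradient = np.asarray(gradient, dtype=float)
    if gradient.shape != coords.shape:
        raise ValueError("gradient/coords shape mismatch")
    if eta < 0 or xi_std < 0:
        raise ValueError("eta and xi_std must be non-negative")
    rng = np.random.default_rng(seed)
    out = coords.copy()
    gnorm = np.linalg.norm(gradient)
    if eta > 0 and gnorm > 1e-12:
        out = out + eta * gradient / gnorm
    if xi_std > 0:
        out = out + rng.normal(0.0, xi_std, size=coords.shape)
    return out


def mask_atom_types(
    types,
    ratio_range: tuple[float, float],
    seed: int | np.random.Generator,
) -> tuple[list[str], np.ndarray]:
    """Replace a random fraction of atom types with ``[MASK]``.

    The fraction is drawn uniformly from ``ratio_range`` per call, and at
    least one atom is always masked so every sample carries a type-recovery
    signal.  Returns the masked sequence and the sorted masked indices.
    """
    lo, hi = ratio_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("ratio_range must satisfy 0 <= lo <= hi <= 1")
    types = list(types)
    m = len(types)
    if m == 0:
        raise ValueError("cannot mask an empty molecule")
    rng = np.random.default_rng(seed)
    ratio = rng.uniform(lo, hi)
    k = max(1, int(round(ratio * m)))
    k = min(k, m)
    idx = np.sort(rng.choice(m, size=k, replace=False))
    masked = list(types)
    for i in idx:
        masked[i] = MASK
    return masked, idx


def corrupt(
    molecule,
    seed: int | np.random.Generator,
    mask_ratio_range: tuple[float, float] = (0.1, 0.3),
    eta_range: tuple[float, float] = (0.1, 0.5),
    xi_std: float = 0.05,
    h: float = 1e-4,
    params: LJParams | None = None,
) -> CorruptedSample:
    """Produce one corrupted pretraining sample from a clean molecule.

    The gradient-noise scale ``eta`` is drawn uniformly per molecule; type
    masking and coordinate noise use independent streams of the same seeded
    generator, so corruption is bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    params = params or LJParams()
    masked, idx = mask_atom_types(molecule.atom_types, mask_ratio_range, rng)
    grad = fd_potential_gradient(molecule.coords, molecule.atom_types, params, h=h)
    eta = float(rng.uniform(*eta_range))
    noisy = apply_gradient_noise(molecule.coords, grad, eta, xi_std, rng)
    return CorruptedSample(
        noisy_coords=noisy,
        clean_coords=molecule.coords.copy(),
        input_types=masked,
        target_types=list(molecule.atom_types),
        mask_indices=idx,
        noise_meta={
            "eta": eta,
            "xi_std": xi_std,
            "grad_norm": float(np.linalg.norm(grad)),
        },
    )
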